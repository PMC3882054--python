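"""Private-variant prioritization cascades and codon-level consequence
annotation that is aware of multi-nucleotide variants (MNVs).

Two filtering strategies are provided:

* **Cascade A** (cases vs. unrelated controls + known-variant catalogue):
  discard variants seen in any control or previously catalogued, keep those
  homozygous-alt in every case, then narrow by region (transcribed → ORF)
  and finally to amino-acid-changing variants.
* **Cascade B** (cases + obligate carriers + non-carriers): keep variants
  homozygous-alt in all cases, heterozygous in all carriers, and absent from
  all non-carriers, then break the survivors down by genomic region and
  coding consequence.

Consequence annotation groups coding substitutions by codon and applies all
substitutions in a codon *jointly* before translating.  Clustered
substitutions that arise from a single multinucleotide mutational event can
otherwise be radically miscalled — e.g. two substitutions that jointly give a
missense change may each look like a nonsense or silent change in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genes import ToyGene, VALID_BASES

# genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing
MISSING = -1


@dataclass(frozen=True)
class VariantRecord:
    """One called sequence variant with per-sample genotype codes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("position must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in VALID_BASES and self.alt in VALID_BASES

    def genotype(self, sample: str) -> int:
        try:
            return self.genotypes[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} absent from variant {self.key}") from None


@dataclass(frozen=True)
class KnownCatalogue:
    """Set of previously reported variants keyed by (chrom, pos, ref, alt)."""

    keys: frozenset[tuple[str, int, str, str]]

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, VariantRecord) else tuple(item)
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in sorted(self.keys):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")

    @classmethod
    def read_tsv(cls, path) -> "KnownCatalogue":
        keys = set()
        with open(path) as fh:
            header = fh.readline()
            if header.split() != ["chrom", "pos", "ref", "alt"]:
                raise ValueError(f"unexpected catalogue header in {path}")
            for line in fh:
                chrom, pos, ref, alt = line.split()
                keys.add((chrom, int(pos), ref, alt))
        return cls(frozenset(keys))


# --------------------------------------------------------------------------
# region classification
# --------------------------------------------------------------------------

REGION_INTERGENIC = "intergenic"
REGION_INTRONIC = "intronic"
REGION_EXONIC_NONCODING = "exonic-noncoding"
REGION_CDS = "CDS"


def classify_region(variant: VariantRecord | int, gene: ToyGene) -> str:
    """Classify a position against the gene model (1-based inclusive spans).

    CDS beats exonic-noncoding (UTR); positions inside the transcript span
    but in no exon are intronic; everything else (including other
    chromosomes) is intergenic.
    """
    if isinstance(variant, VariantRecord):
        if variant.chrom != gene.chrom:
            return REGION_INTERGENIC
        pos = variant.pos
    else:
        pos = int(variant)
    span = gene.span
    if not span[0] <= pos <= span[1]:
        return REGION_INTERGENIC
    cpos = gene.genomic_to_cds(pos)
    if cpos is not None:
        return REGION_CDS
    if gene.genomic_to_transcript(pos) is not None:
        return REGION_EXONIC_NONCODING
    return REGION_INTRONIC


def is_transcribed(variant: VariantRecord | int, gene: ToyGene) -> bool:
    """Exonic (UTR or CDS); introns do not count as transcribed here."""
    return classify_region(variant, gene) in (REGION_CDS, REGION_EXONIC_NONCODING)


# --------------------------------------------------------------------------
# codon arithmetic and MNV-aware annotation
# --------------------------------------------------------------------------


def translate_codon(codon: str) -> tuple[str, str]:
    """Standard genetic code translation of one codon.

    Returns (one-letter, three-letter); stop is ('*', 'Ter').
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in VALID_BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = str(Seq(codon).translate())
    return aa, seq3(aa)


def codon_index(cds_position: int, cds_length: int | None = None) -> int:
    """1-based codon (residue) index containing a 1-based CDS base position."""
    if cds_position < 1 or (cds_length is not None and cds_position > cds_length):
        raise ValueError(f"CDS position {cds_position} out of range")
    return (cds_position - 1) // 3 + 1


@dataclass(frozen=True)
class CdsVariant:
    """A single-base substitution in CDS coordinates (coding strand)."""

    cds_pos: int
    ref: str
    alt: str
    source: VariantRecord | None = None

    @property
    def codon_index(self) -> int:
        return codon_index(self.cds_pos)

    @property
    def offset(self) -> int:
        """0-based position within its codon."""
        return (self.cds_pos - 1) % 3

    @property
    def c_label(self) -> str:
        return f"c.{self.cds_pos}{self.ref}>{self.alt}"


def genomic_to_cds_variant(variant: VariantRecord, gene: ToyGene) -> CdsVariant | None:
    """Project a genomic SNV onto CDS coordinates, complementing alleles on
    minus-strand genes.  Returns None for non-CDS or non-SNV variants."""
    if not variant.is_snv or variant.chrom != gene.chrom:
        return None
    cpos = gene.genomic_to_cds(variant.pos)
    if cpos is None:
        return None
    ref, alt = variant.ref, variant.alt
    if gene.strand == "-":
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    return CdsVariant(cds_pos=cpos, ref=ref, alt=alt, source=variant)


@dataclass(frozen=True)
class CodonGroup:
    """All substitutions landing in one codon of one gene."""

    gene_id: str
    codon_index: int
    members: tuple[CdsVariant, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 3:
            raise ValueError("a codon group holds 1-3 substitutions")
        if any(m.codon_index != self.codon_index for m in self.members):
            raise ValueError("member outside group codon")
        offsets = [m.offset for m in self.members]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate within-codon offsets")


def group_codon_mnv(cds_variants: list[CdsVariant], gene: ToyGene) -> list[CodonGroup]:
    """Group CDS substitutions by codon; variants sharing a codon form one
    multi-member group, all others are singletons.  Groups are returned in
    CDS order."""
    seen: set[int] = set()
    for v in cds_variants:
        if v.cds_pos in seen:
            raise ValueError(f"duplicate CDS position {v.cds_pos}")
        seen.add(v.cds_pos)
    by_codon: dict[int, list[CdsVariant]] = defaultdict(list)
    for v in cds_variants:
        by_codon[v.codon_index].append(v)
    groups = []
    for ci in sorted(by_codon):
        members = tuple(sorted(by_codon[ci], key=lambda m: m.cds_pos))
        groups.append(CodonGroup(gene_id=gene.gene_id, codon_index=ci, members=members))
    return groups


CLASS_SYNONYMOUS = "synonymous"
CLASS_MISSENSE = "missense"
CLASS_NONSENSE = "nonsense"
CLASS_STOP_LOSS = "stop-loss"


@dataclass(frozen=True)
class ConsequenceRecord:
    gene_id: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str  # one-letter; '*' for stop
    alt_aa: str
    consequence: str  # synonymous | missense | nonsense | stop-loss
    c_labels: tuple[str, ...]
    p_label: str
    short_label: str

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "codon_index": self.codon_index,
            "ref_codon": self.ref_codon,
            "alt_codon": self.alt_codon,
            "ref_aa": self.ref_aa,
            "alt_aa": self.alt_aa,
            "consequence": self.consequence,
            "c_labels": list(self.c_labels),
            "p_label": self.p_label,
            "short_label": self.short_label,
        }


def annotate_codon_group(group: CodonGroup, cds_sequence: str) -> ConsequenceRecord:
    """Translate the reference codon and the codon with *all* member
    substitutions applied jointly, then classify the change.

    Raises if any member's reference allele disagrees with the CDS.
    """
    ci = group.codon_index
    ref_codon = cds_sequence[3 * (ci - 1) : 3 * ci]
    if len(ref_codon) != 3:
        raise ValueError(f"codon {ci} outside the CDS")
    alt = list(ref_codon)
    for m in group.members:
        if ref_codon[m.offset] != m.ref:
            raise ValueError(
                f"reference mismatch at CDS position {m.cds_pos}: "
                f"CDS has {ref_codon[m.offset]}, variant claims {m.ref}"
            )
        alt[m.offset] = m.alt
    alt_codon = "".join(alt)
    ref_aa, ref_aa3 = translate_codon(ref_codon)
    alt_aa, alt_aa3 = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        consequence = CLASS_SYNONYMOUS
    elif alt_aa == "*":
        consequence = CLASS_NONSENSE
    elif ref_aa == "*":
        consequence = CLASS_STOP_LOSS
    else:
        consequence = CLASS_MISSENSE
    if consequence == CLASS_SYNONYMOUS:
        p_label = f"p.{ref_aa3}{ci}="
        short = f"{ref_aa}{ci}"
    else:
        p_label = f"p.{ref_aa3}{ci}{alt_aa3}"
        short = f"{ref_aa}{ci}{alt_aa}"
    return ConsequenceRecord(
        gene_id=group.gene_id,
        codon_index=ci,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        c_labels=tuple(m.c_label for m in group.members),
        p_label=p_label,
        short_label=short,
    )


def annotate_cds_variants(variants: list[VariantRecord], gene: ToyGene
                          ) -> list[tuple[CodonGroup, ConsequenceRecord]]:
    """MNV-aware annotation of the CDS substitutions among ``variants``."""
    cds_vars = [cv for v in variants if (cv := genomic_to_cds_variant(v, gene)) is not None]
    groups = group_codon_mnv(cds_vars, gene)
    return [(g, annotate_codon_group(g, gene.cds_sequence)) for g in groups]


# --------------------------------------------------------------------------
# filtering cascades
# --------------------------------------------------------------------------


def _check_samples(variants: list[VariantRecord], sample_ids: list[str], role: str) -> None:
    if not variants:
        return
    missing = [s for s in sample_ids if s not in variants[0].genotypes]
    if missing:
        raise KeyError(f"unknown {role} sample id(s): {missing}")


def filter_known_or_in_controls(
    variants: list[VariantRecord],
    control_ids: list[str],
    catalogue: KnownCatalogue,
) -> tuple[list[VariantRecord], int]:
    """Remove variants whose alt allele appears in any control (het or hom)
    or that are already catalogued.  Missing control genotypes carry no alt
    evidence.  Returns (retained in input order, removed count)."""
    _check_samples(variants, control_ids, "control")
    retained = []
    for v in variants:
        in_controls = any(v.genotype(c) in (1, 2) for c in control_ids)
        if in_controls or v in catalogue:
            continue
        retained.append(v)
    return retained, len(variants) - len(retained)


def percent_removed(removed: int, total: int) -> int:
    """Step-1 removal percentage, rounded to the nearest integer."""
    if total == 0:
        return 0
    return int(round(100.0 * removed / total))


@dataclass
class CascadeAReport:
    total: int
    removed_known_or_in_controls: int
    remaining: int
    percent_removed_step1: int
    hom_in_all_cases: int
    in_transcribed: int
    in_orf: int
    aa_changing: int
    retained: dict[str, list[VariantRecord]] = field(default_factory=dict)
    consequences: list[ConsequenceRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "total": self.total,
            "removed_known_or_in_controls": self.removed_known_or_in_controls,
            "remaining": self.remaining,
            "hom_in_all_cases": self.hom_in_all_cases,
            "in_transcribed": self.in_transcribed,
            "in_orf": self.in_orf,
            "aa_changing": self.aa_changing,
        }


def cascade_a(
    variants: list[VariantRecord],
    case_ids: list[str],
    control_ids: list[str],
    catalogue: KnownCatalogue,
    gene: ToyGene,
) -> CascadeAReport:
    """Private-variant cascade: catalogue/control filter → homozygous-alt in
    all cases → transcribed (exonic) → ORF (CDS) → amino-acid changing.

    The case criterion (homozygous in every affected) is applied explicitly;
    a missing case genotype disqualifies the variant.  Amino-acid-changing
    status is decided per codon group (MNV-aware), and every member of a
    non-synonymous group counts as amino-acid changing.
    """
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control cohorts overlap")
    _check_samples(variants, case_ids, "case")
    step1, removed = filter_known_or_in_controls(variants, control_ids, catalogue)
    step2 = [v for v in step1 if all(v.genotype(s) == 2 for s in case_ids)]
    step3 = [v for v in step2 if is_transcribed(v, gene)]
    step4 = [v for v in step3 if classify_region(v, gene) == REGION_CDS]
    annotated = annotate_cds_variants(step4, gene)
    aa_keys = set()
    consequences = []
    for g, cons in annotated:
        consequences.append(cons)
        if cons.consequence != CLASS_SYNONYMOUS:
            aa_keys.update(m.source.key for m in g.members if m.source is not None)
    step5 = [v for v in step4 if v.key in aa_keys]
    return CascadeAReport(
        total=len(variants),
        removed_known_or_in_controls=removed,
        remaining=len(step1),
        percent_removed_step1=percent_removed(removed, len(variants)),
        hom_in_all_cases=len(step2),
        in_transcribed=len(step3),
        in_orf=len(step4),
        aa_changing=len(step5),
        retained={
            "after_catalogue_control_filter": step1,
            "hom_in_all_cases": step2,
            "in_transcribed": step3,
            "in_orf": step4,
            "aa_changing": step5,
        },
        consequences=consequences,
    )


@dataclass
class CascadeBReport:
    survivors: list[VariantRecord]
    breakdown: dict[str, int]  # intergenic / intronic / exonic-noncoding / coding
    coding_split: dict[str, int]  # synonymous / non-synonymous
    consequences: list[ConsequenceRecord] = field(default_factory=list)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


def cascade_b(
    variants: list[VariantRecord],
    case_ids: list[str],
    carrier_ids: list[str],
    noncarrier_ids: list[str],
    gene: ToyGene,
    *,
    missing_disqualifies: bool = True,
    missing_noncarrier_is_absent: bool = True,
) -> CascadeBReport:
    """Segregation-based cascade: a survivor must be homozygous-alt in every
    case, heterozygous in every obligate carrier, and carry no alt allele in
    any non-carrier.

    Missing genotypes: for the universally-quantified case/carrier criteria a
    missing call cannot certify "all", so by default it disqualifies; a
    missing non-carrier call counts as absence of the alt allele by default.
    """
    cohorts = [set(case_ids), set(carrier_ids), set(noncarrier_ids)]
    if not all(cohorts) or any(a & b for a, b in
                               ((cohorts[0], cohorts[1]), (cohorts[0], cohorts[2]),
                                (cohorts[1], cohorts[2]))):
        raise ValueError("cohorts must be non-empty and pairwise disjoint")
    for ids, role in ((case_ids, "case"), (carrier_ids, "carrier"),
                      (noncarrier_ids, "noncarrier")):
        _check_samples(variants, ids, role)

    def all_equal(v: VariantRecord, ids, value: int) -> bool:
        for s in ids:
            g = v.genotype(s)
            if g == MISSING:
                if missing_disqualifies:
                    return False
                continue
            if g != value:
                return False
        return True

    def absent(v: VariantRecord, ids) -> bool:
        for s in ids:
            g = v.genotype(s)
            if g == MISSING:
                if not missing_noncarrier_is_absent:
                    return False
                continue
            if g in (1, 2):
                return False
        return True

    survivors = [
        v
        for v in variants
        if all_equal(v, case_ids, 2) and all_equal(v, carrier_ids, 1)
        and absent(v, noncarrier_ids)
    ]
    breakdown = {
        REGION_INTERGENIC: 0,
        REGION_INTRONIC: 0,
        REGION_EXONIC_NONCODING: 0,
        "coding": 0,
    }
    coding = []
    for v in survivors:
        region = classify_region(v, gene)
        if region == REGION_CDS:
            breakdown["coding"] += 1
            coding.append(v)
        else:
            breakdown[region] += 1
    annotated = annotate_cds_variants(coding, gene)
    consequences = [cons for _, cons in annotated]
    nonsyn_keys = set()
    for g, cons in annotated:
        if cons.consequence != CLASS_SYNONYMOUS:
            nonsyn_keys.update(m.source.key for m in g.members if m.source is not None)
    n_nonsyn = sum(1 for v in coding if v.key in nonsyn_keys)
    coding_split = {"synonymous": len(coding) - n_nonsyn, "non-synonymous": n_nonsyn}
    return CascadeBReport(
        survivors=survivors,
        breakdown=breakdown,
        coding_split=coding_split,
        consequences=consequences,
    )
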