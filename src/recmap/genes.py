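"""Toy gene models: exon structure, CDS coordinate arithmetic, and file I/O.

A :class:`ToyGene` is a minimal transcript model — an ordered set of exons on
one chromosome, a strand, and the coding sequence (always given on the coding
strand) — sufficient to classify variant positions (intergenic / intronic /
exonic-noncoding / CDS) and to map between genomic and CDS coordinates in
both strand orientations.  Coordinates are 1-based inclusive throughout
(VCF/GFF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (upper-case ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ToyGene:
    """Minimal single-transcript gene model.

    Parameters
    ----------
    gene_id:
        Identifier used in annotations and GFF3 output.
    chrom:
        Chromosome name.
    strand:
        ``'+'`` or ``'-'``.  ``cds_sequence`` is always the coding-strand
        sequence regardless of strand.
    exons:
        Sorted, non-overlapping 1-based inclusive genomic spans.
    cds_sequence:
        The full ORF, starting with ATG and ending with a stop codon.
    utr5_len:
        Number of transcript bases (in transcription order) preceding the CDS.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    utr5_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")
        if not self.cds_sequence.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        if self.cds_sequence[-3:] not in STOP_CODONS:
            raise ValueError("CDS must end with a stop codon")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon span ({start}, {end}) reversed")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.utr5_len + len(self.cds_sequence) > self.transcript_length:
            raise ValueError("CDS does not fit inside the exons")

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span of the transcript (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    # ---- coordinate arithmetic -------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """1-based transcript offset of a genomic position, or None if intronic
        or outside the transcript.  Transcript order follows transcription
        direction (reversed exon order on the minus strand)."""
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        offset = 0
        for start, end in exons:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start) + 1
                return offset + (end - pos) + 1
            offset += end - start + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= self.transcript_length:
            raise ValueError(f"transcript position {tpos} outside 1..{self.transcript_length}")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        remaining = tpos - 1
        for start, end in exons:
            n = end - start + 1
            if remaining < n:
                return start + remaining if self.strand == "+" else end - remaining
            remaining -= n
        raise AssertionError("unreachable")

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, or None if not in CDS."""
        tpos = self.genomic_to_transcript(pos)
        if tpos is None:
            return None
        cpos = tpos - self.utr5_len
        if 1 <= cpos <= self.cds_length:
            return cpos
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        if not 1 <= cpos <= self.cds_length:
            raise ValueError(f"CDS position {cpos} outside 1..{self.cds_length}")
        return self.transcript_to_genomic(cpos + self.utr5_len)

    def cds_base(self, cpos: int) -> str:
        if not 1 <= cpos <= self.cds_length:
            raise ValueError(f"CDS position {cpos} outside 1..{self.cds_length}")
        return self.cds_sequence[cpos - 1]

    def mirrored(self, genome_length: int) -> "ToyGene":
        """The same gene on the opposite strand of a reverse-complemented
        genome of the given length (coordinate p maps to genome_length-p+1).

        Annotation of mirrored variants must produce identical consequences;
        this rendition exists to test exactly that.
        """
        new_exons = tuple(
            sorted((genome_length - e + 1, genome_length - s + 1) for s, e in self.exons)
        )
        new_strand = "-" if self.strand == "+" else "+"
        return replace(self, strand=new_strand, exons=new_exons)


@dataclass(frozen=True)
class CausalCluster:
    """A cluster of single-base substitutions inside one exon, all within a
    7-bp window, jointly inherited as a single mutational event."""

    chrom: str
    genomic_positions: tuple[int, ...]
    cds_positions: tuple[int, ...]
    ref_alleles: tuple[str, ...]
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.genomic_positions)
        if not (len(self.cds_positions) == len(self.ref_alleles) == len(self.alt_alleles) == n):
            raise ValueError("cluster field lengths differ")
        if max(self.genomic_positions) - min(self.genomic_positions) > 6:
            raise ValueError("cluster must span at most 7 bp")
        for r, a in zip(self.ref_alleles, self.alt_alleles):
            if r == a or r not in VALID_BASES or a not in VALID_BASES:
                raise ValueError(f"bad substitution {r}>{a}")

    def __len__(self) -> int:
        return len(self.genomic_positions)


# Default CDS geometry: the substitutions fall in codons 748 (silent, third
# base) and 750 (first + third base, jointly missense).
DEFAULT_CLUSTER_CDS_POSITIONS = (2244, 2248, 2250)
DEFAULT_CLUSTER_REF = ("G", "T", "C")
DEFAULT_CLUSTER_ALT = ("C", "C", "A")


def make_toy_gene(
    rng: np.random.Generator,
    *,
    gene_id: str = "TOY_CLCN7",
    chrom: str = "1",
    gene_start: int = 15_000_000,
    strand: str = "+",
    cds_length: int = 2427,
    utr5_len: int = 50,
    utr3_len: int = 50,
    n_exons: int = 5,
    intron_length: int = 300,
) -> ToyGene:
    """Generate a random ORF of the requested length with fixed codons 748
    (TCG) and 750 (TAC), packaged into a multi-exon transcript whose last exon
    contains the codon-748..750 region entirely.

    Internal codons are sampled uniformly from the 61 non-stop codons; the
    terminal codon is TAA.
    """
    if cds_length % 3 != 0 or cds_length < 3 * 751:
        raise ValueError("cds_length must be a multiple of 3 and cover codon 750")
    n_codons = cds_length // 3
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    idx = rng.integers(0, len(non_stop), size=n_codons)
    codons = [non_stop[i] for i in idx]
    codons[0] = "ATG"
    codons[747] = "TCG"  # Ser, third base 2244
    codons[749] = "TAC"  # Tyr, bases 2248-2250
    codons[-1] = "TAA"
    cds = "".join(codons)

    transcript_len = utr5_len + cds_length + utr3_len
    # Last exon must contain transcript positions for CDS 2200..end; put the
    # final ~quarter of the transcript in it and split the rest evenly.
    last_len = max(transcript_len // 4, transcript_len - (utr5_len + 2200) + 60)
    head = transcript_len - last_len
    cuts = [round(head * k / (n_exons - 1)) for k in range(n_exons)]  # prefix lengths
    lengths = [cuts[k + 1] - cuts[k] for k in range(n_exons - 1)] + [last_len]
    exons = []
    pos = gene_start
    for L in lengths:
        exons.append((pos, pos + L - 1))
        pos += L + intron_length
    return ToyGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_sequence=cds,
        utr5_len=utr5_len,
    )


def make_causal_cluster(gene: ToyGene) -> CausalCluster:
    """Place the default three-substitution cluster on a toy gene, verifying
    that the reference alleles match the CDS and that all three genomic
    positions fall inside one exon."""
    cds_pos = DEFAULT_CLUSTER_CDS_POSITIONS
    for p, r in zip(cds_pos, DEFAULT_CLUSTER_REF):
        if gene.cds_base(p) != r:
            raise ValueError(f"CDS base at {p} is {gene.cds_base(p)}, expected {r}")
    gpos = tuple(gene.cds_to_genomic(p) for p in cds_pos)
    exon_of = []
    for g in gpos:
        hit = [i for i, (s, e) in enumerate(gene.exons) if s <= g <= e]
        if not hit:
            raise ValueError(f"cluster position {g} not exonic")
        exon_of.append(hit[0])
    if len(set(exon_of)) != 1:
        raise ValueError("cluster spans an exon boundary")
    if gene.strand == "+":
        ref = DEFAULT_CLUSTER_REF
        alt = DEFAULT_CLUSTER_ALT
    else:
        # genome holds the reverse complement of the coding strand
        ref = tuple(b.translate(_COMPLEMENT) for b in DEFAULT_CLUSTER_REF)
        alt = tuple(b.translate(_COMPLEMENT) for b in DEFAULT_CLUSTER_ALT)
    order = np.argsort(gpos)
    return CausalCluster(
        chrom=gene.chrom,
        genomic_positions=tuple(gpos[i] for i in order),
        cds_positions=tuple(cds_pos[i] for i in order),
        ref_alleles=tuple(ref[i] for i in order),
        alt_alleles=tuple(alt[i] for i in order),
    )


# ---- file I/O -------------------------------------------------------------


def write_gff3(gene: ToyGene, path) -> None:
    """Write the gene as GFF3 (gene / mRNA / exon / CDS features)."""
    span = gene.span
    lines = ["##gff-version 3"]
    attrs = f"ID=gene:{gene.gene_id};Name={gene.gene_id}"
    lines.append(
        "\t".join(
            [gene.chrom, "recmap", "gene", str(span[0]), str(span[1]), ".", gene.strand, ".", attrs]
        )
    )
    mrna_id = f"transcript:{gene.gene_id}.1"
    lines.append(
        "\t".join(
            [
                gene.chrom,
                "recmap",
                "mRNA",
                str(span[0]),
                str(span[1]),
                ".",
                gene.strand,
                ".",
                f"ID={mrna_id};Parent=gene:{gene.gene_id};utr5_len={gene.utr5_len}",
            ]
        )
    )
    for i, (s, e) in enumerate(gene.exons, 1):
        lines.append(
            "\t".join(
                [gene.chrom, "recmap", "exon", str(s), str(e), ".", gene.strand, ".",
                 f"ID=exon:{gene.gene_id}.{i};Parent={mrna_id}"]
            )
        )
    # CDS features: the exonic pieces overlapping the CDS
    cds_g = sorted(gene.cds_to_genomic(p) for p in (1, gene.cds_length))
    for s, e in gene.exons:
        lo, hi = max(s, cds_g[0]), min(e, cds_g[1])
        if lo <= hi:
            lines.append(
                "\t".join(
                    [gene.chrom, "recmap", "CDS", str(lo), str(hi), ".", gene.strand, "0",
                     f"ID=cds:{gene.gene_id};Parent={mrna_id}"]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path, cds_sequence: str) -> ToyGene:
    """Reconstruct a ToyGene from GFF3 written by :func:`write_gff3` plus the
    CDS FASTA (the CDS sequence is not representable in GFF3 itself)."""
    exons: list[tuple[int, int]] = []
    gene_id = None
    chrom = None
    strand = "+"
    utr5_len = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] == "gene":
                chrom, strand = f[0], f[6]
                for kv in f[8].split(";"):
                    k, _, v = kv.partition("=")
                    if k == "Name":
                        gene_id = v
            elif f[2] == "mRNA":
                for kv in f[8].split(";"):
                    k, _, v = kv.partition("=")
                    if k == "utr5_len":
                        utr5_len = int(v)
            elif f[2] == "exon":
                exons.append((int(f[3]), int(f[4])))
    if gene_id is None or chrom is None:
        raise ValueError(f"no gene feature found in {path}")
    return ToyGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(sorted(exons)),
        cds_sequence=cds_sequence,
        utr5_len=utr5_len,
    )


def write_cds_fasta(gene: ToyGene, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{gene.gene_id} CDS\n")
        seq = gene.cds_sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def read_cds_fasta(path) -> tuple[str, str]:
    """Return (record id, sequence) of the first FASTA record."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()
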