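"""Synthetic population, genotype, callset and voltage-clamp trace generator.

Every downstream stage of the pipeline (autozygosity mapping, variant
prioritization, segregation statistics, kinetics fitting) is exercised
against data produced here, with full ground truth retained:

* a pedigree descending from a single founder carrier of a recessive allele,
  grown until a requested number of affected (homozygous) individuals exists;
* phased SNP-marker haplotypes propagated by gene drop (Poisson crossovers,
  Haldane map function, no interference), with per-position founder-origin
  labels so identity-by-descent is known exactly;
* SNP-array genotype matrices with a configurable genotyping error rate;
* a WGS-like variant callset over a resequencing window around a toy gene,
  containing the planted three-substitution causal cluster, perfectly linked
  haplotype variants, and background variation, plus a known-variants
  catalogue;
* two-electrode voltage-clamp current traces following a single-exponential
  activation/deactivation model with an outwardly rectifying amplitude.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genes import CausalCluster, ToyGene
from .kinetics import ClampProtocol, CurrentTrace
from .prioritize import KnownCatalogue, VariantRecord

__all__ = [
    "SimConfig",
    "Individual",
    "Pedigree",
    "GeneticMap",
    "HaplotypeSet",
    "TraceSimSpec",
    "QuotaError",
    "build_population",
    "gene_drop",
    "emit_array_genotypes",
    "emit_wgs_callset",
    "simulate_traces",
    "default_trace_spec",
]


class QuotaError(RuntimeError):
    """Raised when rejection resampling cannot reach the affected-case quota."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated population.

    Defaults are a desk-scale stand-in for a livestock breed mapping study:
    a closed herd founded by few animals, one of which (a heavily used sire)
    carries the recessive allele; medium-density array markers every 30 kb on
    three 30-Mb chromosomes; and a ~1.15-Mb resequencing window around the
    candidate gene with roughly two variants per kb.
    """

    n_founders: int = 40
    n_generations: int = 5
    mean_offspring: float = 3.0
    target_n_cases: int = 6
    chromosome_lengths: tuple[int, ...] = (30_000_000, 30_000_000, 30_000_000)
    marker_spacing: int = 30_000
    cm_per_mb: float = 1.0
    genotyping_error_rate: float = 0.001
    background_variant_density: float = 1.9  # variants per kb in the WGS window
    catalogue_fraction: float = 0.6
    seed: int = 0
    # population structure knobs
    popular_sire_weight: float = 10.0
    max_attempts: int = 40
    phenocopy_rate: float = 0.0
    # WGS window + linked-variant composition (the disease haplotype carries
    # perfectly linked private variants besides the causal cluster)
    wgs_halfwidth: int = 575_000
    n_linked_intergenic: int = 8
    n_linked_intronic: int = 3
    n_linked_synonymous: int = 1
    common_fraction: float = 0.85  # background variants segregating breed-wide

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.target_n_cases < 0:
            raise ValueError("target_n_cases must be >= 0")
        if self.mean_offspring <= 0:
            raise ValueError("mean_offspring must be positive")
        if self.marker_spacing < 1 or any(L < 1 for L in self.chromosome_lengths):
            raise ValueError("lengths and spacing must be >= 1")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be >= 0")
        for name in ("genotyping_error_rate", "catalogue_fraction", "phenocopy_rate",
                     "common_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_variant_density < 0:
            raise ValueError("background_variant_density must be >= 0")


@dataclass
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str  # 'M' or 'F'
    generation: int
    phenotype: str = "unknown"  # affected | unaffected | unknown
    carrier_state: str = "noncarrier"  # noncarrier | carrier | homozygous

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class Pedigree:
    """Ordered collection of individuals; parents always precede children."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise ValueError(f"duplicate individual id {ind.id}")
        self.individuals[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def ids(self) -> list[str]:
        return list(self.individuals)

    def affected_ids(self) -> list[str]:
        return [i.id for i in self if i.phenotype == "affected"]

    def unaffected_ids(self) -> list[str]:
        return [i.id for i in self if i.phenotype == "unaffected"]

    def carrier_ids(self) -> list[str]:
        return [i.id for i in self if i.carrier_state == "carrier"]

    def noncarrier_ids(self) -> list[str]:
        return [i.id for i in self if i.carrier_state == "noncarrier"]

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": i.id,
                    "sire": i.sire or "0",
                    "dam": i.dam or "0",
                    "sex": i.sex,
                    "generation": i.generation,
                    "phenotype": i.phenotype,
                    "carrier_state": i.carrier_state,
                }
                for i in self
            ]
        )


@dataclass(frozen=True)
class GeneticMap:
    """Linear genetic map: one cM position per marker per chromosome."""

    chroms: tuple[str, ...]
    lengths_bp: dict[str, int]
    positions_bp: dict[str, np.ndarray]
    cm_per_mb: float

    def positions_cm(self, chrom: str) -> np.ndarray:
        return self.positions_bp[chrom] * (self.cm_per_mb / 1e6)

    def length_cm(self, chrom: str) -> float:
        return self.lengths_bp[chrom] * (self.cm_per_mb / 1e6)

    def bp_to_cm(self, chrom: str, pos_bp: int) -> float:
        if not 1 <= pos_bp <= self.lengths_bp[chrom]:
            raise ValueError(f"position {pos_bp} outside map of chromosome {chrom}")
        return pos_bp * (self.cm_per_mb / 1e6)


@dataclass
class HaplotypeSet:
    """Phased marker haplotypes with truth layers.

    ``alleles[chrom]`` has shape (n_samples, 2, n_markers) over {0,1};
    ``origins[chrom]`` carries an integer founder-haplotype label per
    position (the truth layer for identity-by-descent); ``causal`` has shape
    (n_samples, 2) over {0,1} for the recessive allele at
    (causal_chrom, causal_pos).
    """

    sample_ids: list[str]
    gmap: GeneticMap
    alleles: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]
    causal_chrom: str
    causal_pos: int
    causal: np.ndarray

    def index_of(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample}") from None

    def causal_dosage(self, sample: str) -> int:
        return int(self.causal[self.index_of(sample)].sum())

    def subset(self, sample_ids: list[str]) -> "HaplotypeSet":
        idx = [self.index_of(s) for s in sample_ids]
        return HaplotypeSet(
            sample_ids=list(sample_ids),
            gmap=self.gmap,
            alleles={c: a[idx] for c, a in self.alleles.items()},
            origins={c: o[idx] for c, o in self.origins.items()},
            causal_chrom=self.causal_chrom,
            causal_pos=self.causal_pos,
            causal=self.causal[idx],
        )

    def truth_ibd_interval(self, case_ids: list[str]) -> tuple[str, int, int]:
        """Maximal contiguous marker run around the causal position over which
        every given case is homozygous for one single founder-origin label.

        This is the ground-truth autozygous segment that the mapping stage is
        expected to recover (as identity-by-state, hence possibly wider).
        """
        chrom = self.causal_chrom
        idx = [self.index_of(s) for s in case_ids]
        org = self.origins[chrom][idx]  # (n_cases, 2, n_markers)
        pos = self.gmap.positions_bp[chrom]
        jr = min(int(np.searchsorted(pos, self.causal_pos)), len(pos) - 1)
        candidates = [jr - 1, jr] if jr > 0 else [jr]
        j = ok = None
        for cand in candidates:  # flanking markers; recombination may separate
            ref_label = org[0, 0, cand]
            ok_c = (org == ref_label).all(axis=1).all(axis=0)  # all cases, both haps
            if ok_c[cand]:
                j, ok = cand, ok_c
                break
        if j is None:
            raise ValueError("cases are not IBD-homozygous at the causal position")
        lo = j
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        hi = j
        while hi < len(pos) - 1 and ok[hi + 1]:
            hi += 1
        return chrom, int(pos[lo]), int(pos[hi])


# --------------------------------------------------------------------------
# population construction
# --------------------------------------------------------------------------


def _make_genetic_map(config: SimConfig) -> GeneticMap:
    chroms = tuple(str(i + 1) for i in range(len(config.chromosome_lengths)))
    lengths = dict(zip(chroms, config.chromosome_lengths))
    positions = {
        c: np.arange(config.marker_spacing, lengths[c] + 1, config.marker_spacing, dtype=np.int64)
        for c in chroms
    }
    return GeneticMap(chroms=chroms, lengths_bp=lengths, positions_bp=positions,
                      cm_per_mb=config.cm_per_mb)


def _simulate_population(config: SimConfig, rng: np.random.Generator
                         ) -> tuple[Pedigree, HaplotypeSet]:
    """One population realization, built generation by generation.

    The founder carrier and his descendants are preferentially used as sires
    (popular-sire effect, emulating heavy artificial-insemination use of one
    bull line).  Affected individuals are perinatally lethal and never enter
    the breeding pool, so every parent of an affected animal is a carrier.
    """
    gmap = _make_genetic_map(config)
    ped = Pedigree()
    for k in range(config.n_founders):
        sex = "M" if k % 2 == 0 else "F"
        ped.add(Individual(id=f"G0_{k:03d}", sire=None, dam=None, sex=sex, generation=0))
    founder_descendant: set[str] = {"G0_000"}  # the (male) founder carrier

    # haplotype storage grows with the pedigree
    alleles: dict[str, list[np.ndarray]] = {c: [] for c in gmap.chroms}
    origins: dict[str, list[np.ndarray]] = {c: [] for c in gmap.chroms}
    causal_list: list[np.ndarray] = []
    index: dict[str, int] = {}
    causal_chrom = "1"
    causal_pos = 15_001_500  # inside the toy gene's span
    c_cm = np.array([causal_pos * (gmap.cm_per_mb / 1e6)])

    for k, f in enumerate(ped.founders()):
        index[f.id] = k
        for c in gmap.chroms:
            n = len(gmap.positions_bp[c])
            freqs = rng.uniform(0.1, 0.9, size=n)
            alleles[c].append((rng.random((2, n)) < freqs).astype(np.int8))
            origins[c].append(
                np.broadcast_to(
                    np.array([2 * k, 2 * k + 1], dtype=np.int32)[:, None], (2, n)
                ).copy()
            )
        cz = np.zeros(2, dtype=np.int8)
        if k == 0:
            cz[0] = 1  # single heterozygous founder carrier
        causal_list.append(cz)
        f.carrier_state = ("noncarrier", "carrier", "homozygous")[int(cz.sum())]
        f.phenotype = "affected" if cz.sum() == 2 else "unaffected"

    def make_gamete(parent_id: str) -> tuple[dict[str, tuple], int]:
        p = index[parent_id]
        out = {}
        causal_bit = 0
        for c in gmap.chroms:
            q_cm = gmap.positions_cm(c)
            if c == causal_chrom:
                q_cm = np.concatenate([q_cm, c_cm])
            phase = _gamete_phase(rng, gmap.length_cm(c), q_cm)
            if c == causal_chrom:
                causal_bit = int(causal_list[p][phase[-1]])
                phase = phase[:-1]
            rows = np.arange(len(phase))
            out[c] = (alleles[c][p][phase, rows], origins[c][p][phase, rows])
        return out, causal_bit

    prev = ped.founders()
    counter = 0
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if i.sex == "M" and i.phenotype != "affected"]
        dams = [i for i in prev if i.sex == "F" and i.phenotype != "affected"]
        if not males or not dams:
            break
        weights = np.array(
            [config.popular_sire_weight if m.id in founder_descendant else 1.0 for m in males]
        )
        weights = weights / weights.sum()
        cur: list[Individual] = []
        for dam in dams:
            n_off = rng.poisson(config.mean_offspring)
            for _ in range(n_off):
                sire = males[rng.choice(len(males), p=weights)]
                sex = "M" if rng.random() < 0.5 else "F"
                child = Individual(
                    id=f"G{g}_{counter:03d}", sire=sire.id, dam=dam.id, sex=sex, generation=g
                )
                counter += 1
                index[child.id] = len(causal_list)
                causal_pair = np.zeros(2, dtype=np.int8)
                gametes = []
                for h, parent in enumerate((sire.id, dam.id)):
                    gam, cbit = make_gamete(parent)
                    gametes.append(gam)
                    causal_pair[h] = cbit
                for c in gmap.chroms:
                    alleles[c].append(np.stack([gametes[0][c][0], gametes[1][c][0]]))
                    origins[c].append(np.stack([gametes[0][c][1], gametes[1][c][1]]))
                causal_list.append(causal_pair)
                d = int(causal_pair.sum())
                child.carrier_state = ("noncarrier", "carrier", "homozygous")[d]
                affected = d == 2 or (
                    config.phenocopy_rate > 0 and rng.random() < config.phenocopy_rate
                )
                child.phenotype = "affected" if affected else "unaffected"
                ped.add(child)
                cur.append(child)
                if sire.id in founder_descendant or dam.id in founder_descendant:
                    founder_descendant.add(child.id)
        prev = cur

    haps = HaplotypeSet(
        sample_ids=ped.ids(),
        gmap=gmap,
        alleles={c: np.stack(alleles[c]) for c in gmap.chroms},
        origins={c: np.stack(origins[c]) for c in gmap.chroms},
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        causal=np.stack(causal_list),
    )
    return ped, haps


def founder_haplotypes(config: SimConfig, gmap: GeneticMap, ped: Pedigree,
                       rng: np.random.Generator) -> HaplotypeSet:
    """Random founder haplotypes (per-marker allele frequencies uniform on
    [0.1, 0.9]) with unique origin labels and a single heterozygous founder
    carrier, for use with :func:`gene_drop` on a caller-supplied pedigree."""
    founders = ped.founders()
    ids = [f.id for f in founders]
    alleles: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    for c in gmap.chroms:
        n = len(gmap.positions_bp[c])
        freqs = rng.uniform(0.1, 0.9, size=n)
        alleles[c] = (rng.random((len(ids), 2, n)) < freqs).astype(np.int8)
        lab = np.arange(len(ids) * 2, dtype=np.int32).reshape(len(ids), 2)
        origins[c] = np.broadcast_to(lab[:, :, None], (len(ids), 2, n)).copy()
    causal_chrom = "1"
    causal_pos = 15_001_500  # inside the toy gene's span
    causal = np.zeros((len(ids), 2), dtype=np.int8)
    causal[0, 0] = 1  # single founder carrier, heterozygous
    return HaplotypeSet(
        sample_ids=ids,
        gmap=gmap,
        alleles=alleles,
        origins=origins,
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        causal=causal,
    )


def _gamete_phase(rng: np.random.Generator, length_cm: float,
                  query_cm: np.ndarray) -> np.ndarray:
    """Which parental haplotype (0/1) transmits at each query position.
    Crossover count is Poisson(length in Morgans); positions uniform on the
    cM axis (Haldane, no interference)."""
    k = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    start = int(rng.integers(0, 2))
    if k == 0:
        return np.full(query_cm.shape, start, dtype=np.int8)
    cuts = np.sort(rng.uniform(0.0, length_cm, size=k))
    return ((start + np.searchsorted(cuts, query_cm, side="right")) % 2).astype(np.int8)


def gene_drop(
    pedigree: Pedigree,
    gmap: GeneticMap,
    founder_haplotypes: HaplotypeSet,
    seed: int | np.random.Generator,
) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree.

    Each gamete is a crossover mosaic of the parent's two haplotypes; the
    marker alleles, the founder-origin truth labels, and the causal allele are
    all transmitted through the same crossover realization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for c in gmap.chroms:
        pos = gmap.positions_bp[c]
        fpos = founder_haplotypes.gmap.positions_bp.get(c)
        if fpos is None or pos.max(initial=0) > gmap.lengths_bp[c]:
            raise ValueError(f"marker outside genetic map on chromosome {c}")

    ids = pedigree.ids()
    index = {s: k for k, s in enumerate(ids)}
    alleles = {
        c: np.zeros((len(ids), 2, len(gmap.positions_bp[c])), dtype=np.int8) for c in gmap.chroms
    }
    origins = {
        c: np.zeros((len(ids), 2, len(gmap.positions_bp[c])), dtype=np.int32) for c in gmap.chroms
    }
    causal = np.zeros((len(ids), 2), dtype=np.int8)
    cc = founder_haplotypes.causal_chrom
    c_cm = np.array([founder_haplotypes.causal_pos * (gmap.cm_per_mb / 1e6)])

    for ind in pedigree:
        i = index[ind.id]
        if ind.is_founder:
            j = founder_haplotypes.index_of(ind.id)
            for c in gmap.chroms:
                alleles[c][i] = founder_haplotypes.alleles[c][j]
                origins[c][i] = founder_haplotypes.origins[c][j]
            causal[i] = founder_haplotypes.causal[j]
            continue
        for h, parent_id in enumerate((ind.sire, ind.dam)):
            p = index[parent_id]
            for c in gmap.chroms:
                q_cm = gmap.positions_cm(c)
                if c == cc:
                    # causal locus rides the same crossover realization
                    q_cm = np.concatenate([q_cm, c_cm])
                phase = _gamete_phase(rng, gmap.length_cm(c), q_cm)
                if c == cc:
                    causal[i, h] = causal[p, phase[-1]]
                    phase = phase[:-1]
                rows = np.arange(len(phase))
                alleles[c][i, h] = alleles[c][p, phase, rows]
                origins[c][i, h] = origins[c][p, phase, rows]

    return HaplotypeSet(
        sample_ids=ids,
        gmap=gmap,
        alleles=alleles,
        origins=origins,
        causal_chrom=cc,
        causal_pos=founder_haplotypes.causal_pos,
        causal=causal,
    )


def build_population(config: SimConfig, seed: int | None = None
                     ) -> tuple[Pedigree, HaplotypeSet]:
    """Simulate a pedigree + haplotypes with at least ``target_n_cases``
    affected individuals, by rejection-resampling whole populations.

    The founder carrier is heterozygous; under the full-penetrance recessive
    model every affected individual is causal-homozygous and therefore traces
    to that founder through both parents.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng([int(seed), attempt])
        ped, haps = _simulate_population(config, rng)
        if len(ped.affected_ids()) >= config.target_n_cases:
            return ped, haps
    raise QuotaError(
        f"could not reach target_n_cases={config.target_n_cases} affected "
        f"individuals in {config.max_attempts} attempts (seed {seed})"
    )


# --------------------------------------------------------------------------
# SNP-array genotypes
# --------------------------------------------------------------------------


def emit_array_genotypes(
    haps: HaplotypeSet,
    error_rate: float,
    seed: int,
    sample_ids: list[str] | None = None,
):
    """Collapse phased haplotypes to an array-style genotype matrix
    (0/1/2 alt-allele dosage), perturbing each call to a random *different*
    genotype with probability ``error_rate``.

    Returns a :class:`recmap.mapping.GenotypeMatrix`.
    """
    from .mapping import GenotypeMatrix

    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = list(haps.sample_ids)
    sub = haps.subset(sample_ids)
    marker_rows = []
    geno_cols = []
    base_pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for c in haps.gmap.chroms:
        g = sub.alleles[c].sum(axis=1).astype(np.int8)  # (n_samples, n_markers)
        pos = haps.gmap.positions_bp[c]
        pick = rng.integers(0, len(base_pairs), size=len(pos))
        for k, p in enumerate(pos):
            ref, alt = base_pairs[pick[k]]
            marker_rows.append((c, int(p), f"snp_{c}_{p}", ref, alt))
        geno_cols.append(g)
    genotypes = np.concatenate(geno_cols, axis=1)
    if error_rate > 0:
        flip = rng.random(genotypes.shape) < error_rate
        shift = rng.integers(1, 3, size=genotypes.shape)
        genotypes = np.where(flip, (genotypes + shift) % 3, genotypes).astype(np.int8)
    markers = pd.DataFrame(marker_rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(sample_ids=list(sample_ids), markers=markers, genotypes=genotypes)


# --------------------------------------------------------------------------
# WGS-like callset
# --------------------------------------------------------------------------


def emit_wgs_callset(
    haps: HaplotypeSet,
    gene: ToyGene,
    cluster: CausalCluster,
    config: SimConfig,
    seed: int,
    sample_ids: list[str] | None = None,
) -> tuple[list[VariantRecord], KnownCatalogue, pd.DataFrame]:
    """Emit a per-sample variant callset over the resequencing window.

    Variant classes
    ---------------
    cluster
        The three causal substitutions; genotype follows the causal dosage.
    linked_*
        Private variants riding on the disease haplotype (perfectly linked to
        the causal allele): intergenic, intronic, and synonymous-coding by
        configuration.  Never in the catalogue.
    background_common
        Breed-wide segregating variants; per-sample genotypes are independent
        Hardy-Weinberg draws at a random allele frequency.  Enters the
        catalogue with probability ``catalogue_fraction``.
    background_private
        Rare variants present as heterozygotes in a small random subset of
        samples; never in the catalogue.

    Returns (variants, catalogue, truth table).  The truth table records per
    variant its class, catalogue membership, and region annotation computed
    from the generator's own placement bookkeeping.
    """
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = list(haps.sample_ids)
    for p in cluster.genomic_positions:
        if not any(s <= p <= e for s, e in gene.exons):
            raise ValueError(f"cluster position {p} lies outside every exon")
    dosage = {s: haps.causal_dosage(s) for s in sample_ids}

    lo = max(1, min(cluster.genomic_positions) - config.wgs_halfwidth)
    hi = max(cluster.genomic_positions) + config.wgs_halfwidth
    span = gene.span
    region_len = hi - lo + 1
    taken = set(cluster.genomic_positions)

    def draw_position(predicate) -> int:
        for _ in range(10_000):
            p = int(rng.integers(lo, hi + 1))
            if p not in taken and predicate(p):
                taken.add(p)
                return p
        raise RuntimeError("could not place variant in region")

    def in_exon(p: int) -> bool:
        return any(s <= p <= e for s, e in gene.exons)

    def is_intronic(p: int) -> bool:
        return span[0] <= p <= span[1] and not in_exon(p)

    def is_intergenic(p: int) -> bool:
        return p < span[0] or p > span[1]

    bases = "ACGT"

    def random_alleles() -> tuple[str, str]:
        i = int(rng.integers(0, 4))
        j = (i + 1 + int(rng.integers(0, 3))) % 4
        return bases[i], bases[j]

    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []
    catalogue_keys: set[tuple[str, int, str, str]] = set()

    def add(chrom, pos, ref, alt, genotypes, kind, in_catalogue):
        variants.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                      genotypes=genotypes))
        truth_rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "kind": kind,
             "in_catalogue": in_catalogue}
        )
        if in_catalogue:
            catalogue_keys.add((chrom, pos, ref, alt))

    # 1. causal cluster — genotype equals causal dosage
    for p, r, a in zip(cluster.genomic_positions, cluster.ref_alleles, cluster.alt_alleles):
        add(cluster.chrom, p, r, a, {s: dosage[s] for s in sample_ids}, "cluster", False)

    # 2. linked private variants on the disease haplotype
    linked_plan = (
        [("linked_intergenic", is_intergenic)] * config.n_linked_intergenic
        + [("linked_intronic", is_intronic)] * config.n_linked_intronic
    )
    for kind, pred in linked_plan:
        p = draw_position(pred)
        ref, alt = random_alleles()
        add(gene.chrom, p, ref, alt, {s: dosage[s] for s in sample_ids}, kind, False)
    for _ in range(config.n_linked_synonymous):
        cpos, ref, alt = _synonymous_site(gene, rng, exclude=set(cluster.cds_positions))
        p = gene.cds_to_genomic(cpos)
        if p in taken:
            continue
        taken.add(p)
        if gene.strand == "-":
            ref, alt = str(Seq(ref).complement()), str(Seq(alt).complement())
        add(gene.chrom, p, ref, alt, {s: dosage[s] for s in sample_ids},
            "linked_synonymous", False)

    # 3. background variation
    n_background = int(rng.poisson(config.background_variant_density * region_len / 1000.0))
    for _ in range(n_background):
        p = draw_position(lambda _p: True)
        ref, alt = random_alleles()
        if rng.random() < config.common_fraction:
            af = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, af, size=len(sample_ids)).astype(int)
            genotypes = dict(zip(sample_ids, (int(x) for x in g)))
            in_cat = bool(rng.random() < config.catalogue_fraction)
            add(gene.chrom, p, ref, alt, genotypes, "background_common", in_cat)
        else:
            k = int(rng.integers(1, min(3, len(sample_ids)) + 1))
            who = rng.choice(len(sample_ids), size=k, replace=False)
            genotypes = {s: 0 for s in sample_ids}
            for w in who:
                genotypes[sample_ids[int(w)]] = 1
            add(gene.chrom, p, ref, alt, genotypes, "background_private", False)

    order = np.lexsort(([v.pos for v in variants], [v.chrom for v in variants]))
    variants = [variants[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return variants, KnownCatalogue(frozenset(catalogue_keys)), truth


def _synonymous_site(gene: ToyGene, rng: np.random.Generator,
                     exclude: set[int]) -> tuple[int, str, str]:
    """Find a CDS position + substitution that leaves the protein unchanged."""
    n = gene.n_codons
    for _ in range(1000):
        ci = int(rng.integers(2, n))  # skip start and stop codons
        codon = gene.cds_sequence[3 * (ci - 1) : 3 * ci]
        off = int(rng.integers(0, 3))
        cpos = 3 * (ci - 1) + off + 1
        if cpos in exclude:
            continue
        ref = codon[off]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutated = codon[:off] + alt + codon[off + 1 :]
            if str(Seq(mutated).translate()) == str(Seq(codon).translate()):
                return cpos, ref, alt
    raise RuntimeError("no synonymous site found")


# --------------------------------------------------------------------------
# voltage-clamp traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of the simulated two-electrode voltage-clamp experiment.

    During a test pulse at voltage V the current is

        I(t) = A(V) * [f + (1 - f) * (1 - exp(-t / tau_act))] + noise

    with instantaneous fraction ``f``; the deactivation segment relaxes
    single-exponentially with ``tau_deact`` toward A(V_deact).  The amplitude
    A(V) is a sigmoid-gated driving force producing outward rectification:

        A(V) = conductance_scale * (V - reversal_potential)
               / (1 + exp(-(V - rectification_midpoint) / rectification_slope))

    (a phenomenological shape chosen to yield outwardly rectifying traces; it
    is not itself a fitting target).  Set ``rectification_slope`` to ``None``
    for a purely ohmic amplitude.
    """

    protocol: ClampProtocol = field(default_factory=ClampProtocol)
    tau_act: float = 341.0  # ms
    tau_deact: float = 300.0  # ms
    instantaneous_fraction: float = 0.1
    conductance_scale: float = 0.05  # uA per mV
    # just below the most negative test pulse: keeps A(V) >= 0 and
    # monotonically increasing over the whole protocol (outward rectification)
    reversal_potential: float = -90.0  # mV
    rectification_midpoint: float | None = 20.0  # mV
    rectification_slope: float | None = 25.0  # mV
    noise_sd: float = 0.0  # uA
    sampling_interval: float = 1.0  # ms (1 kHz acquisition)

    def validate(self) -> None:
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.instantaneous_fraction <= 1.0:
            raise ValueError("instantaneous_fraction must be in [0, 1]")

    def amplitude(self, v: float) -> float:
        drive = self.conductance_scale * (v - self.reversal_potential)
        if self.rectification_slope is None or self.rectification_midpoint is None:
            return drive
        gate = 1.0 / (1.0 + np.exp(-(v - self.rectification_midpoint) / self.rectification_slope))
        return drive * gate


def default_trace_spec(**overrides) -> TraceSimSpec:
    return replace(TraceSimSpec(), **overrides)


def simulate_traces(spec: TraceSimSpec, n_traces: int, seed: int) -> list[CurrentTrace]:
    """Simulate ``n_traces`` independent voltage-clamp recordings."""
    spec.validate()
    rng = np.random.default_rng(seed)
    proto = spec.protocol
    dt = spec.sampling_interval
    t = np.arange(0.0, proto.test_duration_ms + dt / 2, dt)
    t_d = np.arange(0.0, proto.deact_duration_ms + dt / 2, dt)
    f = spec.instantaneous_fraction
    traces = []
    for _ in range(n_traces):
        currents: dict[float, np.ndarray] = {}
        deact: dict[float, np.ndarray] = {}
        for v in proto.test_voltages:
            a = spec.amplitude(v)
            gating = f + (1.0 - f) * (1.0 - np.exp(-t / spec.tau_act))
            i_test = a * gating
            if spec.noise_sd > 0:
                i_test = i_test + rng.normal(0.0, spec.noise_sd, size=i_test.shape)
            currents[v] = i_test
            a_d = spec.amplitude(proto.deact_voltage)
            g_end = gating[-1]
            i_d = a_d + (a_d * g_end - a_d) * np.exp(-t_d / spec.tau_deact)
            if spec.noise_sd > 0:
                i_d = i_d + rng.normal(0.0, spec.noise_sd, size=i_d.shape)
            deact[v] = i_d
        traces.append(
            CurrentTrace(
                protocol=proto,
                time_ms=t.copy(),
                currents=currents,
                deact_time_ms=t_d.copy(),
                deact_currents=deact,
            )
        )
    return traces
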