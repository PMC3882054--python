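"""Autozygosity mapping: shared-homozygosity intervals and a haplotype
window association scan.

The locus of a fully penetrant recessive disease in an inbred population is
expected to lie inside the maximal genomic segment over which every affected
individual is homozygous and identical by state (a proxy for identity by
descent from the shared carrier ancestor).  Two complementary views are
implemented:

* :func:`shared_homozygosity_segments` — exact detection of maximal runs of
  markers at which all cases are homozygous for the same allele;
* :func:`haplotype_window_scan` — a genome-wide case/control scan on phased
  haplotypes: per window, a Pearson chi-square on the contingency table of
  distinct window-haplotype strings (two chromosomes per individual) against
  phenotype.  This is a deliberately simple association statistic for
  simulated, stratification-free cohorts; it is not a mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeMatrix:
    """Samples × markers genotype codes with genomic coordinates.

    ``markers`` columns: chrom, pos (1-based bp), id, ref, alt, sorted by
    chromosome then position.  ``genotypes``: int8 array (n_samples,
    n_markers) over {0,1,2} alt-allele dosage; -1 is missing.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        m = self.markers
        for chrom, grp in m.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"markers unsorted on chromosome {chrom}")

    def index_of(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive chromosome span covering ``n_markers`` concordant
    markers."""

    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


def interval_length_mb(interval: GenomicInterval) -> float:
    """Interval length in Mb: (end - start) / 1e6 rounded to 2 decimals.

    The end-minus-start convention matches how mapping intervals are usually
    quoted from their outermost marker coordinates.
    """
    return round((interval.end_bp - interval.start_bp) / 1e6, 2)


def concordant_homozygous_markers(
    genotypes: np.ndarray, max_missing_per_marker: int = 0,
    max_mismatch_per_marker: int = 0,
) -> np.ndarray:
    """Boolean mask over markers: the non-missing case genotypes are
    homozygous for one shared allele, with at most ``max_missing_per_marker``
    missing calls and at most ``max_mismatch_per_marker`` calls deviating
    from the modal homozygous genotype (an allowance for genotyping errors;
    0 demands perfect concordance)."""
    g = genotypes
    missing = g == -1
    n_missing = missing.sum(axis=0)
    n_nonmissing = (~missing).sum(axis=0)
    n_homref = (g == 0).sum(axis=0)
    n_homalt = (g == 2).sum(axis=0)
    modal = np.maximum(n_homref, n_homalt)
    deviants = n_nonmissing - modal
    return (
        (modal >= 1)
        & (deviants <= max_mismatch_per_marker)
        & (n_missing <= max_missing_per_marker)
    )


def shared_homozygosity_segments(
    genotypes: GenotypeMatrix,
    case_ids: list[str],
    max_missing_per_marker: int = 0,
    min_markers: int = 10,
    max_mismatch_per_marker: int = 0,
) -> list[GenomicInterval]:
    """Maximal runs of consecutive markers at which all cases are homozygous
    identical-by-state, per chromosome, keeping runs of >= ``min_markers``.

    Interval bounds are the outermost concordant marker coordinates.
    ``max_mismatch_per_marker`` > 0 tolerates isolated discordant calls
    (genotyping errors) without splitting a run.
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    rows = [genotypes.index_of(s) for s in case_ids]
    if not rows:
        raise ValueError("case_ids must be non-empty")
    intervals: list[GenomicInterval] = []
    m = genotypes.markers.reset_index(drop=True)
    for chrom in genotypes.chromosomes():
        cols = np.flatnonzero((m["chrom"] == chrom).to_numpy())
        sub = genotypes.genotypes[np.ix_(rows, cols)]
        mask = concordant_homozygous_markers(sub, max_missing_per_marker,
                                             max_mismatch_per_marker)
        pos = m.loc[cols, "pos"].to_numpy()
        # maximal runs of True
        padded = np.concatenate([[False], mask, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            n = e - s
            if n >= min_markers:
                intervals.append(
                    GenomicInterval(
                        chrom=str(chrom),
                        start_bp=int(pos[s]),
                        end_bp=int(pos[e - 1]),
                        n_markers=int(n),
                    )
                )
    return intervals


# --------------------------------------------------------------------------
# window haplotype scan
# --------------------------------------------------------------------------


@dataclass
class ScanResult:
    table: pd.DataFrame  # window_id, chrom, start_bp, end_bp, mid_bp, statistic, df, p, neg_log10_p

    def min_p_row(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]


def _window_chi_square(
    hap_strings: list[bytes], affected: np.ndarray, min_hap_count: int
) -> tuple[float, int, float]:
    """Pearson chi-square of distinct window-haplotype counts vs phenotype.

    Haplotypes seen fewer than ``min_hap_count`` times overall are pooled
    into a single rare class.  df = (number of classes - 1).
    """
    counts: dict[bytes, int] = {}
    for h in hap_strings:
        counts[h] = counts.get(h, 0) + 1
    keep = {h for h, n in counts.items() if n >= min_hap_count}
    classes = {h: (h if h in keep else b"__rare__") for h in counts}
    labels = sorted(set(classes.values()))
    if len(labels) < 2:
        return 0.0, 0, 1.0
    lab_idx = {h: i for i, h in enumerate(labels)}
    tab = np.zeros((len(labels), 2))
    for h, aff in zip(hap_strings, affected):
        tab[lab_idx[classes[h]], int(aff)] += 1
    # drop empty rows (possible after pooling) and require both phenotype cols
    tab = tab[tab.sum(axis=1) > 0]
    if tab.shape[0] < 2 or (tab.sum(axis=0) == 0).any():
        return 0.0, 0, 1.0
    stat, _, df, _ = stats.chi2_contingency(tab, correction=False)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), min(max(p, np.nextafter(0, 1)), 1.0)


def haplotype_window_scan(
    haplotypes,
    labels: dict[str, bool],
    window_size: int = 4,
    step: int = 2,
    min_hap_count: int = 2,
) -> ScanResult:
    """Sliding-window haplotype association scan on phased haplotypes.

    ``haplotypes`` is a :class:`recmap.simulate.HaplotypeSet`; ``labels``
    maps sample id -> affected flag (both classes must be represented).
    Each individual contributes two chromosomes per window.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    samples = [s for s in haplotypes.sample_ids if s in labels]
    affected_flags = np.array([bool(labels[s]) for s in samples])
    if affected_flags.all() or not affected_flags.any():
        raise ValueError("both phenotype classes must be non-empty")
    idx = [haplotypes.index_of(s) for s in samples]
    aff2 = np.repeat(affected_flags, 2)

    rows = []
    wid = 0
    for chrom in haplotypes.gmap.chroms:
        alleles = haplotypes.alleles[chrom][idx]  # (n, 2, n_markers)
        pos = haplotypes.gmap.positions_bp[chrom]
        n_markers = alleles.shape[2]
        flat = alleles.reshape(-1, n_markers)  # 2 rows per individual
        for start in range(0, max(n_markers - window_size + 1, 1), step):
            stop = min(start + window_size, n_markers)
            window = flat[:, start:stop]
            hap_strings = [w.tobytes() for w in window]
            stat, df, p = _window_chi_square(hap_strings, aff2, min_hap_count)
            rows.append(
                {
                    "window_id": wid,
                    "chrom": chrom,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[stop - 1]),
                    "mid_bp": int((pos[start] + pos[stop - 1]) // 2),
                    "statistic": stat,
                    "df": df,
                    "p": p,
                    "neg_log10_p": float(-np.log10(p)),
                }
            )
            wid += 1
            if stop == n_markers:
                break
    return ScanResult(table=pd.DataFrame(rows))


def manhattan_table(scan: ScanResult) -> pd.DataFrame:
    """Serializable Manhattan-plot table: one row per window midpoint in
    genome order."""
    if scan.table.empty:
        raise ValueError("empty scan result")
    return scan.table[["chrom", "mid_bp", "neg_log10_p"]].rename(
        columns={"mid_bp": "position"}
    ).reset_index(drop=True)


def write_manhattan_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_manhattan_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_intervals_bed(intervals: list[GenomicInterval], path) -> None:
    """BED is 0-based half-open: start_bp-1, end_bp."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.n_markers}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, n = line.split()
            out.append(
                GenomicInterval(chrom=chrom, start_bp=int(start) + 1, end_bp=int(end),
                                n_markers=int(n))
            )
    return out
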