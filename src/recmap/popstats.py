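"""Genotype-level population statistics: Hardy-Weinberg tests, allele and
carrier frequencies, and recessive-segregation checking.

A lethal recessive allele segregating in a livestock population shows a
characteristic deficit of mutant homozygotes among healthy controls: with
q the alt-allele frequency, the expected N*q^2 homozygotes are missing.  The
default Hardy-Weinberg test is the Pearson chi-square over the three
genotype classes with 1 degree of freedom and no continuity correction;
Yates-corrected and exact (full enumeration) variants are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log, exp

import pandas as pd
from scipy import stats

from .simulate import Pedigree


@dataclass(frozen=True)
class GenotypeCounts:
    n_homref: int
    n_het: int
    n_homalt: int

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homalt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt

    @property
    def alt_frequency(self) -> float:
        if self.total == 0:
            raise ValueError("no genotypes")
        return (self.n_het + 2 * self.n_homalt) / (2 * self.total)

    def swapped(self) -> "GenotypeCounts":
        return GenotypeCounts(self.n_homalt, self.n_het, self.n_homref)


@dataclass(frozen=True)
class HweResult:
    statistic: float | None
    p_value: float
    method: str
    expected: tuple[float, float, float] | None = None


def hwe_chi_square(counts: GenotypeCounts, method: str = "pearson") -> HweResult:
    """Test the genotype counts against Hardy-Weinberg proportions at the
    observed allele frequency.

    methods: ``pearson`` (default; chi-square, df=1, no continuity
    correction), ``yates`` (continuity-corrected chi-square), ``exact``
    (exact enumeration of heterozygote counts conditional on allele counts).
    If only one allele is observed the test is vacuous: p = 1.
    """
    if counts.total == 0:
        raise ValueError("no genotypes to test")
    q = counts.alt_frequency
    if q == 0.0 or q == 1.0:
        return HweResult(statistic=0.0, p_value=1.0, method=method)
    if method == "exact":
        return HweResult(statistic=None, p_value=hwe_exact_p(counts), method=method)
    n = counts.total
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)
    observed = (counts.n_homref, counts.n_het, counts.n_homalt)
    if method == "pearson":
        stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    elif method == "yates":
        stat = sum((abs(o - e) - 0.5) ** 2 / e for o, e in zip(observed, expected))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(stat, df=1))
    return HweResult(statistic=float(stat), p_value=p, method=method, expected=expected)


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg p-value: sum of probabilities of all heterozygote
    counts (conditional on the observed allele counts) no more probable than
    the observed one."""
    n = counts.total
    n_alt = counts.n_het + 2 * counts.n_homalt
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    obs_het = counts.n_het

    def log_prob(het: int) -> float:
        homr = (rare - het) // 2
        homc = n - het - homr
        return (
            log(2.0) * het
            + lgamma(n + 1)
            - lgamma(het + 1)
            - lgamma(homr + 1)
            - lgamma(homc + 1)
            - (lgamma(2 * n + 1) - lgamma(rare + 1) - lgamma(2 * n - rare + 1))
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    m = max(logs.values())
    probs = {h: exp(lp - m) for h, lp in logs.items()}
    z = sum(probs.values())
    p_obs = probs[obs_het] / z
    return min(1.0, sum(p / z for p in probs.values() if p / z <= p_obs * (1 + 1e-12)))


def allele_frequency_percent(counts: GenotypeCounts) -> tuple[float, str]:
    """Alt-allele frequency as a percentage, plus a nearest-integer
    rendering like ``"5%"``."""
    if counts.total == 0:
        raise ValueError("no genotypes")
    pct = 100.0 * counts.alt_frequency
    return pct, f"{int(round(pct))}%"


# --------------------------------------------------------------------------
# segregation checking
# --------------------------------------------------------------------------


@dataclass
class SegregationReport:
    affected_not_homozygous: list[str] = field(default_factory=list)
    parent_of_affected_not_carrier: list[str] = field(default_factory=list)
    unaffected_homozygote: list[str] = field(default_factory=list)
    external_alt_carrier: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (
            self.affected_not_homozygous
            or self.parent_of_affected_not_carrier
            or self.unaffected_homozygote
            or self.external_alt_carrier
        )

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "affected_not_homozygous": self.affected_not_homozygous,
            "parent_of_affected_not_carrier": self.parent_of_affected_not_carrier,
            "unaffected_homozygote": self.unaffected_homozygote,
            "external_alt_carrier": self.external_alt_carrier,
        }


def check_recessive_segregation(
    pedigree: Pedigree,
    genotypes: dict[str, int],
    external_ids: set[str] | None = None,
) -> SegregationReport:
    """Verify genotypes at the candidate variant against the fully penetrant
    recessive model:

    * every affected individual must be homozygous-alt;
    * every genotyped parent of an affected must be heterozygous;
    * no unaffected pedigree member or control may be homozygous-alt;
    * samples outside the pedigree (``external_ids``) must carry no alt
      allele at all.
    """
    external_ids = external_ids or set()
    report = SegregationReport()
    ped_ids = set(pedigree.ids())
    for iid in genotypes:
        if iid not in ped_ids and iid not in external_ids:
            raise KeyError(f"genotyped id {iid!r} neither in pedigree nor marked external")

    affected = [i for i in pedigree if i.phenotype == "affected"]
    affected_parents = set()
    for ind in affected:
        for parent in (ind.sire, ind.dam):
            if parent is not None:
                affected_parents.add(parent)
        g = genotypes.get(ind.id)
        if g is not None and g != 2:
            report.affected_not_homozygous.append(ind.id)
    for pid in sorted(affected_parents):
        g = genotypes.get(pid)
        if g is not None and g != 1:
            report.parent_of_affected_not_carrier.append(pid)
    for ind in pedigree:
        if ind.phenotype == "unaffected":
            g = genotypes.get(ind.id)
            if g == 2:
                report.unaffected_homozygote.append(ind.id)
    for iid in sorted(external_ids):
        g = genotypes.get(iid)
        if g is not None and g in (1, 2):
            report.external_alt_carrier.append(iid)
    return report


def carrier_frequency_by_group(
    genotype_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group carrier/allele frequency table.

    ``genotype_table`` columns: sample, group, genotype (0/1/2).  Returns one
    row per group plus a totals row with columns n, carriers, homalt,
    carrier_pct, allele_pct.
    """
    required = {"sample", "group", "genotype"}
    if not required.issubset(genotype_table.columns):
        raise ValueError(f"genotype table must have columns {sorted(required)}")
    if genotype_table["group"].isna().any() or (genotype_table["group"] == "").any():
        raise ValueError("empty group label")
    rows = []
    for group, grp in genotype_table.groupby("group", sort=True):
        g = grp["genotype"].to_numpy()
        n = len(g)
        het = int((g == 1).sum())
        hom = int((g == 2).sum())
        rows.append(
            {
                "group": group,
                "n": n,
                "carriers": het,
                "homalt": hom,
                "carrier_pct": 100.0 * het / n,
                "allele_pct": 100.0 * (het + 2 * hom) / (2 * n),
            }
        )
    g = genotype_table["genotype"].to_numpy()
    n = len(g)
    het = int((g == 1).sum())
    hom = int((g == 2).sum())
    rows.append(
        {
            "group": "TOTAL",
            "n": n,
            "carriers": het,
            "homalt": hom,
            "carrier_pct": 100.0 * het / n,
            "allele_pct": 100.0 * (het + 2 * hom) / (2 * n),
        }
    )
    return pd.DataFrame(rows)
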