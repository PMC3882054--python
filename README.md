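# recmap

Recessive-disease gene discovery at desk scale: a tested, reusable Python
implementation of the analysis by which a lethal recessive defect is mapped
and resolved in a closed livestock population, exercised end-to-end on a
synthetic cohort generator with known ground truth.

The package is aimed at people building or teaching positional-cloning
pipelines — autozygosity mapping, variant filtering, consequence annotation —
and at anyone who needs a self-contained, seedable cohort simulator to
validate such code against planted truth.

## What it implements

1. **Cohort simulator** (`recmap.simulate`) — a pedigree descending from a
   single founder carrier of a recessive allele, bred with a popular-sire
   bias; phased marker haplotypes propagated by gene drop (Poisson
   crossovers, Haldane map, no interference) with exact identity-by-descent
   truth labels; SNP-array genotype matrices with genotyping error; a
   WGS-like callset over a ~1.15-Mb window around a toy gene, containing a
   planted cluster of three substitutions within 7 bp of one exon plus
   linked and background variation; and two-electrode voltage-clamp current
   traces with single-exponential gating.

2. **Autozygosity mapping** (`recmap.mapping`) — exact maximal runs of
   markers at which every affected animal is homozygous and identical by
   state (the signature of autozygosity for a shared ancestral haplotype),
   plus a sliding-window haplotype association scan. The scan statistic per
   window is Pearson's chi-square on the table of distinct window-haplotype
   strings × phenotype, with rare haplotypes pooled:

       X² = Σ (O − E)² / E,  df = (#haplotype classes − 1)

3. **Variant prioritization** (`recmap.prioritize`) — two cascades:
   *Cascade A*: drop variants seen in controls or in a known-variants
   catalogue, keep those homozygous in all cases, then transcribed → ORF →
   amino-acid-changing. *Cascade B*: keep variants homozygous-alt in all
   cases, heterozygous in all obligate carriers, absent from all
   non-carriers, with region and coding breakdowns. Consequence annotation
   is **MNV-aware**: all substitutions sharing a codon are applied jointly
   before translation — c.2248T>C and c.2250C>A together turn TAC into CAA
   (p.Tyr750Gln), whereas c.2250C>A alone would be miscalled as a nonsense
   change (TAC→TAA).

4. **Genotype statistics** (`recmap.popstats`) — Hardy–Weinberg test
   (Pearson χ², df = 1, no continuity correction, with Yates and exact
   variants), allele/carrier frequencies, and full recessive-segregation
   checking against a pedigree. With q̂ the observed alt frequency and N the
   cohort size, expected genotype counts are N(1−q̂)², 2Nq̂(1−q̂), Nq̂².

5. **Voltage-clamp kinetics** (`recmap.kinetics`) — mono-exponential fits
   I(t) = I_ss − ΔI·e^(−t/τ) of current activation (first 250 ms at +80 mV
   by default) and deactivation, normalized current–voltage curves, and
   two-sample t-test comparison of fitted time constants between groups.

6. **Pipeline + CLI** (`recmap.pipeline`, `recmap.cli`) — `recmap all
   --seed 1 --out run/` executes simulate → map → prioritize → stats →
   kinetics from one YAML config, writing VCF, PED/MAP, GFF3, FASTA, BED,
   TSV and a consolidated JSON report. Identical config + seed reproduce
   every output byte-for-byte.

See `docs/methods.md` for the models, parameter meanings and design choices.

## Worked example

```sh
recmap all --seed 1 --out run1
```

or equivalently in Python:

```python
from recmap.pipeline import RunConfig, run_all
report = run_all(RunConfig(seed=1, out_dir="run1"))
```

With seed 1 this simulates a five-generation herd (892 animals, six of them
affected calves), and
the report (`run1/run_report.json`) contains, among others:

* **Mapping** — the shared-homozygosity interval containing the planted
  locus: `chr1:8,730,000–15,150,000` (6.42 Mb), and the window-scan minimum
  p = 1.08×10⁻¹⁵ inside it. Fewer cases than a full field study means a
  wider interval; the truth labels confirm it covers the planted gene.
* **Cascade A** — 2184 callset variants; 1995 (91 %) removed as known or
  seen in controls; 189 remaining, of which 15 homozygous in all cases,
  4 in the ORF and 2 amino-acid-changing — the two members of the planted
  codon-750 multi-nucleotide variant.
* **Cascade B** — 15 survivors: 8 intergenic, 3 intronic, 4 coding
  (2 synonymous, 2 non-synonymous); the unique non-synonymous consequence
  is `Y750Q` (`p.Tyr750Gln`, TAC>CAA, missense).
* **Statistics** — segregation check passes (all cases homozygous, all
  parents of cases carriers); among 886 unaffected animals
  (709/177/0 genotype counts) the absence of mutant homozygotes gives
  HWE χ² = 10.9, p = 9.6×10⁻⁴.
* **Kinetics** — fitted activation time constants 344 ± 7 ms vs
  106 ± 1 ms (mean ± s.e.m.), fold acceleration 3.25, t-test p < 10⁻¹⁵.

Every number above is recomputed, not stored: rerunning the command
reproduces the report exactly, and a different seed gives a different
population with the same qualitative outcome.

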