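# Methods

`recmap` re-implements, as a tested pipeline on synthetic cohorts, the
analysis pattern by which a lethal recessive defect is mapped and resolved in
a closed livestock population: autozygosity mapping from medium-density SNP
genotypes, private-variant prioritization from whole-genome callsets,
codon-level consequence annotation that handles multi-nucleotide variants
(MNVs) jointly, Hardy–Weinberg and segregation statistics, and
voltage-clamp gating-kinetics analysis of the candidate channel mutation.
This note records the models, the parameters that matter, and the choices
made where the design was genuinely open.

## Population simulator

**Model.** A closed herd of `n_founders = 40` unrelated founders (alternating
sexes) is bred for `n_generations = 5`. Exactly one founder — a male — is a
heterozygous carrier of the recessive allele. Sires are drawn per offspring
with a popular-sire weight (`popular_sire_weight = 10`) favouring the carrier
founder and his descendants, emulating the heavy artificial-insemination use
of one bull line that drives recessive outbursts in closed beef breeds. Each
dam of the previous generation produces Poisson(`mean_offspring = 3.0`)
calves. The disease model is fully penetrant recessive with perinatal
lethality: affected ⇔ causal-homozygous, and affected animals never enter
the breeding pool (hence every parent of a case is an obligate carrier).
A phenocopy rate is configurable and defaults to 0. Populations are
rejection-resampled (bounded at 40 attempts) until at least
`target_n_cases = 6` affected individuals exist; with the defaults the
median realization has ~12 cases, so the quota is nearly always met on the
first attempt.

Five generations of depth was chosen to match the scale of a founder a few
decades back at cattle generation intervals; it yields all-case shared
autozygous segments on the megabase scale, the same order as real mapping
studies in such populations, with an occasional short-segment tail when a
realization accumulates unusually many informative meioses.

**Genome and gene drop.** Three 30-Mb chromosomes with one biallelic marker
per 30 kb (a desk-scale stand-in for a bovine 50K array) and a linear genetic
map at 1 cM/Mb. Meioses follow the Haldane model: crossover counts are
Poisson with mean equal to the map length in Morgans, positions uniform on
the cM axis, no interference. Founder marker alleles are Bernoulli draws at
per-marker frequencies uniform on [0.1, 0.9]. Two truth layers ride the same
crossover realizations as the marker alleles: per-position founder-origin
labels (so identity-by-descent is known exactly) and the causal allele at a
fixed locus inside the toy gene. All randomness flows from explicit seeds;
identical config + seed reproduce outputs byte-for-byte.

**Array genotypes.** Genotype = sum of the two haplotype alleles; each call
is perturbed to a uniformly random *different* genotype with probability
`genotyping_error_rate = 0.001` (ordinary array error rates). Output as
multi-sample VCF v4.2 (GT only) and a PED/MAP pair; both round-trip through
the package's readers (PED/MAP needs the ref/alt sidecar, since PLINK text
does not carry allele roles).

**WGS-like callset.** The resequencing window spans ±575 kb around the
planted cluster (~1.15 Mb, the scale of a mapped autozygous interval).
Variant classes:

* *cluster* — three substitutions within 7 bp of one exon, at CDS positions
  2244 (G>C), 2248 (T>C) and 2250 (C>A); per-sample genotype equals the
  causal dosage.
* *linked* — private variants riding the disease haplotype (genotype =
  causal dosage): 8 intergenic, 3 intronic and 1 synonymous-coding by
  default, so the segregation cascade retains a realistic handful of
  survivors besides the causal group.
* *background* — Poisson(`1.9/kb` × window) variants at uniform positions;
  a `common_fraction = 0.85` of them segregate breed-wide (independent
  Hardy–Weinberg genotypes at a frequency uniform on [0.05, 0.5]) and enter
  the known-variants catalogue with probability `catalogue_fraction = 0.6`;
  the rest are rare, present as heterozygotes in 1–3 random samples.
  The catalogue never contains the cluster or the linked variants.

The sharing structure among cohorts is a free design parameter of the
generator, exposed in `SimConfig` rather than inferred from anything.

**What the generator does not emulate.** No read-level errors or missing
genotype calls in the WGS layer, no population demography beyond the pedigree
(no migration, no mutation, no background relatedness among founders), no
linkage disequilibrium in the founder haplotypes, and no confounding
population stratification. Passing tests therefore demonstrate correctness of
the analysis logic under the stated inheritance model, not robustness to the
full messiness of real callsets.

## Autozygosity mapping

**Shared-homozygosity intervals.** Per chromosome, a marker is *concordant*
when the non-missing case genotypes are homozygous for one shared allele,
with at most `max_missing_per_marker` (default 0) missing calls and at most
`max_mismatch_per_marker` (default 0) calls deviating from the modal
homozygous genotype. Maximal runs of ≥ `min_markers` (default 10) concordant
markers are reported with bounds at the outermost concordant markers —
matching how such intervals are quoted from marker coordinates — and interval
length is (end − start)/10⁶ Mb rounded to two decimals. The mismatch knob
exists because a single genotyping error otherwise splits a run; the
pipeline's default analysis setting tolerates ⌊0.1·n_cases⌋ discordant calls
per marker — the programmatic analogue of the visual curation a human
analyst applies to raw array genotypes, scaled so that one bad call among
thirty cases is forgiven but one among six is not. An exact brute-force enumeration serves as
the test oracle, and concordance is provably monotone: adding a case can
only shrink the concordant marker set.

**Window haplotype scan.** A deliberately simple case/control statistic on
phased haplotypes (the simulator's output is phased by construction): per
sliding window (default 4 markers, step 2), the contingency table of distinct
window-haplotype strings × phenotype over chromosomes (two per individual) is
tested with Pearson's chi-square, df = (classes − 1), haplotypes seen fewer
than `min_hap_count = 2` times pooled into one rare class. This replaces the
mixed-model machinery a real study uses to absorb population stratification —
the simulator generates none — while preserving the mapping deliverable: a
genome-wide peak over the planted interval. Type-I error is checked by label
permutation (empirical fraction of p < 0.05 within [0.03, 0.07]).

## Variant prioritization

**Cascade A** (cases vs. unrelated controls + catalogue): remove variants
whose alt allele appears in any control (het or hom — "non-private") or that
are already catalogued; keep variants homozygous-alt in every case (stated
explicitly here; a real study applies it implicitly through the autozygous
interval); narrow to transcribed positions (exonic: UTR or CDS — introns do
not count), then to the ORF, then to amino-acid-changing variants. The
removal percentage at step 1 is rounded to the nearest integer. Counts
telescope by construction.

**Cascade B** (cases + obligate carriers + non-carriers): a survivor must be
hom-alt in all cases, het in all carriers, and alt-free in all non-carriers.
Missing genotypes: a missing call cannot certify a universally quantified
criterion, so it disqualifies for the case/carrier criteria by default,
while a missing non-carrier call counts as absence (both configurable).
Survivors are broken down into intergenic / intronic / exonic-noncoding /
coding, and coding survivors split synonymous vs. non-synonymous.

**MNV-aware annotation.** Coding substitutions are grouped by codon index
(⌊(pos−1)/3⌋+1); all substitutions in a codon are applied *jointly* before
translating with the standard genetic code. This matters: of the planted
cluster, c.2250C>A alone converts TAC to the stop TAA (a nonsense call),
whereas the joint c.2248T>C + c.2250C>A event gives CAA — a missense
Tyr→Gln. Consequences are classified synonymous / missense / nonsense /
stop-loss and labelled in c.-dot and p.-dot style plus a short form
(e.g. `Y750Q`). Annotation is strand-invariant (minus-strand genes complement
the alleles and mirror the coordinates first), and indels pass through the
filters by (pos, ref, alt) identity but are excluded from codon annotation.

## Genotype statistics

The Hardy–Weinberg test is Pearson's chi-square over the three genotype
classes against expectations at the observed allele frequency, df = 1, no
continuity correction — the form under which a deficit of mutant homozygotes
among 6489 controls (5845/644/0) gives χ² ≈ 17.7, p ≈ 2.6×10⁻⁵. A
Yates-corrected and an exact test (full enumeration of heterozygote counts
conditional on allele counts) are provided as options; they give materially
different p-values on the same counts, which is why the default is stated
explicitly. Allele frequency is reported as a percentage with a
nearest-integer rendering (644 carriers among 6489 → 4.96 % → "5 %").
Segregation checking flags affected non-homozygotes, genotyped parents of
affected that are not carriers, unaffected homozygotes, and any alt allele in
cohort-external samples.

## Voltage-clamp kinetics

**Protocol.** Holding −30 mV; 2-s test pulses from −80 to +80 mV in 20-mV
steps, each followed by a 0.5-s deactivation pulse at −80 mV; 1-kHz
sampling.

**Trace model.** During a test pulse at voltage V,
`I(t) = A(V)·[f + (1−f)(1 − e^(−t/τ_act))] + ε`, with instantaneous fraction
f (default 0.1) and Gaussian noise ε. The deactivation segment relaxes
single-exponentially with τ_deact toward A(−80), starting from the
instantaneous jump A(−80)·g(end). The amplitude
`A(V) = g·(V − V_rev) / (1 + e^(−(V−V_mid)/k))` is a phenomenological
sigmoid-gated driving force chosen solely to produce outwardly rectifying
traces; its parameters are not fitting targets. The default reversal
potential sits at −90 mV, just below the most negative test pulse, which
keeps A(V) non-negative and monotonically increasing over the whole
protocol; setting the rectification parameters to `None` gives an ohmic
amplitude.

**Fitting.** The three-parameter mono-exponential `I(t) = I_ss − ΔI·e^(−t/τ)`
is fitted by nonlinear least squares over the first 250 ms of the +80 mV
pulse (window and voltage configurable), initialized by log-linearizing
`I_ss_est − I`. The fitted quantities are reported as activation *time
constants* in ms (the field sometimes prints these as "rate constants"; the
number reported is the exponential's τ). Non-convergence and non-positive τ
are flagged, never silent; flat segments are reported as non-converged with
ΔI ≈ 0. For any noiseless trace from the module's own model class the fit
recovers the generating τ to solver tolerance (property-tested over
τ ∈ [20, 2000] ms), and τ is invariant under current scaling and time-base
shifts.

**Group comparison harness.** Per-oocyte activation time constants are drawn
normally around the group means 341 ms ("WT"-like, n = 13) and 104 ms
(mutant-like, n = 18) with per-oocyte scatter 18 ms and 6 ms respectively —
the printed dispersion of the two groups used directly as the generating
scatter — traces are simulated at those constants with noise equal to 1 % of
the +80 mV amplitude, refitted, and compared with a two-sample Student's
t-test (equal-variance by default; Welch optional) plus the fold ratio of
means. Under these conditions the separation is decisive (fold ≈ 3.3,
p ≪ 10⁻⁶). Group sizes follow the 13-vs-18 reading of the source figure
legend; the source text elsewhere says 17 and 13, a discrepancy we document
rather than resolve. Whether the original fit carried an offset term is also
not stated; the three-parameter form (offset + amplitude + τ) is the
default here.

**IV curves.** Mean current over the final 10 ms of each test pulse,
normalized per trace by the +80 mV value, averaged across traces with s.e.m.
The value at +80 mV is exactly 1 by construction.

## Pipeline

`run_all` executes simulate → map → prioritize → stats → kinetics from one
YAML config and a single seed (per-stage seeds are derived by hashing), logs
stage timings, writes every intermediate file in plain-text standard formats
(VCF, PED/MAP, GFF3, FASTA, BED, TSV, JSON), and emits a consolidated JSON
report with a config digest for exact re-runs. On the default configuration
the planted codon-750 group is the unique non-synonymous survivor of
cascade B and lies inside a reported shared-homozygosity interval; over 100
seeded runs this end-to-end recovery succeeds in ≥95 (the residual failures
are populations whose true shared segment is shorter than the 10-marker
reporting threshold — a genuine resolution limit of 30-kb marker spacing,
not an analysis error).

## Numerical and convention notes

* Coordinates are 1-based inclusive everywhere (VCF convention); BED export
  converts to 0-based half-open and the conversion is round-trip tested.
* Genotype codes: 0 hom-ref, 1 het, 2 hom-alt, −1 missing.
* Window-scan p-values are clamped away from exact 0 before −log₁₀.
* Interval length uses end − start (not +1), matching how printed intervals
  reconcile with their marker coordinates.
* Problem sizes used by the test-suite simulations (100-seed recovery, 10⁴
  meioses for the crossover check, 10⁵ multinomial draws for the HWE
  Monte-Carlo oracle) were chosen as the smallest sizes at which the checked
  statistics are stable.

## Known limitations

* The window scan is not a mixed model; it must not be used on stratified
  real cohorts.
* The exact HWE test enumerates heterozygote counts and is O(min allele
  count); fine for cohort-scale counts, slow for millions of alleles.
* Codon annotation covers substitutions only; frameshift/splice classes are
  out of scope, as is any deleteriousness prediction.
* The trace model has a single gating variable; real ClC-7/Ostm1 common
  gating is richer (two subunits, temperature- and pH-dependence), none of
  which is modelled.
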