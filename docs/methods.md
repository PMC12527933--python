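# Methods

This note documents the models, estimators, numerical conventions and
design choices in `pofokit`, and what the simulation-based validation does
and does not establish.

## Simulator

**Meiosis.** Crossovers per meiosis are Poisson with mean equal to the
parent-sex map length in Morgans; positions are uniform on the sex-specific
cM scale and mapped to bp by inverse interpolation. No crossover
interference is modelled: the sibling-score machinery only uses expected
counts (`λ = 4·l_c` for the four meioses behind a sibling pair) and local
map contrasts, neither of which requires an interference model.

**Genetic maps.** Maps are piecewise linear in bp. The bundled random-map
generator draws female and male interval rates independently from a
Gamma(shape = 1) distribution and rescales each chromosome to its target
length (defaults approximate the human autosomes: ~43 female / ~26 male
Morgans across 22 chromosomes). Independent draws give local female:male
rate ratios spanning orders of magnitude, which is the signal the crossover
sex-scoring exploits; real maps are somewhat smoother at the Mb scale, so
simulated per-crossover evidence is, if anything, conservative-to-generous
depending on the window, and the genome-wide score's separation on
simulation should not be read as a quantitative accuracy forecast for any
particular cohort.

**Founders and variants.** Founder haplotypes are drawn site-independently
from a Beta(0.8, 0.8) frequency spectrum clipped to [0.02, 0.98]; there is
no linkage disequilibrium. Marker density is configurable
(`variants_per_cm`); IBD detection requires roughly ≥ 12 markers per cM for
a 3-cM segment floor to be meaningful (below that, chance identity runs
reach 3 cM). Simulated kinship coefficients between true relatives have
realistic variance only when a genome-scale map is simulated: on one or two
short chromosomes the true IBD fraction between siblings varies so much
that threshold-based relationship classification genuinely degrades — that
is biology, not estimator error.

**X and mtDNA.** Males carry a single, maternally inherited X (the
pseudoautosomal regions are omitted); mothers transmit a recombinant X
(uniform 180-cM female map), fathers pass their X to daughters unchanged.
mtDNA is copied from the mother with a per-site, per-meiosis mutation
probability (default 2×10⁻³ over 400 variant sites with a skewed
Beta(0.5, 5) minor-allele spectrum) so maternal-line sharing is high but
not degenerate.

**Observation model.** Observed haplotypes are the truth after (i) a random
per-chromosome orientation (interchromosomal phase is unobservable to
intrachromosomal phasing), (ii) Poisson switch errors at a configurable
rate per cM (default 0.01), (iii) genotype flips at a configurable rate per
genotype call (default 10⁻³). Optional founder-haplotype "ancestry
painting" (`track_ancestry`) records the founder origin of every allele,
giving exact truth IBD tracts for validating the detector.

**Phenotypes.** Quantitative traits are
`Σ (β_pat·pat_allele + β_mat·mat_allele)` plus covariate effects and
Gaussian noise; binary traits pass the same linear predictor through a
logistic link.

## Relatedness and clustering

Kinship is the robust estimator
`φ̂ = (N_het,het − 2·N_IBS0) / (N_het(a) + N_het(b))`; the classification
bands are the standard half-intervals (1st degree 0.1767–0.3535, then
0.0884, 0.0442, 0.0221), with parent–offspring vs sibling resolved by
IBS0 (0.0012) and a 15-year age gap. Surrogate-parent clustering joins a
target's 2nd–4th-degree relatives whenever their mutual kinship exceeds
the 4th-degree floor and takes connected components as family sides; more
than two components is flagged and the two largest retained.

## IBD detection

The detector scans for identity runs between a target haplotype and either
haplotype of each group member. Exact runs are merged across isolated
single-site mismatches when (a) the merged span's mismatch density stays
within `max_mismatch_rate` (default 0.01, absorbing genotype errors) and
(b) the runs on both sides of the mismatch span at least 8 sites. Guard (b)
matters: without it a long segment erodes outwards through short chance
runs by roughly 1% of its length, displacing scaffold flip points. Runs
must span ≥ 32 sites and ≥ 3 cM (sex-averaged); overlapping segments from
members of one side are merged. With `max_mismatch_rate = 0` the detector
reduces exactly to a maximal-exact-run scan, which is how it is validated
against a brute-force oracle. Coordinates are 0-based half-open bp
throughout.

Segment boundaries carry intrinsic uncertainty of a few markers (runs
extend through homozygous stretches past the true recombination point);
boundary-sensitive consumers (scaffold flips, crossover windows) use gap
midpoints.

## Interchromosomal phasing

Side-labelled segments act as orientation anchors: between consecutive
anchors demanding different orientations, the haplotype pair is flipped at
the bp midpoint of the inter-anchor gap (for overlapping anchors, the
overlap midpoint). The exact flip position inside a gap is unidentifiable;
the midpoint choice is therefore reported rather than estimated.
Chromosomes without anchors keep their input orientation and are excluded
from genome-wide scoring. Pedigree phasing (when parents are genotyped)
uses transmission logic, masking Mendel-inconsistent sites and resolving
single-parent cases by exclusion.

## Parental-side probabilities

X sharing, MVS and the sibling score all use one estimator: with reference
values from targets whose sides are known, the paternal probability at a
query value `v` is `F̂_pat(v) / (F̂_pat(v) + F̂_mat(v))` with strict
indicators, applied below a separation-maximising cut; above the cut the
symmetric survival-function form gives the maternal probability
(`Pr_mat = 1 − Pr_pat` always). The cut is the midpoint of the training
interval maximising `F̂_low(c) + 1 − F̂_high(c)`. Orientation (which class
is the low-value class) is auto-detected from class means for X and MVS —
making the estimator exactly symmetric under a label swap — and fixed for
the sibling score, whose sign convention (negative ⇒ haplotype 0 paternal)
is known a priori.

Two boundary rules: queries beyond every training value get probability 1
for the corresponding side (the strict-indicator limit); queries *tied*
with training values while the strict indicators are empty (typically many
values at a detection floor, e.g. zero X sharing) use inclusive counts
with a half pseudo-count, which keeps ties informative without claiming
certainty. Consequently the paternal probability is monotone in the value
above the floor but deliberately less-than-certain exactly at it.

With small reference panels the estimator is overconfident at extremes: the
top-ranked member of a class always has an empty opposite-side strict
count, so roughly one query per class and stratum can receive probability
1.0 spuriously. At biobank scale this affects ~1/N of calls; at simulation
scale it is visible, which is why distant-relative strata are only treated
as well-calibrated when they hold dozens of reference values, and why
conflicting mtDNA calls from different 3rd/4th-degree relatives leave a
target undetermined rather than resolved.

MVS predictions are stratified by relative degree; for 3rd/4th-degree
relatives a maternal-side lineage often passes through a male (probability
3/4 for a 4th-degree path), so low MVS does not indicate a paternal
relationship — the calibration data contain those broken-line maternal
relatives and the estimator returns ≈ 0.5 for low values in those strata.

## Sibling crossover scoring

Breakends of the per-haplotype IBD sharing profile (3-cM floor applied) are
crossover calls; chromosome-end boundaries are not breakends. Each call's
1,000-bp window is measured on both sex maps (clamped at map ends, floored
at 10⁻⁸ Morgan before log10). Per-chromosome and genome scores follow the
signed-sum definitions; the probability of paternal origin compares the
target's score to reference scores whose phased genomic length lies within
±3 Morgans (widened stepwise until both classes hold ≥ 3 values). The
single-chromosome fallback keeps the hard ±2 thresholds. Crossover-count
QC drops individuals outside `[Q1 − 10·IQR, Q3 + 10·IQR]` per chromosome,
falling back to a 10⁻⁶ two-sided Poisson tail at `λ = 4·l_c` when the IQR
degenerates.

Because the 3-cM floor removes short inter-crossover segments (and
chromosome-end segments), the measured breakend rate is ~3.6–3.7 per
Morgan per sibling pair, below the idealised Poisson mean of 4 — the
observed count is bounded above by the expectation, as the QC model
anticipates.

## Combination, encoding, filters

Parental-genome calls override everything; otherwise the predictor with
the highest probability wins, ties broken in the order X, sibling score,
MVS. Conflicting mtDNA calls from distinct distant relatives in one
cluster leave the target undetermined. The second haplotype's parent
follows by exclusion (uniparental disomy is assumed absent). Dosage
encoding follows `DS_mat = AP_mat·p_t + AP_pat·(1 − p_t)` (and
symmetrically), GP triplets as `(1 − DS, DS, 0)`, and the differential
triplet is defined at heterozygous entries only, missing when the diploid
dosage vanishes. Scan filters: INFO > 0.8 and MAF > 1% per variant; the
differential scan additionally requires, per entry, one parental dosage
> 0.99 and the other < 0.01 (the per-entry reading of the dosage-certainty
filter; a variant-level mean would not restrict entries).

Haploid imputation itself is not re-implemented: the simulator emits AP
values as truth alleles under configurable noise, which exercises the
encoding, filters and scans identically.

## Association scans and POE statistics

Quantitative scans use OLS with covariates (vectorised via
Frisch–Waugh residualisation; per-variant complete-case fits where the
differential regressor is missing), binary scans use logistic ML with
separation flagged by unstable standard errors. No whole-genome ridge step
is included: simulated cohorts have no polygenic confounding by default,
and a polygenic covariate can be added for stress tests. Regressors with
residual variance below 10⁻⁸·n after covariate projection are flagged
collinear. The differential summary statistic is the signed contrast
`Z_D = (β_P − β_M)/√(se_P² + se_M²)`; a squared-numerator variant seen in
some summary-data contexts cannot produce a signed two-sided statistic and
is treated as a typographical artifact. POE classification applies the
parent-dominant rules (one |Z| at least twice the other) before the
bipolar/asymmetric rules so the five classes partition the plane. simpleM
uses the documented 0.995 variance-explained cutoff. LD pruning greedily
keeps the smallest-P hit and removes neighbours within 500 kb or r² ≥
0.01. Odds-ratio contrasts recover each log-OR standard error from its
reported CI as `(ln U − ln L)/(2·1.96)`.

## Validation scale and limitations

Default validation sizes: 2,000 sibling pairs on a 2-Morgan chromosome for
the breakend rate; 500 pairs across 22 autosomes for genome-wide score
accuracy; a 600-family mixed cohort (trios, duos, sibling-pairs-plus-uncle,
and 2nd–4th-degree surrogate families, both-sided for degrees 3–4) for
end-to-end recovery; 10⁴ null variants for differential type-I error.

Passing these suites shows the pipeline is internally correct under the
simulator's assumptions. It does not demonstrate robustness to linkage
disequilibrium, population structure, genotyping-array artefacts, imputation
error beyond the injected AP noise, consanguinity, or realistic phasing
error patterns — all of which a production deployment would need to assess
on real data. The mismatch tolerance of the IBD scanner is a configuration
stand-in for an HMM's error absorption, and rearing effects cannot be
distinguished from true imprinting by transmitted-allele tests.
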