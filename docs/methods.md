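# Methods

`metascreen` reimplements, as a tested library, a strategy for predicting
drug–target relationships in *Saccharomyces cerevisiae* from untargeted
metabolomics: the metabolome profile of yeast treated with a drug is
matched against the profiles of β-estradiol–inducible overexpression
strains of candidate target genes. A drug that antagonizes a target should
resemble the strain's uninduced (loss-of-function-like) state and
anti-correlate with strong induction; an agonist shows the opposite
pattern. This note records the models, parameter choices, and numerical
decisions, and what the synthetic benchmarks do and do not demonstrate.

## Preprocessing chain (`normalize`)

Flow-injection TOF-MS ion tables (samples × ions) are cleaned in a fixed
order:

1. ions missing in more than half the samples are dropped;
2. samples whose OD600 or total ion current deviates from the plate median
   by more than `mad_multiplier` scaled MADs (default 4.0; MAD × 1.4826)
   are removed per plate — plates with fewer than 4 samples skip the
   filter;
3. ions known to be drug-derived artifacts are dropped;
4. per batch, each ion's LOWESS trend over injection order (span 0.3,
   2 robustifying iterations) is subtracted, and batch medians are aligned
   to the ion's global median. Batches too small for a stable local fit
   fall back to median subtraction;
5. each ion is regressed on OD600 (ordinary least squares over all
   retained samples) and the fitted biomass component is removed;
6. z-scoring per ion per 96-well plate: against all samples of the plate
   (chemical screens) or against the plate's estradiol-treated wild-type
   controls (overexpression dose series);
7. optional restriction to ions annotated to organism compounds, then
   replicate z-scores are averaged per condition.

Corrections subtract on the raw intensity scale (a config switch enables
log-scale operation, default off). Standard deviations use the n−1
convention throughout; this choice fixes the values of every hand example
(controls 10/12/14 with a treated 16 give z = 2).

Two consequences worth knowing. First, LOWESS detrending of a screen whose
injection order randomizes biological conditions removes a little real
signal along with the drift; condition effects are attenuated by a few
percent, which is why even artifact-free synthetic data do not reproduce
the planted effect pattern with rank correlation exactly 1. Second,
detecting drift *removal* as "residual correlation with injection order
below 0.05" is only meaningful when the correlation is estimated from many
pooled batches — with 96 samples the sampling noise of a correlation
coefficient alone is ≈ 0.1.

## Profile matching (`profile_match`)

Similarity between condition-averaged z-profiles supports Spearman
correlation (mean ranks for ties; the primary metric), Pearson, and cosine.
Missing ions are handled pairwise-complete, with a minimum overlap of 20
ions per comparison (the paper-scale restriction set has 226 metabolites;
20 guards against degenerate comparisons on sparse data). Dose–response
series collect one similarity per inducer dose — dose 0 (uninduced)
included — for every (gene, drug, timepoint).

## Logistic hit calling (`logistic_hits`)

Each similarity series is min-max scaled to [0, 1] and fitted with the
two-parameter logistic f(x) = 1/(1 + exp(−k(x − x0))), x = log10(dose in
nM), by nonlinear least squares with a forward-difference Jacobian,
starting from x0 = 2, k = 0. The asymptotes are fixed at 0 and 1 by the
scaling. The uninduced point is placed one decade below the smallest
positive dose; the fit quality is the trace of the estimated parameter
covariance (the simplest scalar summary of "the estimated covariance";
determinant or a single variance would rank similarly), +∞ for
non-converged fits. Hits must (i) rank in the best decile of their gene's
converged fit qualities, (ii) reach the positive-control benchmark in
maximum absolute similarity, (iii) keep x0 inside
[log10(d_min) − 1, log10(d_max)], and (iv) not be on the exclusion list.
A negative fitted slope predicts an antagonist. Timepoints are fitted
independently and reported per timepoint.

A caution on interpreting x0 from pipeline similarity curves: because
correlation is magnitude-invariant, a noiseless similarity-versus-dose
series is a step between its two plateaus, crossing where the induction
response changes sign — at x0 + ln(A/C)/k when the uninduced gain C is
smaller than the induced gain A. The fitted inflection of a similarity
curve therefore sits systematically above the biochemical inflection of
the induction response itself. Parameter-recovery benchmarks consequently
evaluate the *fitter* on noisy samples of the planted sigmoids (additive
noise, sd 0.1 on the scaled values), where the noiseless fit is exact to
1e-6 and the noisy median |x0 error| is ≈ 0.2 decades; slope-sign mode
classification, which is insensitive to the offset, is evaluated through
the full pipeline.

## Single-dose evaluation (`single_dose_eval`)

With one inducer concentration, drugs are ranked per gene by similarity to
the induced or uninduced profile. Expected signs: induced state —
agonists positive, antagonists negative; uninduced state — reversed.
Known interactions are scored with their annotated mode; unlabeled drugs
are scored under the mode most favorable to them (their absolute
similarity), which biases the reported AUC downward (conservative). Each
drug contributes its rank percentile (rank − 0.5)/n within its gene, so
genes with different library sizes pool on one scale; the ROC sweeps a
percentile threshold and AUC equals the Mann–Whitney U statistic with
half-tie counting (verified against brute-force pair counting). Per-drug
eligibility for the top-20 tabulation requires p < 0.05 (plain two-sided
equal-variance t-tests, unadjusted) in at least 5 metabolites against
same-plate vehicle controls.

## Structural coherence (`chem_similarity`)

Molecules are element-labeled heavy-atom graphs with typed bonds (1, 2, 3,
aromatic); hydrogens are implicit and aromaticity is taken from the input
(SDF bond type 4, lowercase SMILES) without re-perception. The maximum
common substructure is the largest common *connected* node-induced
subgraph under strict element and bond-order matching (aromatic matches
only aromatic), found by branch-and-bound maximum-clique search on the
modular product graph with a greedy coloring bound and a connectivity
constraint on the c-edges; it is exact (verified against exhaustive
enumeration for ≤ 12 heavy atoms) and deterministic, with a per-pair time
budget (default 5 s; exceeding it returns the best bound found, flagged).
MCS Tanimoto = |MCS| / (|a| + |b| − |MCS|) over heavy atoms. Hit-set
coherence compares the median pairwise MCS Tanimoto of the hit set against
medians of random same-size draws from the library (default 10,000 draws,
sampling without replacement within a draw); empirical
p = (1 + exceedances)/(1 + draws).

## Clustering and GO enrichment (`cluster_enrich`)

Gene profiles are clustered by Ward's method on Manhattan distances — the
Lance–Williams Ward recurrence applied to the distances as given (classic
`hclust ward.D` behaviour). Implementation detail: scipy's Ward linkage
applies the recurrence to the squares of its input, so the package passes
sqrt(D); merges and cut partitions equal ward.D(D) exactly (checked
against R's hclust in the test suite) while stored heights are the square
roots of ward.D heights. The tree is cut to 15 clusters by default.

Per cluster, every term is tested with the one-sided hypergeometric tail,
BH-adjusted within the cluster (α = 0.05), and the most widespread
significant term (largest k; ties toward smaller p, then term id) is
selected. The coherence statistic is the gene-weighted mean enrichment
factor (k/n)/(K/N) of selected terms, with genes in clusters lacking a
significant term contributing a neutral factor of 1; the null shuffles
gene → cluster labels preserving cluster sizes (default 1,000 rounds).
Because the statistic sits exactly at 1 whenever no cluster has a
significant term — which happens for most label shuffles — its empirical
p-value is discrete with a large mass near 1: the test is *valid*
(P(p ≤ t) ≤ t, verified) and detects planted coherence at p ≤ 0.01, but
its null p-values are not distributionally uniform and cannot be, for any
annotation density, as long as per-cluster discoveries are FDR-controlled.

## Chemical genetics (`chem_genetics`)

Target dependence is quantified by counting metabolites that change
significantly (two-sided equal-variance Student's t-test, unadjusted,
α = 0.05) under a drug versus same-genotype vehicle controls, in the wild
type and in a deletion mutant of the predicted target; `impaired` means
the wild-type count exceeds the mutant's, and the ratio uses add-one
smoothing. Single-metabolite contrasts normalize each replicate to the
same-genotype vehicle mean before comparing genotypes.

## Synthetic screens (`synthetic_screen`)

The generator emulates the study design so every stage is testable without
downloads: 96-well plates measured in injection order, per-batch drift
(low-frequency sinusoid + linear, fractional amplitude 0.10),
multiplicative OD600 effect (od ~ N(1, 0.1) truncated > 0.5; per-ion
exponent ~ N(1, 0.25) — intensity roughly proportional to biomass),
lognormal measurement noise (CV 0.15), 2 replicates, vehicle (DMSO) and
estradiol-treated wild-type control wells on every plate, two timepoints
(1.5 and 3 h), an 8-concentration inducer series spanning seven orders of
magnitude (1–10⁷ nM) plus the uninduced state, and drugs at a fixed
10 µM. Default scaled-down sizes: 40 genes, 200 drugs, 200 ions, 20
planted pairs (tests stay fast; the full 86 × 1,280 scale also runs at a
desk).

Biology of the planted signal: each gene carries a sparse log-intensity
effect vector (15% of ions, standard-normal entries centered on their
support — perturbations redistribute metabolite pools rather than shifting
total ion current, which in real FIA data is dominated by thousands of
unannotated ions and is nearly treatment-insensitive). Induction follows a
logistic L(d) with inflection uniform in the interior of the dose range
and steepness uniform in (1, 3); L(0) := 0 exactly, so the uninduced state
is a pure loss-of-function phenotype. The induced gain is 1.0 and the
uninduced (loss) gain 0.15: basal expression retains partial function, so
the uninduced metabolome phenotype is present but much weaker than full
induction — consistent with the markedly poorer uninduced-state recall
reported for the original screens. Planted drugs shift the metabolome by
±potency × gene effect (antagonists toward the loss state; 60%
antagonists, potency uniform in (0.5, 1.5)) plus a drug-specific sparse
off-target vector; non-planted drugs carry off-target effects only.
Deletion-mutant screens give mutants the loss-of-function background and
remove the on-target component of the drug response.

What the synthetic benchmarks show: the pipeline recovers planted
interactions (induced-state AUC ≥ 0.9; induced beats uninduced recall in
≥ 19/20 seeds), classifies antagonists by slope sign, detects planted
structural families and planted GO coherence, and all statistics agree
with independent oracles. What they do not show: performance on real FIA
spectra (no isotopes, adducts, unresolved isobars, or ion-annotation
errors), robustness to growth-rate confounding, or calibrated hit rates
for real chemical libraries — the generator's noise and effect scales are
plausible placeholders, not estimates fitted to the deposited data.

## Numerical choices and degenerate inputs

- Random streams: every generator derives from an explicit integer seed
  through independent named substreams; reruns are bit-identical.
- Constant similarity series min-max scale to all-0.5 and are flagged
  unfittable; zero-variance ions within a plate become missing and are
  flagged `zero_variance`; non-converged or singular-covariance fits get
  quality +∞ and can never be hits.
- Ties: Spearman uses mean ranks; drug rankings break score ties
  alphabetically; AUC counts ties one half; term selection breaks ties by
  smaller p then lexicographic term id.
- Tables are tab-separated UTF-8 with '.' decimals; floats round-trip
  bitwise via shortest-repr serialization. Missing intensities are NaN,
  never 0, and are excluded pairwise downstream.

## Benchmark problem sizes

Test and acceptance runs use the scaled-down defaults above; the recall
benchmark simulates the single-concentration design (doses {0, 10⁷ nM},
one timepoint) with the full 40 × 200 default, the dose-series benchmarks
use 30 genes × 60 drugs over all 9 dose points, inflection recovery uses
200 planted sigmoids, structural coherence a 60-compound library, and GO
coherence 86 genes in 15 clusters — the original study's gene-panel shape.
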