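# Methods

## Overview

The pipeline quantifies how two protein domains (the MT3-specific
C-terminal hexapeptide insert and the threonine-containing N-terminal
motif) reorganise the transcriptome and phenotype of stably transfected
MCF-7 cells. Its stages are: fold-change gene-set construction against the
parental line, overlap-distance hierarchical clustering of arrays, a
SAM-style permutation differential-expression test, doubling-time
estimation from MTT growth curves, and dome/TER phenotype summaries with a
phenotype–expression association test. A synthetic-data generator supplies
inputs with known ground truth at every stage.

## Gene sets and overlap clustering

For each array `a` from a transformed line, the gene set is
`{probe : value_a(probe) / max(ref(probe), ε) > θ}` with `ref` the
arithmetic mean over the parental reference arrays, `θ = 2` (strict
inequality) and `ε` a floor defaulting to the smallest positive reference
value (intensities of exactly 0 are legal inputs; the floor keeps ratios
finite). A two-sided mode additionally admits `FC < 1/θ`. Parental arrays
are not clustering leaves: their fold change against their own mean is
uninformative, and the study design compares transformed lines only. A
per-line mode (sets built from each line's mean profile) is available for
the alternative reading of the set rule.

Distances are `D(A, B) = 1 − |A ∩ B| / |A ∪ B|`, a metric on sets
(Jaccard distance). Conventions for degenerate inputs: two empty sets are
identical (distance 0, logged); exactly one empty set gives 1.

Agglomeration uses Ward's method via the Lance–Williams recurrence on the
precomputed distances. The default variant applies the recurrence to
squared distances and reports square-root heights — the convention of
scipy and of R's `ward.D2` — with the unsquared variant selectable; the
source analysis does not name its variant, so one is documented as the
default rather than silently assumed. Ward's coefficients satisfy the
reducibility condition, so merge heights are monotone even on arbitrary
dissimilarities; an inversion check is nevertheless kept and logged. Ties
in the minimum inter-cluster distance break toward the lowest cluster-id
pair, making merge order deterministic. Tree cuts use the merge order
(scipy's `cut_tree` on the package's own linkage matrix); Newick export
places each node at depth `height/2`, so a pair merged at 0.4 renders as
`(a:0.2,b:0.2);`.

## SAM differential expression

The two-class unpaired statistic is `d_i = (x̄_A − x̄_B)/(s_i + s0)` with
`s_i` the two-sample pooled standard error. The fudge factor `s0` is
chosen by the percentile search of the original method: candidates are the
0, 5, …, 100 percentiles of the `s_i` distribution; for each candidate,
probes are split into up to 100 equal-occupancy `s_i` bins, the median
absolute deviation of `d_i` (scaled by 1/0.64) is computed per bin, and
the candidate minimising the coefficient of variation of these values
wins. The search is deterministic; degenerate all-zero `s_i` returns a
small positive floor with a warning.

P-values permute group labels, holding `s0` fixed at its observed-data
value. When the number of distinct assignments `C(n, n_A)` is at most the
requested `n_perm`, all are enumerated and `p` is the plain count
`#{|d*| ≥ |d|}/C(n, n_A)` — the observed assignment is in the enumeration,
so `p ≥ 1/C(n, n_A)`; otherwise `n_perm` seeded shuffles are drawn with
the add-one convention `(1 + count)/(1 + n_perm)`. Multiplicity is
adjusted by Benjamini–Hochberg (statsmodels implementation behind
`bh_fdr`).

**Granularity at the study's design size.** At 3 vs 3 arrays the
exhaustive null has 20 assignments, and because `|d|` is invariant under
swapping the group labels, the observed assignment and its mirror both
count: every per-probe `p ≥ 2/20 = 0.1` for a genuinely regulated probe,
and every BH `q = min_k p_(k)·m/k ≥ 0.05`. No probe can reach `q < 0.05`
at this design size under per-probe permutation p-values — a property of
the design, not of the implementation. Detection at triplicate scale
should therefore read the ranking of `d` (the planted block dominates it;
see the README example) rather than a fixed q cutoff; q-based calling
becomes meaningful at larger group sizes where the permutation
granularity is finer. The original delta-threshold/median-false-positive
machinery of SAM, which sidesteps this floor, is intentionally out of
scope here.

## Doubling times

MTT absorbance at 570 nm is treated as proportional to viable cell number
(the assay's standard assumption). After blank subtraction (floored at a
small positive value before the log), the "linear region of the
exponential portion" is operationalised deterministically: among all
contiguous windows of at least `min_window = 3` time points, the fit of
log2(absorbance) vs time with positive slope and maximal R² wins, ties
going to the longer and then the earlier window (R² compared at 1e-12
resolution). `T_d = 1/slope` hours; the standard error follows by the
delta method from the slope's standard error. A curve with no
positive-slope window raises "no exponential region". Rescaling time units
rescales `T_d` exactly. Group comparison is one-way ANOVA with Tukey HSD
(scipy/statsmodels).

## Phenotype

Dome records hold exactly 21 per-field counts per flask; the summary is
`mean/field = total/(21·flasks)`, `mean/21 fields = 21 × mean/field`
(exact by construction), and a positive flag if any dome was seen. TER
filter values are `(mean of 8 readings − blank) × area`; daily summaries
are mean ± SEM over triplicate filters, and the combined day-5/6/7 value
is the arithmetic mean of the three daily means reported to two decimals
with round-half-to-even. Two of the published combined values are
arithmetically inconsistent with their own daily means (one by ~1.7, one
by 0.01 through non-half-even rounding); the package reproduces the
self-consistent rows and deliberately does not encode the discrepant
values.

The dome–expression association is an exact one-sided rank-sum
permutation test over line labels: the statistic is the sum of expression
ranks of dome-positive lines, `p` the plain-count fraction of label
assignments (exhaustive when `C(n, n_pos)` is small, e.g. 1/56 at 3 vs 5
lines for perfect separation) with a rank sum at least the observed.
Because rank sums are integers, ties make the test conservative
(super-uniform p under the null), never anti-conservative.

## Synthetic data generator

Expression is log-normal: `log intensity = baseline(probe) + log f(line,
probe) + noise`, with per-probe baselines `N(5, 1)` (natural log of
arbitrary fluorescence units, i.e. median ≈ 150), per-array noise sd 0.2
(≈ 0.29 on the log2 scale — moderate array noise), and defaults of 2,000
probes and the study's 8 lines × 3 replicates. Three disjoint planted
blocks of 16 probes each encode the regulatory structure:

1. **GAGE-like block**: × `ct_effect` (default 4) in lines with the
   C-terminal but not the N-terminal domain; × `nt_effect` (default 0.25)
   whenever the N-terminal domain is present — dominance of the N-terminal
   suppression over C-terminal induction, regardless of `has_ct`.
2. **Shared transfection-response block**: × 4 in every transformed line —
   stable transfection, selection and clonal expansion perturb every clone
   relative to the parent.
3. **NT-suppressed response block**: × 4 in transformed lines lacking the
   N-terminal domain, baseline otherwise — the same dominance applied to
   the transfection response.

Blocks 2–3 exist because the reported dendrogram topology is impossible
without them: with a single block, up-regulated gene sets of
N-terminal-bearing, empty-vector and MT1E-like arrays are all
structureless and mutually equidistant, so no two-way cut can separate
"N-terminal-bearing" from "the rest" reliably. With them, the expected
between-group set distances are 1/3 (non-NT lines among themselves) versus
1/2–2/3 (to NT lines), and the k=2 cut recovers the split with adjusted
Rand index 1.0 in effectively every seeded run. Both block sizes are
configurable and may be set to 0 to recover the minimal single-block
design (used in unit tests of the set rule). Effect sizes are declared
arbitrary-but-realistic: the source reports no usable effect-size
estimate, and ×4 places planted probes ≈ 3 noise-sd beyond the ×2 set
threshold. The 16-probe block size represents a mid-sized co-regulated
gene family. Zero-noise runs reproduce planted fold factors exactly, which
the truth object exposes as the oracle for downstream tests.

Growth curves follow lag → exponential (doubling every `true_td` h) →
plateau with additive Gaussian well noise; the study replica uses time
points 0–168 h every 24 h, a 24-h lag, amplitude 0.05, plateau 2.0 and
per-line true doubling times at the published scale (≈ 32–40 h for
parent-like lines, ≈ 53–65 h for domain-bearing lines). Dome counts are
Poisson per field with per-line rates following the published pattern
(≈ 2.7/field for the two C-terminal-only lines, 0.1 for wild-type MT3, 0
elsewhere); TER values are Gaussian around the published daily means with
the blank/area geometry reconstructed in the raw readings.

What the generator does **not** emulate: probe cross-hybridisation, batch
and chip spatial effects, intensity-dependent (heteroscedastic) noise,
correlated noise between replicates, and non-exponential growth shapes.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not robustness to real-array artefacts.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 10,000 random set pairs
and 1,000 triples for the distance law; 100 random matrices (n ≤ 12) for
Ward agreement with an independent reference implementation; 100 seeded
study replicas (2,000 probes) for the dendrogram split; 200 null and 20
planted 500-probe datasets for SAM behaviour; and 500 seeded growth
curves for doubling-time recovery — sizes chosen to put Monte-Carlo error
well below each decision margin. Floating-point ties in permutation
counts use a 1e-12 absolute tolerance so exact-equality cases (the
observed assignment, mirrored assignments) count deterministically.
Seeded `numpy.random.default_rng` streams drive all randomness; the CLI
records the seed, package version and a parameter hash in provenance
sidecars, and stage outputs are written atomically (temp-then-rename).

## Known limitations

- No detection-p-value filtering of probes before set construction; the
  input matrix is taken as already normalised (chip-level normalisation
  and IDAT parsing are out of scope).
- Ward on a non-Euclidean dissimilarity is a heuristic (as in the source
  analysis); only the squared/unsquared variant choice is exposed.
- The SAM stage implements p-values + BH only; see the granularity note
  above for triplicate designs.
- The doubling-time window search assumes a single exponential region;
  biphasic curves will fit whichever phase maximises R².
- The association test operates on line-level summary expression (n = 8
  lines), so its power is bounded by the exhaustive permutation count.
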