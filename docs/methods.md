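# Methods

## The screening statistic

The screen targets genes whose *detection frequency* rises with age. For
gene *g* in age group *a* with cells *C_a*, the positive-cell rate is

    r_g(a) = |{ c ∈ C_a : rpkm(c, g) > 1 }| / |C_a|

and genes are ranked on Δ_g = r_g(old) − r_g(young), descending. The
rationale: a marker of a senescent subpopulation behaves as a mixture —
near-silent in normal cells, induced in senescent ones — so the fraction of
expressing cells tracks the subpopulation's prevalence far more directly
than a mean over all cells does. No p-value is attached to Δ: the screen is
a ranking device whose output is validated downstream, and the pipeline
deliberately computes none.

Conventions fixed here (and why):

* **Positivity is strict** (`rpkm > 1`, so exactly 1.0 is negative), as are
  both QC rules (< 200 genes excluded, > 20% mitochondrial excluded; cells
  exactly at a boundary are kept).
* **"Genes expressed" for QC means count > 0** — the only threshold-free
  reading.
* The **mitochondrial fraction uses raw counts**, since QC precedes
  normalisation in the stage order.
* The ranking's **gene universe is the union** of both groups' genes, with
  rate 0 where a gene was never detected: absence of detection is itself
  evidence for an increase screen. (Real young/old matrices typically
  differ in gene count; a merge rule is unavoidable.)
* **Ties break by ascending gene id**, making the ranking a deterministic
  permutation.
* The **ortholog filter runs before truncation** to top K = 43, so the list
  always contains K ortholog-bearing genes when enough exist;
  `require_ortholog=False` gives the plain head instead.
* The **albumin gate reuses the >1 RPKM positivity rule** (default 1.0,
  configurable): gating and positivity are conceptually the same operation
  applied to a marker gene.
* QC runs before gating and before all rate denominators are formed;
  denominators are per-group, post-QC, post-gate cell counts and are
  recorded in the outputs.

## RPKM

`rpkm(c,g) = count(c,g) · 10⁹ / (total(c) · length_bp(g))` with one
transcript length per gene taken from the annotation table (data providers
should supply the longest isoform). Two exact invariants are tested: the
length-weighted per-cell sum Σ_g rpkm·length = 10⁹, and invariance under
scaling a cell's counts. Cells with zero total counts are rejected by
normalisation (QC removes them first in any sane configuration).

## Correlation analysis

Within each group, Pearson correlation (configurable to Spearman) of
untransformed RPKM vectors across the group's cells, for all unordered
pairs of the requested genes and against a reference senescence gene set.
A gene with zero variance in a group — typically never detected there —
has **undefined** correlations; these are carried as an explicit marker and
serialised as `-`, never silently dropped, because "not computable" is a
biologically meaningful outcome (a senescence gene absent from young cells).
Pearson on raw RPKM is the default because the screen's claims are about
co-occurrence of expression in the same cells, which a monotone transform
would not change qualitatively; the "high correlation" flag threshold
(0.6) is an explicit, configurable analysis choice.

## The synthetic-data generator

Counts for cell *c*, gene *g* are negative binomial with mean
`depth_c · p_g` and size (dispersion) θ, drawn as a gamma–Poisson mixture:

* `p` — per-gene relative abundances, lognormal(μ=0, σ=1) across genes,
  normalised to sum 1;
* `depth_c` — lognormal(9.9, 0.35), i.e. ≈ 2.1 × 10⁴ reads per cell,
  emulating deep per-cell read counts (not UMIs) of a full-length protocol;
* θ = 10 by default, i.e. variance m + m²/10 — modest overdispersion, see
  below;
* a **gate gene** ("Alb") pinned to the 99th percentile of abundances, so
  essentially every simulated cell is albumin-positive while the gate still
  filters;
* a **mitochondrial block** (13 genes) rescaled to 8% of total abundance so
  the mito-fraction QC rule measures a realistic quantity;
* **markers** assigned the 1st-percentile abundance — near-silent in normal
  cells, as true senescence markers are in young hepatocytes, where such
  genes are typically undetectable; in **senescent cells** marker abundance
  is multiplied by
  `marker_fold` (default 8) and the abundance vector renormalised, so
  library size is independent of senescence status and the planted signal
  cannot leak through depth.

Senescent membership is Bernoulli per cell (fraction 0.02 in young, 0.35 in
old by default) rather than a fixed count — prevalence is the hypothesis
under study, and truth labels make either convention testable. One RNG
stream is seeded per simulate call, gene-level draws before cell-level
draws, so output is independent of any chunking. Group sizes default to
255 young / 1251 old cells and 2000 genes.

**Choice of θ.** The marker signal lives in two places: the detection-rate
difference (wants markers mostly *off* in normal cells) and the
marker–marker correlation among senescent cells (wants induced expression
well above count noise). Under the mixture model the old-group
marker–marker correlation is approximately
`s/(s + 3.45/m + 23.05/θ)` with `s ≈ 11.15` for the default fractions and
fold, where m is the normal-cell marker mean count: θ = 2 caps it near 0.4,
at which point the handful of senescent cells in the *young* group can
produce outlier-driven young correlations of similar size and the young/old
contrast that defines the phenomenon disappears. θ = 10 yields old-group
marker correlations around 0.5–0.6 against young-group values around
0.2–0.3, reproducing the qualitative pattern (strong co-expression only
where senescent cells are common) while keeping normal-cell marker
detection low enough (rate ≈ 0.45) for the rate screen to work. Lower θ
remains available for stress-testing.

The generator does **not** model doublets, batch effects, ambient RNA,
UMI deduplication, multiple lineages, or gene-specific dispersions. Passing
tests therefore demonstrate the pipeline's correctness and its statistical
behaviour under a clean two-population mixture — not robustness to those
real-data artifacts.

Annotation: transcript lengths uniform in [300, 10000] bp; a configurable
fraction (default 10%) of genes carries no mouse-ortholog symbol to
exercise the candidate filter, but markers and the gate gene always carry
one (markers emulate genes selected for having orthologs; the gate gene
must survive every filter).

## Numerical and degenerate-input choices

* RPKM and calls preserve the sparsity pattern exactly; zero count ⇔ zero
  RPKM ⇔ negative call.
* Correlation is computed on densified submatrices of only the requested
  genes and cells; coefficients are clipped to [−1, 1] against rounding.
* Zero-variance genes (including all-zero) are undefined in correlations,
  including their own diagonal.
* Empty matrices, cells with zero counts, unknown/ambiguous gene symbols,
  unassigned cells, empty groups, missing annotation rows, non-positive
  lengths, malformed MTX triples all raise typed errors naming the
  offenders (up to 10 listed).
* All file writes are atomic (temp file + rename); outputs contain no
  timestamps, so a fixed config and seed reproduce every file byte for
  byte. The seed governs simulation only; analysis stages are
  deterministic.
* On-disk matrices are genes × cells (CellRanger convention), transposed to
  cells × genes in memory.

## Problem sizes used in the test suite

Unit and property tests run on fixtures up to ~50 × 100; oracle-equivalence
checks compare 100 random fixtures against dense brute-force
reimplementations. End-to-end statistical checks use the default
scale (255 + 1251 cells × 2000 genes) over 50 simulation replicates for
the planted and null conditions — sizes chosen to make Monte-Carlo
fractions at the 95% level meaningful while keeping a laptop run of the
whole suite in the one-to-two-minute range.

## Known limitations

* RPKM (not TPM/CPM) is the only normalisation offered; the screen's
  positivity threshold is calibrated to it.
* The positive-rate difference carries no uncertainty estimate; at very
  small group sizes ranks are noisy and the top-K list should be read
  accordingly.
* The generator's single global dispersion understates gene-level
  variability of real data; correlation magnitudes in simulations should
  not be read as predictions of real effect sizes.
* Ortholog mapping is consumed, not computed: the annotation table is
  trusted as given.
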