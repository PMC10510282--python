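# Methods

## Design and notation

The experiment is a 4 genotype × 3 treatment factorial: genotypes
`WT`, `cKO`, `D16p19`, `D16d19`; treatments `Cre` (control lentivirus)
and `ICD19` / `ICDd19` (Cre plus one splice variant of the receptor
intracellular domain).  `WT.Cre` is the global reference.  For each
mutant genotype *g* and variant *i* the pipeline fits three two-group
contrasts: the Cre baseline `g.Cre vs WT.Cre`, the within-genotype
treatment `g.i vs g.Cre`, and the treated group against the reference
`g.i vs WT.Cre`; the two WT overexpression contrasts `WT.i vs WT.Cre`
are fitted as well, giving 17 contrast tables per run.

## Differential expression model

Counts K_gj are modeled as negative binomial with mean `mu_gj = s_j
q_gj` and variance `mu + alpha mu^2`.  Size factors s_j are
median-of-ratios (the median over genes expressed in every sample of
the count over the gene's geometric mean), rescaled to geometric mean
one so that factors are identifiable.  Dispersions are estimated by
method of moments on normalized counts, `alpha_g = (var_g - mean_g) /
mean_g^2`, with the variance pooled within design groups (removing
group-mean differences), floored at `1e-8`, and shrunk 50/50 on the
log scale toward a least-squares `a0 + a1/mean` trend (one
MAD-trimming pass guards the fit against outlier genes).  Genes with
zero mean or zero variance are pinned at the floor.

The test statistic is the log2 ratio of normalized group means with a
pseudocount of 0.5, `log2FC = log2((m_b + 0.5)/(m_a + 0.5))`; its
standard error follows by the delta method from `Var(m) = n^-2 sum_j
(m/s_j + alpha m^2)`, and the two-sided p-value from the normal tail
of `log2FC/SE`.  Reversing a contrast negates `log2FC` exactly and
leaves p unchanged.  Genes with zero counts in both groups are
reported `tested=False` (p = 1, log2FC = 0) and are excluded from all
downstream combination (propagated as missing, never silently as 1).

This stage deliberately omits fold-change shrinkage, outlier
refitting, and independent filtering: it is a documented, transparent
stand-in for a DESeq2-style fit, and any externally produced contrast
table with columns `base_mean, log2fc, se, p, padj, tested` can be
substituted.  Raw p-values feed the classification thresholds; BH-adjusted
values are reported per contrast for transparency.  Calibration under
the null (2,000 NB genes, 6 vs 6, alpha = 0.1) sits near the nominal
5% with KS distance from uniform around 0.02 (see
`scripts/acceptance.py`).

## Additive p-value combination

For k p-values with sum S, the combined p-value is `min(1, S^k / k!)`.
This expression is the CDF of the Irwin–Hall distribution (sum of k
independent uniforms) wherever `S <= 1`, hence exactly calibrated at
any rejection threshold alpha with `(k! alpha)^(1/k) <= 1` — which
covers every threshold used here (alpha = 0.05, k = 2 ⇒ S = 0.316).
Beyond `S = 1` the monomial exceeds the true CDF and is capped at 1;
whether the original analyses capped or simply never rejected there is
unknowable from the printed formula, and the cap only affects
non-significant values.  `mode="exact"` evaluates the full
inclusion–exclusion CDF `sum_j (-1)^j C(k,j) (S-j)_+^k / k!` and is
the statistically correct alternative; the capped form is the default
for fidelity to the published rule.

The design statistics are k = 2 combinations: rescue (baseline p with
ICD-vs-baseline p), effect (ICD-vs-WT p with ICD-vs-baseline p), vWT
(the two vs-WT p-values, computed only when both fold changes exceed
the 0.58 gate with one sign), and the both-ICD statistics, which by
default combine the two already-combined per-ICD values (`nested-k2`).
A `flat-k4` alternative combines the four raw inputs of the two pairs
instead; for rescue the shared baseline p then enters twice.  The two
contrasts in each pair share one group, so they are positively
dependent; the combination treats them as independent, as the
published rule does, which makes the combined values mildly
anticonservative in the tail — a caveat inherited by design.

## Classification rules

With thresholds p < 0.05, |log2FC| > 0.58, reversion ≥ 0.5, relaxed
|log2FC| > 0.5 (all strict comparisons, constants used verbatim):

* **rescued(g, i)** — rescue p < 0.05 AND baseline |log2FC vs WT| >
  0.58 AND |log2FC vs WT with ICD| ≤ baseline |log2FC| − 0.5.  "At
  least 0.5 closer to zero" is read as a reduction in absolute fold
  change; overshooting past zero still counts (a gene going +1.0 →
  −0.2 is rescued), since the rule constrains distance from zero, not
  sign.
* **effected(g, i)** — (effect p < 0.05 OR rescue p < 0.05) AND
  |log2FC| > 0.58 vs both WT and the genotype baseline; direction is
  the sign of the ICD-vs-baseline change.
* **basal(g)** — baseline |log2FC| > 0.58 AND min over available
  routes {baseline p, rescue p of either ICD, vWT p of either ICD} <
  0.05.  "Any available" is used when only one ICD's statistic is
  defined.  Rescued ⇒ basal holds by construction and is asserted in
  the test suite.
* **shared module** — basal-significant (full criteria) in ≥ 1
  genotype AND |log2FC vs WT| > 0.5 with one consistent sign in all
  three mutant genotypes.

Genes with missing inputs (untested contrasts) are reported `NA`
(unclassifiable), never silently `False`.  When only one ICD's rescue
call is defined, `rescued_both` is `NA` rather than promoted from the
single ICD.  All labels are pure functions of the stored contrast and
combined tables; the classification table is byte-identical across
reruns and invariant to gene- and sample-order permutations.

## Synthetic data generator

`simulate_experiment` draws gamma–Poisson (NB) counts for the full
design from planted per-class log2FC profiles relative to `WT.Cre`:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes simulated |
| `replicates_per_group` | 5 | per-group sample size (design range 4–9) |
| `baseline_mean_log_range` | (ln 50, ln 5000) | log-uniform gene mean bounds |
| `dispersion_intercept` a0 | 0.04 | asymptotic dispersion |
| `dispersion_slope` a1 | 1.0 | low-count dispersion inflation, `alpha = a0 + a1/mu` |
| `lfc_magnitude` | 1.5 | planted baseline \|log2FC\| |
| `rescue_reversion` | 1.0 | fraction of the baseline shift removed by a rescuing ICD |
| `class_proportions` | 70% null, 5%+5% rescued-both (up/down), 4%+4% single-ICD, 6% not-rescued, 6% effect-only | planted class mix |

Mean bounds emulate a count table after the low-count filtering any
practitioner applies before DE (genes under ~50 normalized counts are
dropped); dispersion defaults are typical of bulk brain-tissue
biological replicates.  Basal classes plant the same shift in all
three mutant genotypes (which is what makes the shared-module rule
testable); effect-only genes shift only ICD-treated groups, including
WT.  Library-size factors are log-uniform in [0.5, 2] and recorded in
the sample metadata as ground truth.  Samples are independent — the
wet-lab pooling of some replicates has no stated statistical model and
is not emulated.  Class counts use largest-remainder apportionment so
they sum exactly to `n_genes`; identical configs (including seed) give
bit-identical output.

What the generator does **not** emulate: 3'UTR coverage bias of
amplified RNA, batch or sex effects, correlated genes, outlier
samples, or per-genotype effect heterogeneity.  Passing recovery tests
therefore demonstrates correctness of the inference pipeline under its
own model assumptions, not robustness to real-data pathologies.

## Problem sizes and numerics

Tests and the acceptance script use 2,000-gene simulations with 5
replicates per group (the package's standard demonstration size —
large enough for stable Monte-Carlo rates, small enough to run in
seconds), 100,000 uniform pairs for combination calibration, and 10^6
draws for Irwin–Hall tail checks.  Ties and degenerate cases: zero
variance ⇒ dispersion floor; all-zero genes ⇒ untested; `sign(0)` can
never pass the strict fold-change gates, so direction ties cannot
arise.  The Irwin–Hall inclusion–exclusion sum is numerically safe for
the small k (≤ 6) used here.

## Known limitations

* The Wald normal approximation is slightly anticonservative at very
  small replicate numbers (n ≤ 3/group) and low means.
* Dependence between the combined contrasts (shared groups) is ignored,
  as in the published rule.
* The rescue reversion rule compares point estimates of fold changes
  without propagating their uncertainty.
* Hypergeometric over-representation treats genes as exchangeable; no
  length/expression bias correction is attempted, and no annotation
  databases ship with the package.
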