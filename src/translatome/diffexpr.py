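"""Two-group negative-binomial differential expression.

A deliberately transparent stand-in for the DESeq2 stage whose output the
combination and classification stages consume: median-of-ratios size
factors, method-of-moments dispersions shrunk toward a 1/mean trend, and
a Wald test on log2 group-mean ratios with delta-method standard errors
from the NB variance ``mu + alpha * mu**2``.  No fold-change shrinkage,
no outlier refitting, no independent filtering — per-contrast tables
produced elsewhere (e.g. real DESeq2 runs) can be substituted anywhere a
``ContrastResult`` frame is accepted, as long as they carry the same
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ValidationError

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8
PSEUDOCOUNT = 0.5

#: column schema of a per-contrast result table
RESULT_COLUMNS = ("base_mean", "log2fc", "se", "p", "padj", "tested")


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast; log2fc reports group_b relative to group_a."""

    name: str
    group_a: tuple[str, str]  # (genotype, treatment) reference
    group_b: tuple[str, str]

    def reversed(self) -> "ContrastSpec":
        return ContrastSpec(self.name + ".rev", self.group_b, self.group_a)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over genes (expressed in
    every sample) of ``count_gj / geometric_mean_g(count)``.
    """
    vals = counts.to_numpy(dtype=float)
    expressed = (vals > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError(
            "no gene has nonzero counts in every sample; "
            "filter empty samples or genes before normalization"
        )
    logs = np.log(vals[expressed])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_geomean, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def _fit_dispersion_trend(alpha_mom: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mean, one outlier-trimming pass."""
    ok = np.isfinite(alpha_mom) & (alpha_mom > ALPHA_MIN) & (mean > 0)
    if ok.sum() < 10:
        return max(float(np.nanmedian(alpha_mom[ok])) if ok.any() else 0.01, 1e-6), 0.0
    x = 1.0 / mean[ok]
    y = alpha_mom[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
    keep = np.abs(resid - np.median(resid)) < 4.0 * 1.4826 * mad
    if 10 <= keep.sum() < keep.size:
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    a0 = max(float(coef[0]), 1e-6)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-gene NB dispersion from normalized counts.

    Method of moments on within-group residuals: ``alpha = (var - mean) /
    mean**2`` with variance pooled across groups, then geometric 50/50
    shrinkage toward a fitted ``a0 + a1/mean`` trend.  Genes with zero
    mean or zero variance are degenerate and pinned at ``ALPHA_MIN``.

    ``groups`` maps sample id -> group label; omitted, all samples form
    one group.
    """
    y = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy()
    if groups is None:
        labels = np.zeros(y.shape[1], dtype=int)
    else:
        labels = pd.Categorical(groups.loc[counts.columns]).codes
    mean = y.mean(axis=1)
    rss = np.zeros(y.shape[0])
    dof = 0
    for g in np.unique(labels):
        cols = labels == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        yg = y[:, cols]
        rss += ((yg - yg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += n_g - 1
    if dof < 1:
        raise ValidationError("dispersion estimation needs a group with >= 2 samples")
    var = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var - mean) / mean**2
    a0, a1 = _fit_dispersion_trend(alpha_mom, mean)
    with np.errstate(divide="ignore"):
        trend = np.maximum(a0 + a1 / np.maximum(mean, 1e-12), ALPHA_MIN)
    gene_wise = np.maximum(alpha_mom, ALPHA_MIN)
    alpha = np.exp(0.5 * np.log(gene_wise) + 0.5 * np.log(trend))
    alpha = np.maximum(alpha, ALPHA_MIN)
    degenerate = (mean <= 0) | (var <= 0)
    alpha[degenerate] = ALPHA_MIN
    return pd.Series(alpha, index=counts.index, name="alpha")


def wald_test(
    cm: CountMatrix,
    contrast: ContrastSpec,
    factors: pd.Series | None = None,
    alphas: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided Wald test of the log2 ratio of normalized group means.

    Returns a frame indexed by gene id with columns ``base_mean, log2fc,
    se, p, padj, tested``.  Genes with zero counts in both groups are
    flagged ``tested=False`` (p=1, log2fc=0).  A pseudocount of 0.5
    stabilizes the ratio; the SE follows by the delta method from the NB
    variance of each group mean.
    """
    samples_a = cm.samples(*contrast.group_a)
    samples_b = cm.samples(*contrast.group_b)
    for grp, smp in ((contrast.group_a, samples_a), (contrast.group_b, samples_b)):
        if len(smp) < 2:
            raise ValidationError(
                f"contrast {contrast.name!r}: group {grp} has {len(smp)} sample(s); "
                "need >= 2"
            )
    if factors is None:
        factors = size_factors(cm.counts)
    if alphas is None:
        alphas = estimate_dispersions(cm.counts, factors, cm.group_labels())

    counts = cm.counts
    alpha = alphas.loc[counts.index].to_numpy(dtype=float)

    def group_stats(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        s = factors.loc[samples].to_numpy()
        y = counts[samples].to_numpy(dtype=float) / s
        m = y.mean(axis=1)
        n = len(samples)
        # Var(K_j / s_j) = mu_j/s_j^2 + alpha*mu_j^2/s_j^2 with mu_j = s_j*m
        var_mean = (m[:, None] / s[None, :] + alpha[:, None] * m[:, None] ** 2).sum(
            axis=1
        ) / n**2
        return m, var_mean

    m_a, v_a = group_stats(samples_a)
    m_b, v_b = group_stats(samples_b)

    log2fc = np.log2((m_b + PSEUDOCOUNT) / (m_a + PSEUDOCOUNT))
    var_log = v_a / ((m_a + PSEUDOCOUNT) ** 2 * LN2**2) + v_b / (
        (m_b + PSEUDOCOUNT) ** 2 * LN2**2
    )
    se = np.sqrt(var_log)

    tested = counts[samples_a + samples_b].sum(axis=1).to_numpy() > 0
    p = np.ones(len(counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p[tested] = 2.0 * stats.norm.sf(np.abs(z[tested]))
    log2fc = np.where(tested, log2fc, 0.0)
    se = np.where(tested, se, np.nan)

    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    base_mean = np.concatenate(
        [
            counts[samples_a].to_numpy(float) / factors.loc[samples_a].to_numpy(),
            counts[samples_b].to_numpy(float) / factors.loc[samples_b].to_numpy(),
        ],
        axis=1,
    ).mean(axis=1)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "tested": tested,
        },
        index=counts.index,
    )


def run_contrasts(
    cm: CountMatrix,
    contrasts: list[ContrastSpec],
    factors: pd.Series | None = None,
    alphas: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Run several contrasts with shared size factors and dispersions."""
    if factors is None:
        factors = size_factors(cm.counts)
    if alphas is None:
        alphas = estimate_dispersions(cm.counts, factors, cm.group_labels())
    return {
        c.name: wald_test(cm, c, factors=factors, alphas=alphas) for c in contrasts
    }


def write_contrast_result(result: pd.DataFrame, path) -> None:
    out = result.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
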