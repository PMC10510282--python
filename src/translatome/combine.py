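"""Additive (Edgington) combination of p-values across contrasts.

The combined significance of k p-values is based on their sum S.  In
``paper`` mode the tail is ``min(1, S**k / k!)`` — the leading term of
the Irwin–Hall CDF, exact whenever S <= 1 and capped at 1 beyond its
domain of validity.  ``exact`` mode evaluates the full Irwin–Hall CDF
(the distribution of a sum of k independent uniforms) by
inclusion–exclusion.  The two agree to machine precision for S <= 1.

On top of the primitive sit the design-specific statistics: the
*rescue* p-value (baseline-vs-WT combined with ICD-vs-baseline), the
*effect* p-value (ICD-vs-WT combined with ICD-vs-baseline), the *vWT*
p-value (the two vs-WT contrasts, gated on concordant fold changes),
and the both-ICD combinations of the per-ICD statistics.
"""

from __future__ import annotations

from math import comb, factorial, fsum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import design

MODES = ("paper", "exact")
BOTH_MODES = ("nested-k2", "flat-k4")


def irwin_hall_cdf(s, k: int):
    """P(U_1 + ... + U_k <= s) for independent uniform(0,1) variables.

    Inclusion–exclusion closed form; vectorized over ``s``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    s_arr = np.asarray(s, dtype=float)
    out = np.zeros_like(s_arr)
    kfact = factorial(k)
    with np.errstate(invalid="ignore"):
        for j in range(k + 1):
            term = (-1) ** j * comb(k, j) * np.clip(s_arr - j, 0.0, None) ** k
            out = out + term
    out = np.clip(out / kfact, 0.0, 1.0)
    out = np.where(s_arr >= k, 1.0, out)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out)
    return out


def additive_combine(pvals: Iterable[float], mode: str = "paper") -> float:
    """Combine k p-values by the distribution of their sum.

    mode='paper': ``min(1, (sum p)**k / k!)``; mode='exact': Irwin–Hall
    CDF of the sum.  Inputs outside [0, 1] are rejected.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p.tolist()}")
    k = p.size
    s = fsum(p.tolist())
    if mode == "paper":
        return min(1.0, s**k / factorial(k))
    if mode == "exact":
        return irwin_hall_cdf(s, k)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _combine_columns(cols: list[np.ndarray], mode: str) -> np.ndarray:
    """Vectorized additive combination; NaN in any input propagates."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    stacked = np.column_stack(cols)
    finite = np.isfinite(stacked).all(axis=1)
    if np.any((stacked[finite] < 0) | (stacked[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = stacked.shape[1]
    s = stacked.sum(axis=1)
    if mode == "paper":
        out = np.minimum(1.0, s**k / factorial(k))
    else:
        out = irwin_hall_cdf(s, k)
    return np.where(finite, out, np.nan)


def _pcol(result: pd.DataFrame, index: pd.Index) -> np.ndarray:
    """Raw p aligned to ``index``; untested genes become NaN (never 1)."""
    r = result.reindex(index)
    p = r["p"].to_numpy(dtype=float)
    tested = r["tested"].fillna(False).to_numpy(dtype=bool)
    return np.where(tested, p, np.nan)


def _lfc_col(result: pd.DataFrame, index: pd.Index) -> np.ndarray:
    r = result.reindex(index)
    lfc = r["log2fc"].to_numpy(dtype=float)
    tested = r["tested"].fillna(False).to_numpy(dtype=bool)
    return np.where(tested, lfc, np.nan)


def rescue_pvalue(p_baseline_vs_wt: float, p_icd_vs_baseline: float,
                  mode: str = "paper") -> float:
    """Does the ICD revert a genotype effect?  Combines the baseline
    genotype-vs-WT p with the ICD-vs-baseline p (k=2)."""
    return additive_combine([p_baseline_vs_wt, p_icd_vs_baseline], mode=mode)


def effect_pvalue(p_icd_vs_wt: float, p_icd_vs_baseline: float,
                  mode: str = "paper") -> float:
    """Genotype-independent ICD effect: combines ICD-vs-WT with
    ICD-vs-baseline (k=2)."""
    return additive_combine([p_icd_vs_wt, p_icd_vs_baseline], mode=mode)


def vwt_pvalue(
    p_baseline_vs_wt: float,
    p_icd_vs_wt: float,
    lfc_baseline_vs_wt: float,
    lfc_icd_vs_wt: float,
    mode: str = "paper",
    lfc_gate: float = 0.58,
) -> float:
    """Combined vs-WT p-value, defined only when both fold changes vs WT
    (with and without the ICD) exceed the gate and share a sign;
    otherwise NaN."""
    if not (np.isfinite(lfc_baseline_vs_wt) and np.isfinite(lfc_icd_vs_wt)):
        return float("nan")
    if abs(lfc_baseline_vs_wt) <= lfc_gate or abs(lfc_icd_vs_wt) <= lfc_gate:
        return float("nan")
    if np.sign(lfc_baseline_vs_wt) != np.sign(lfc_icd_vs_wt):
        return float("nan")
    return additive_combine([p_baseline_vs_wt, p_icd_vs_wt], mode=mode)


def both_icd_pvalue(p_icd19: float, p_icdd19: float, mode: str = "paper") -> float:
    """Do both ICD variants rescue (or affect) the transcript?  k=2
    combination of the two already-combined per-ICD statistics."""
    if not (np.isfinite(p_icd19) and np.isfinite(p_icdd19)):
        return float("nan")
    return additive_combine([p_icd19, p_icdd19], mode=mode)


def combined_stats(
    results: Mapping[str, pd.DataFrame],
    mode: str = "paper",
    both_mode: str = "nested-k2",
    vwt_lfc_gate: float = 0.58,
) -> pd.DataFrame:
    """Rescue/effect/vWT/both-ICD statistics for every gene × genotype × ICD.

    ``results`` maps contrast names (see :mod:`translatome.design`) to
    per-contrast result frames.  Returns a long frame with one row per
    (gene_id, genotype, icd); the both-ICD columns are repeated on both
    ICD rows of a genotype.  Undefined values (untested inputs, failed
    vWT gate) are NaN.
    """
    if both_mode not in BOTH_MODES:
        raise ValueError(f"both_mode must be one of {BOTH_MODES}, got {both_mode!r}")
    first = next(iter(results.values()))
    index = first.index
    frames = []
    for geno in design.KO_GENOTYPES:
        base = results[design.baseline_name(geno)]
        p_base = _pcol(base, index)
        lfc_base = _lfc_col(base, index)
        per_icd: dict[str, dict[str, np.ndarray]] = {}
        for icd in design.ICDS:
            vs_base = results[design.icd_vs_baseline_name(geno, icd)]
            vs_wt = results[design.icd_vs_wt_name(geno, icd)]
            p_vs_base = _pcol(vs_base, index)
            p_vs_wt = _pcol(vs_wt, index)
            lfc_vs_wt = _lfc_col(vs_wt, index)
            rescue = _combine_columns([p_base, p_vs_base], mode)
            effect = _combine_columns([p_vs_wt, p_vs_base], mode)
            gate = (
                (np.abs(lfc_base) > vwt_lfc_gate)
                & (np.abs(lfc_vs_wt) > vwt_lfc_gate)
                & (np.sign(lfc_base) == np.sign(lfc_vs_wt))
            )
            vwt = np.where(gate, _combine_columns([p_base, p_vs_wt], mode), np.nan)
            per_icd[icd] = {
                "rescue_p": rescue,
                "effect_p": effect,
                "vwt_p": vwt,
                "p_vs_base": p_vs_base,
                "p_vs_wt": p_vs_wt,
            }
        if both_mode == "nested-k2":
            both_rescue = _combine_nan(
                [per_icd[i]["rescue_p"] for i in design.ICDS], mode
            )
            both_effect = _combine_nan(
                [per_icd[i]["effect_p"] for i in design.ICDS], mode
            )
            k_both = 2
        else:  # flat-k4 over the raw inputs of the two per-ICD pairs
            both_rescue = _combine_nan(
                [p_base, per_icd["ICD19"]["p_vs_base"],
                 p_base, per_icd["ICDd19"]["p_vs_base"]],
                mode,
            )
            both_effect = _combine_nan(
                [per_icd["ICD19"]["p_vs_wt"], per_icd["ICD19"]["p_vs_base"],
                 per_icd["ICDd19"]["p_vs_wt"], per_icd["ICDd19"]["p_vs_base"]],
                mode,
            )
            k_both = 4
        for icd in design.ICDS:
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": index,
                        "genotype": geno,
                        "icd": icd,
                        "rescue_p": per_icd[icd]["rescue_p"],
                        "effect_p": per_icd[icd]["effect_p"],
                        "vwt_p": per_icd[icd]["vwt_p"],
                        "both_rescue_p": both_rescue,
                        "both_effect_p": both_effect,
                        "k": 2,
                        "k_both": k_both,
                        "mode": mode,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _combine_nan(cols: list[np.ndarray], mode: str) -> np.ndarray:
    """Combine with NaN propagation (any undefined input -> undefined)."""
    return _combine_columns(cols, mode)


def write_combined_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)
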