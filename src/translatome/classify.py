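"""Transcript-level decision rules: basal, rescued, effected, shared module.

All rules operate on per-contrast fold changes / p-values and the
combined statistics, with the printed thresholds: p < 0.05 (strict),
|log2FC| > 0.58 (~1.5-fold, strict, the constant used verbatim), a
rescue reversion of at least 0.5 log2 units toward zero, and a relaxed
|log2FC| > 0.5 for the shared cross-genotype module.

A transcript is *rescued* by an ICD when (1) the rescue p-value is
below 0.05, (2) its Cre baseline deviates from wild type by more than
0.58 log2 units, and (3) adding the ICD moves the vs-WT fold change at
least 0.5 log2 units closer to zero (overshooting past zero still
counts).  It is *effected* by an ICD when the effect or rescue p-value
is below 0.05 and the ICD group differs from both WT and its own Cre
baseline by more than 0.58 log2 units; the direction is the sign of the
ICD-vs-baseline change.  It is a *basal* difference when its baseline
deviates by more than 0.58 log2 units and any of the plain, rescue, or
vWT p-values is below 0.05 — so every rescued transcript is basal by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design


@dataclass(frozen=True)
class Thresholds:
    """Decision constants (defaults are the printed values)."""

    p: float = 0.05
    lfc: float = 0.58
    reversion_delta: float = 0.5
    relaxed_lfc: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p", "lfc", "reversion_delta", "relaxed_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


DEFAULT_THRESHOLDS = Thresholds()


def classify_rescued(
    rescue_p: float,
    lfc_baseline_vs_wt: float,
    lfc_icd_vs_wt: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool | None:
    """True iff all three rescue criteria hold; None if unclassifiable."""
    if not all(
        np.isfinite(v) for v in (rescue_p, lfc_baseline_vs_wt, lfc_icd_vs_wt)
    ):
        return None
    return bool(
        rescue_p < thresholds.p
        and abs(lfc_baseline_vs_wt) > thresholds.lfc
        and abs(lfc_icd_vs_wt) <= abs(lfc_baseline_vs_wt) - thresholds.reversion_delta
    )


def classify_effected(
    effect_p: float,
    rescue_p: float,
    lfc_icd_vs_wt: float,
    lfc_icd_vs_baseline: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str | None:
    """'up'/'down'/'none'; None if the needed inputs are unavailable.

    The p gate accepts either the effect or the rescue combined p-value;
    a missing one simply cannot open the gate.
    """
    if not (np.isfinite(lfc_icd_vs_wt) and np.isfinite(lfc_icd_vs_baseline)):
        return None
    if not (np.isfinite(effect_p) or np.isfinite(rescue_p)):
        return None
    p_ok = (np.isfinite(effect_p) and effect_p < thresholds.p) or (
        np.isfinite(rescue_p) and rescue_p < thresholds.p
    )
    if (
        p_ok
        and abs(lfc_icd_vs_wt) > thresholds.lfc
        and abs(lfc_icd_vs_baseline) > thresholds.lfc
    ):
        return "up" if lfc_icd_vs_baseline > 0 else "down"
    return "none"


def classify_basal(
    lfc_baseline_vs_wt: float,
    p_baseline_vs_wt: float,
    rescue_ps=(),
    vwt_ps=(),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str | None:
    """'up'/'down'/'none' basal call; None when the baseline is untested.

    The significance gate takes the minimum over every available route:
    the plain baseline p, the rescue p of either ICD, the vWT p of
    either ICD.
    """
    if not (np.isfinite(lfc_baseline_vs_wt) and np.isfinite(p_baseline_vs_wt)):
        return None
    candidates = [p_baseline_vs_wt]
    candidates += [p for p in rescue_ps if np.isfinite(p)]
    candidates += [p for p in vwt_ps if np.isfinite(p)]
    if abs(lfc_baseline_vs_wt) > thresholds.lfc and min(candidates) < thresholds.p:
        return "up" if lfc_baseline_vs_wt > 0 else "down"
    return "none"


def classification_table(
    results: dict[str, pd.DataFrame],
    combined: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format classification: one row per gene × genotype.

    Columns carry every fold change / p-value the rules consumed plus
    the labels: ``basal`` ∈ {up, down, none, NA}, per-ICD ``rescued_*``
    booleans, per-ICD ``effected_*`` directions, ``rescued_both``,
    ``shared_module`` with its direction.  Rows are ordered by genotype
    (design order) then gene id; re-running on identical inputs yields a
    byte-identical table.
    """
    first = next(iter(results.values()))
    index = first.index
    blocks = []
    for geno in design.KO_GENOTYPES:
        base = results[design.baseline_name(geno)].reindex(index)
        tested = base["tested"].fillna(False).to_numpy(bool)
        lfc_base = np.where(tested, base["log2fc"].to_numpy(float), np.nan)
        p_base = np.where(tested, base["p"].to_numpy(float), np.nan)
        block = pd.DataFrame({"gene_id": index, "genotype": geno})
        block["lfc_vs_wt"] = lfc_base
        block["p_vs_wt"] = p_base
        for icd in design.ICDS:
            sub = combined[(combined["genotype"] == geno) & (combined["icd"] == icd)]
            sub = sub.set_index("gene_id").reindex(index)
            vs_wt = results[design.icd_vs_wt_name(geno, icd)].reindex(index)
            vs_b = results[design.icd_vs_baseline_name(geno, icd)].reindex(index)
            t_wt = vs_wt["tested"].fillna(False).to_numpy(bool)
            t_b = vs_b["tested"].fillna(False).to_numpy(bool)
            lfc_icd_wt = np.where(t_wt, vs_wt["log2fc"].to_numpy(float), np.nan)
            lfc_icd_b = np.where(t_b, vs_b["log2fc"].to_numpy(float), np.nan)
            block[f"lfc_{icd}_vs_wt"] = lfc_icd_wt
            block[f"p_{icd}_vs_wt"] = np.where(t_wt, vs_wt["p"].to_numpy(float), np.nan)
            block[f"lfc_{icd}_vs_base"] = lfc_icd_b
            block[f"p_{icd}_vs_base"] = np.where(
                t_b, vs_b["p"].to_numpy(float), np.nan
            )
            rescue_p = sub["rescue_p"].to_numpy(float)
            effect_p = sub["effect_p"].to_numpy(float)
            vwt_p = sub["vwt_p"].to_numpy(float)
            block[f"rescue_p_{icd}"] = rescue_p
            block[f"effect_p_{icd}"] = effect_p
            block[f"vwt_p_{icd}"] = vwt_p
            # vectorized rescue rule
            inputs_ok = (
                np.isfinite(rescue_p) & np.isfinite(lfc_base) & np.isfinite(lfc_icd_wt)
            )
            rescued = (
                inputs_ok
                & (rescue_p < thresholds.p)
                & (np.abs(lfc_base) > thresholds.lfc)
                & (
                    np.abs(lfc_icd_wt)
                    <= np.abs(lfc_base) - thresholds.reversion_delta
                )
            )
            block[f"rescued_{icd}"] = np.where(
                inputs_ok, np.where(rescued, "True", "False"), "NA"
            )
            # vectorized effect rule
            e_inputs_ok = np.isfinite(lfc_icd_wt) & np.isfinite(lfc_icd_b) & (
                np.isfinite(effect_p) | np.isfinite(rescue_p)
            )
            p_ok = (np.isfinite(effect_p) & (effect_p < thresholds.p)) | (
                np.isfinite(rescue_p) & (rescue_p < thresholds.p)
            )
            effected = (
                e_inputs_ok
                & p_ok
                & (np.abs(lfc_icd_wt) > thresholds.lfc)
                & (np.abs(lfc_icd_b) > thresholds.lfc)
            )
            block[f"effected_{icd}"] = np.where(
                ~e_inputs_ok,
                "NA",
                np.where(effected, np.where(lfc_icd_b > 0, "up", "down"), "none"),
            )
        both = combined[
            (combined["genotype"] == geno) & (combined["icd"] == design.ICDS[0])
        ].set_index("gene_id").reindex(index)
        block["both_rescue_p"] = both["both_rescue_p"].to_numpy(float)
        block["both_effect_p"] = both["both_effect_p"].to_numpy(float)
        r19 = block[f"rescued_{design.ICDS[0]}"]
        rd19 = block[f"rescued_{design.ICDS[1]}"]
        block["rescued_both"] = np.where(
            (r19 == "NA") | (rd19 == "NA"),
            "NA",
            np.where((r19 == "True") & (rd19 == "True"), "True", "False"),
        )
        # basal: lfc gate + min over available significance routes
        route = p_base.copy()
        for icd in design.ICDS:
            for col in (f"rescue_p_{icd}", f"vwt_p_{icd}"):
                cand = block[col].to_numpy(float)
                route = np.where(
                    np.isfinite(cand) & ~(route <= cand), cand, route
                )
        basal_ok = np.isfinite(lfc_base) & np.isfinite(p_base)
        basal_sig = (
            basal_ok & (np.abs(lfc_base) > thresholds.lfc) & (route < thresholds.p)
        )
        block["basal"] = np.where(
            ~basal_ok,
            "NA",
            np.where(basal_sig, np.where(lfc_base > 0, "up", "down"), "none"),
        )
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    up_set, down_set = shared_module_set(table, thresholds)
    shared = table["gene_id"].isin(up_set | down_set)
    table["shared_module"] = np.where(shared, "True", "False")
    # genotype in design order, not lexicographic
    order = {g: i for i, g in enumerate(design.KO_GENOTYPES)}
    table = table.sort_values(
        by=["genotype", "gene_id"],
        key=lambda s: s.map(order) if s.name == "genotype" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def shared_module_set(
    table: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[set, set]:
    """Cross-genotype shared-module genes under the relaxed criterion.

    A gene belongs when it is basal-significant (full criteria) in at
    least one genotype and |log2FC vs WT| exceeds the relaxed threshold
    with one consistent sign in *all three* genotypes.  Returns (up,
    down) gene-id sets.
    """
    wide_lfc = table.pivot(index="gene_id", columns="genotype", values="lfc_vs_wt")
    wide_basal = table.pivot(index="gene_id", columns="genotype", values="basal")
    genos = list(design.KO_GENOTYPES)
    lfc = wide_lfc[genos].to_numpy(float)
    sig_any = (wide_basal[genos].isin(["up", "down"])).any(axis=1).to_numpy()
    all_up = (lfc > thresholds.relaxed_lfc).all(axis=1)
    all_down = (lfc < -thresholds.relaxed_lfc).all(axis=1)
    genes = wide_lfc.index.to_numpy()
    up = set(genes[sig_any & all_up])
    down = set(genes[sig_any & all_down])
    return up, down


def label_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype counts of each label, for quick inspection."""
    rows = []
    for geno, sub in table.groupby("genotype", sort=False):
        row = {"genotype": geno}
        row["basal_up"] = int((sub["basal"] == "up").sum())
        row["basal_down"] = int((sub["basal"] == "down").sum())
        for icd in design.ICDS:
            row[f"rescued_{icd}"] = int((sub[f"rescued_{icd}"] == "True").sum())
            row[f"effected_{icd}_up"] = int((sub[f"effected_{icd}"] == "up").sum())
            row[f"effected_{icd}_down"] = int(
                (sub[f"effected_{icd}"] == "down").sum()
            )
        row["rescued_both"] = int((sub["rescued_both"] == "True").sum())
        row["shared_module"] = int((sub["shared_module"] == "True").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def write_classification(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
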