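"""End-to-end pipeline: DE -> combination -> classification -> reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classify, combine, design, diffexpr, enrichment
from .io import CountMatrix, ValidationError, read_counts

log = logging.getLogger("translatome")


@dataclass
class RunConfig:
    counts: str
    sample_sheet: str
    out_dir: str
    gene_sets: str | None = None
    p_thresh: float = 0.05
    lfc_thresh: float = 0.58
    reversion_delta: float = 0.5
    relaxed_lfc: float = 0.5
    combine_mode: str = "paper"
    both_icd_mode: str = "nested-k2"
    seed: int = 0

    def thresholds(self) -> classify.Thresholds:
        return classify.Thresholds(
            p=self.p_thresh,
            lfc=self.lfc_thresh,
            reversion_delta=self.reversion_delta,
            relaxed_lfc=self.relaxed_lfc,
        )

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def analyze(
    cm: CountMatrix,
    thresholds: classify.Thresholds | None = None,
    combine_mode: str = "paper",
    both_icd_mode: str = "nested-k2",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Run DE, combination, and classification on a count matrix.

    Returns (per-contrast results, combined statistics, classification
    table).  All stages are deterministic given the input counts.
    """
    thresholds = thresholds or classify.DEFAULT_THRESHOLDS
    contrasts = design.standard_contrasts()
    results = diffexpr.run_contrasts(cm, contrasts)
    combined = combine.combined_stats(
        results,
        mode=combine_mode,
        both_mode=both_icd_mode,
        vwt_lfc_gate=thresholds.lfc,
    )
    table = classify.classification_table(results, combined, thresholds)
    return results, combined, table


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write every stage's TSV outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("translatome %s | config %s | seed %d",
                 __version__, config.digest(), config.seed)
        cm = read_counts(config.counts, config.sample_sheet)
        log.info("loaded %d genes x %d samples", len(cm.gene_ids), len(cm.sample_ids))
        results, combined, table = analyze(
            cm,
            thresholds=config.thresholds(),
            combine_mode=config.combine_mode,
            both_icd_mode=config.both_icd_mode,
        )
        de_dir = out / "contrasts"
        de_dir.mkdir(exist_ok=True)
        for name, res in results.items():
            diffexpr.write_contrast_result(res, de_dir / f"{name}.tsv")
        combine.write_combined_stats(combined, out / "combined_stats.tsv")
        classify.write_classification(table, out / "classification.tsv")
        classify.label_summary(table).to_csv(
            out / "label_summary.tsv", sep="\t", index=False
        )
        if config.gene_sets:
            sets = enrichment.read_gene_sets(config.gene_sets)
            universe = set(cm.gene_ids)
            up, down = classify.shared_module_set(table, config.thresholds())
            for name, query in (("shared_up", up), ("shared_down", down)):
                if query:
                    enr = enrichment.hypergeom_enrichment(query, sets, universe)
                    enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
            basal_sets = {
                geno: set(
                    table.loc[
                        (table["genotype"] == geno)
                        & table["basal"].isin(["up", "down"]),
                        "gene_id",
                    ]
                )
                for geno in design.KO_GENOTYPES
            }
            if all(basal_sets.values()):
                part = enrichment.overlap_partition(basal_sets)
                part.to_csv(out / "basal_overlap.tsv", sep="\t", index=False)
        log.info("pipeline complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
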