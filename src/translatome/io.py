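"""Count-matrix and sample-sheet I/O with factorial-design validation.

Counts are exchanged in the featureCounts tab-separated dialect: an
optional ``#`` comment header, a ``Geneid`` first column, optional
annotation columns (Chr, Start, End, Strand, Length), then one integer
column per sample.  Sample sheets assign every sample a genotype and a
treatment from the closed design vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "cKO", "D16p19", "D16d19")
TREATMENTS = ("Cre", "ICD19", "ICDd19")

#: annotation columns featureCounts emits ahead of the sample counts
FEATURECOUNTS_ANNOTATION = ("Chr", "Start", "End", "Strand", "Length")


class ValidationError(ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


@dataclass
class CountMatrix:
    """Integer gene × sample count table plus per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    sample_meta
        DataFrame indexed by sample id with at least ``genotype`` and
        ``treatment`` columns drawn from the design vocabularies.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------

    def validate(self) -> None:
        genes = self.counts.index
        if genes.has_duplicates:
            dup = genes[genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        samples = self.counts.columns
        if samples.has_duplicates:
            dup = samples[samples.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        missing_meta = [s for s in samples if s not in self.sample_meta.index]
        extra_meta = [s for s in self.sample_meta.index if s not in samples]
        if missing_meta or extra_meta:
            raise ValidationError(
                "sample sheet / count matrix mismatch: "
                f"missing from sheet {missing_meta}, missing from counts {extra_meta}"
            )
        for col in ("genotype", "treatment"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample sheet lacks required column {col!r}")
        bad_geno = set(self.sample_meta["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(
                f"unknown genotype(s) {sorted(bad_geno)}; allowed: {list(GENOTYPES)}"
            )
        bad_treat = set(self.sample_meta["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise ValidationError(
                f"unknown treatment(s) {sorted(bad_treat)}; allowed: {list(TREATMENTS)}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac = np.mod(vals.astype(float), 1.0)
            bad = np.argwhere((frac != 0) | ~np.isfinite(vals.astype(float)))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {genes[i]!r}, sample {samples[j]!r}: "
                    f"{vals[i, j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {genes[i]!r}, sample {samples[j]!r}"
            )
        # keep metadata aligned to count-column order
        self.sample_meta = self.sample_meta.loc[list(samples)]

    # -- convenience ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples(self, genotype: str, treatment: str) -> list[str]:
        """Sample ids belonging to one (genotype, treatment) group."""
        m = self.sample_meta
        sel = (m["genotype"] == genotype) & (m["treatment"] == treatment)
        return list(m.index[sel])

    def group_sizes(self) -> pd.Series:
        return self.sample_meta.groupby(["genotype", "treatment"]).size()

    def group_labels(self) -> pd.Series:
        """Per-sample '<genotype>.<treatment>' label, count-column order."""
        m = self.sample_meta
        return m["genotype"].str.cat(m["treatment"], sep=".")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a CSV/TSV sample sheet (sample_id, genotype, treatment, ...)."""
    sheet = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    required = {"sample_id", "genotype", "treatment"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet {path} lacks columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dup}")
    return sheet.set_index("sample_id")


def read_counts(path, sample_sheet_path) -> CountMatrix:
    """Read a featureCounts-style TSV plus sample sheet into a CountMatrix.

    featureCounts annotation columns are tolerated and dropped; count
    columns are reordered to sample-sheet order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "Geneid":
        raise ValidationError(
            f"count file {path} must have 'Geneid' as first column, "
            f"found {df.columns[0]!r}"
        )
    df = df.set_index("Geneid")
    df = df.drop(columns=[c for c in FEATURECOUNTS_ANNOTATION if c in df.columns])
    meta = read_sample_sheet(sample_sheet_path)
    missing = [s for s in meta.index if s not in df.columns]
    extra = [s for s in df.columns if s not in meta.index]
    if missing or extra:
        raise ValidationError(
            f"count columns do not match sample sheet: sheet-only {missing}, "
            f"counts-only {extra}"
        )
    df = df[list(meta.index)]
    return CountMatrix(counts=df, sample_meta=meta)


def write_counts(cm: CountMatrix, path) -> None:
    """Write counts as featureCounts-style TSV (Geneid + sample columns)."""
    out = cm.counts.copy()
    out.insert(0, "Geneid", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_sample_sheet(cm: CountMatrix, path) -> None:
    out = cm.sample_meta.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
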