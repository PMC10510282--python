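"""Synthetic TRAP-seq counts for the 4 genotype × 3 treatment design.

Generates gene × sample negative-binomial counts with mean-dependent
dispersion and planted gene classes, so every downstream stage (DE →
combination → classification) can be scored against ground truth:

* ``null`` — no change anywhere;
* ``basal_up_rescued_both`` / ``basal_down_rescued_both`` — shifted at
  the Cre baseline of every non-WT genotype, reverted by both ICDs;
* ``basal_rescued_p19_only`` / ``basal_rescued_d19_only`` — reverted by
  one splice variant only;
* ``basal_not_rescued`` — shifted at baseline and under both ICDs;
* ``effect_only`` — unchanged at baseline, shifted in every ICD-treated
  group (including WT).

Counts are gamma–Poisson draws (NB with size 1/alpha), the same model
the differential stage assumes, with per-sample library-size factors
drawn log-uniform in [0.5, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd
import yaml

from .io import GENOTYPES, TREATMENTS, CountMatrix, ValidationError

CLASS_LABELS = (
    "null",
    "basal_up_rescued_both",
    "basal_down_rescued_both",
    "basal_rescued_p19_only",
    "basal_rescued_d19_only",
    "basal_not_rescued",
    "effect_only",
)

KO_GENOTYPES = ("cKO", "D16p19", "D16d19")
ICDS = ("ICD19", "ICDd19")

DEFAULT_CLASS_PROPORTIONS = {
    "null": 0.70,
    "basal_up_rescued_both": 0.05,
    "basal_down_rescued_both": 0.05,
    "basal_rescued_p19_only": 0.04,
    "basal_rescued_d19_only": 0.04,
    "basal_not_rescued": 0.06,
    "effect_only": 0.06,
}


def _default_replicates() -> dict[tuple[str, str], int]:
    return {(g, t): 5 for g in GENOTYPES for t in TREATMENTS}


@dataclass
class SimConfig:
    """Configuration of one simulated experiment.

    Defaults emulate a filtered bulk TRAP-seq experiment: baseline means
    log-uniform between 50 and 5000, dispersion trend
    ``alpha(mu) = a0 + a1/mu`` with a0=0.04 and a1=1.0, planted
    |log2FC| of 1.5 fully reverted by a rescuing ICD, and 5 replicates
    in each of the 12 groups.
    """

    n_genes: int = 2000
    replicates_per_group: dict = field(default_factory=_default_replicates)
    baseline_mean_log_range: tuple[float, float] = (log(50.0), log(5000.0))
    dispersion_intercept: float = 0.04
    dispersion_slope: float = 1.0
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    lfc_magnitude: float = 1.5
    rescue_reversion: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.dispersion_intercept <= 0 or self.dispersion_slope < 0:
            raise ValidationError(
                "dispersion must satisfy alpha(mu) > 0: intercept > 0, slope >= 0"
            )
        if not 0.0 <= self.rescue_reversion <= 1.0:
            raise ValidationError("rescue_reversion must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ValidationError("lfc_magnitude must be positive")
        lo, hi = self.baseline_mean_log_range
        if not lo <= hi:
            raise ValidationError("baseline_mean_log_range must be ordered (lo, hi)")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        unknown = set(self.class_proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValidationError(f"unknown class labels: {sorted(unknown)}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        for g in GENOTYPES:
            for t in TREATMENTS:
                n = self.replicates_per_group.get((g, t), 0)
                if n < 2:
                    raise ValidationError(
                        f"group ({g}, {t}) needs >= 2 replicates, got {n}"
                    )


def nb_draws(rng: np.random.Generator, mu, alpha):
    """NB(mu, alpha) via gamma–Poisson: variance mu + alpha*mu**2."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu <= 0) or np.any(alpha <= 0):
        raise ValidationError("nb_draws needs mu > 0 and alpha > 0")
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _class_counts(props: dict, n_genes: int) -> dict[str, int]:
    """Largest-remainder apportionment so counts sum exactly to n_genes."""
    labels = [c for c in CLASS_LABELS if props.get(c, 0.0) > 0]
    raw = {c: props[c] * n_genes for c in labels}
    counts = {c: int(np.floor(raw[c])) for c in labels}
    short = n_genes - sum(counts.values())
    by_rem = sorted(labels, key=lambda c: (raw[c] - counts[c], c), reverse=True)
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def expected_lfc_profile(
    label: str, sign: float, lfc: float, reversion: float
) -> dict[tuple[str, str], float]:
    """Planted log2FC of every (genotype, treatment) group vs WT.Cre."""
    prof = {(g, t): 0.0 for g in GENOTYPES for t in TREATMENTS}
    if label == "null":
        return prof
    base = sign * lfc
    residual = (1.0 - reversion) * base
    if label == "effect_only":
        for g in GENOTYPES:
            for icd in ICDS:
                prof[(g, icd)] = base
        return prof
    for g in KO_GENOTYPES:
        prof[(g, "Cre")] = base
        if label in ("basal_up_rescued_both", "basal_down_rescued_both"):
            prof[(g, "ICD19")] = residual
            prof[(g, "ICDd19")] = residual
        elif label == "basal_rescued_p19_only":
            prof[(g, "ICD19")] = residual
            prof[(g, "ICDd19")] = base
        elif label == "basal_rescued_d19_only":
            prof[(g, "ICD19")] = base
            prof[(g, "ICDd19")] = residual
        elif label == "basal_not_rescued":
            prof[(g, "ICD19")] = base
            prof[(g, "ICDd19")] = base
    return prof


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one experiment; returns (CountMatrix, truth frame).

    The truth frame is row-aligned with the counts and carries
    ``class_label``, the planted sign, and one ``lfc_<genotype>.<treatment>``
    column per group with the expected log2FC vs WT.Cre.  Identical
    config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = [(g, t) for g in GENOTYPES for t in TREATMENTS]
    sample_ids, sample_geno, sample_treat = [], [], []
    for g, t in groups:
        for r in range(config.replicates_per_group[(g, t)]):
            sample_ids.append(f"{g}.{t}.rep{r + 1}")
            sample_geno.append(g)
            sample_treat.append(t)
    n_samples = len(sample_ids)

    counts_per_class = _class_counts(config.class_proportions, config.n_genes)
    labels = np.concatenate(
        [np.repeat(c, n) for c, n in counts_per_class.items()]
    )
    rng.shuffle(labels)

    # per-gene planted sign: classes named up/down are pinned, others random
    signs = np.where(rng.random(config.n_genes) < 0.5, 1.0, -1.0)
    signs[labels == "basal_up_rescued_both"] = 1.0
    signs[labels == "basal_down_rescued_both"] = -1.0

    lo, hi = config.baseline_mean_log_range
    baseline = np.exp(rng.uniform(lo, hi, size=config.n_genes))
    lib_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))

    # expected lfc per gene per group, from the per-class profile
    lfc = np.zeros((config.n_genes, len(groups)))
    profiles = {
        (lab, s): expected_lfc_profile(
            lab, s, config.lfc_magnitude, config.rescue_reversion
        )
        for lab in counts_per_class
        for s in (1.0, -1.0)
    }
    for gi, (lab, s) in enumerate(zip(labels, signs)):
        prof = profiles[(lab, s)]
        lfc[gi, :] = [prof[grp] for grp in groups]

    group_of_sample = [groups.index((g, t)) for g, t in zip(sample_geno, sample_treat)]
    mu = (
        baseline[:, None]
        * 2.0 ** lfc[:, group_of_sample]
        * lib_factors[None, :]
    )
    if np.any(mu <= 0):
        raise ValidationError("non-positive simulated mean")
    alpha = config.dispersion_intercept + config.dispersion_slope / mu
    counts = nb_draws(rng, mu, alpha)

    gene_ids = [f"gene{str(i + 1).zfill(5)}" for i in range(config.n_genes)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "Geneid"
    meta = pd.DataFrame(
        {
            "genotype": sample_geno,
            "treatment": sample_treat,
            # simulation ground truth, carried as an extra metadata column
            "lib_size_factor": lib_factors,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(counts=counts_df, sample_meta=meta)

    truth = pd.DataFrame(
        {"class_label": labels, "sign": signs, "baseline_mean": baseline},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for j, (g, t) in enumerate(groups):
        truth[f"lfc_{g}.{t}"] = lfc[:, j]
    return cm, truth


def truth_lfc(truth: pd.DataFrame, genotype: str, treatment: str) -> pd.Series:
    return truth[f"lfc_{genotype}.{treatment}"]


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    """Read a written truth table ('null' must survive NA sniffing)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["sign"] = df["sign"].astype(float)
    num = [c for c in df.columns if c.startswith("lfc_") or c == "baseline_mean"]
    df[num] = df[num].astype(float)
    return df.set_index("gene_id")


def config_from_file(path) -> SimConfig:
    """Load a SimConfig from a YAML/JSON key-value file.

    ``replicates_per_group`` may be a single integer (applied to every
    group) or a mapping with '<genotype>.<treatment>' keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimConfig()
    if "replicates_per_group" in raw:
        reps = raw.pop("replicates_per_group")
        if isinstance(reps, int):
            cfg.replicates_per_group = {
                (g, t): reps for g in GENOTYPES for t in TREATMENTS
            }
        else:
            table = dict(cfg.replicates_per_group)
            for key, n in reps.items():
                g, t = key.split(".")
                table[(g, t)] = int(n)
            cfg.replicates_per_group = table
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown simulation config key {key!r}")
        if key == "baseline_mean_log_range":
            value = tuple(float(v) for v in value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
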