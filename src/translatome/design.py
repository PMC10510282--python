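"""The 4 genotype × 3 treatment factorial design and its standard contrasts.

Genotypes: wild type (WT), conditional knockout (cKO), and the two
cleavage-resistant knock-ins with or without exon 19 (D16p19, D16d19).
Treatments: Cre-only lentivirus (Cre) or Cre plus one of the two
receptor intracellular-domain splice variants (ICD19, ICDd19).  The
global reference group is WT.Cre.
"""

from __future__ import annotations

from .diffexpr import ContrastSpec
from .io import GENOTYPES, TREATMENTS  # noqa: F401  (re-exported)

#: genotypes compared against wild type
KO_GENOTYPES = ("cKO", "D16p19", "D16d19")
#: the two intracellular-domain splice variants used as treatments
ICDS = ("ICD19", "ICDd19")
REFERENCE = ("WT", "Cre")


def baseline_name(genotype: str) -> str:
    return f"{genotype}.Cre_vs_WT.Cre"


def icd_vs_baseline_name(genotype: str, icd: str) -> str:
    return f"{genotype}.{icd}_vs_{genotype}.Cre"


def icd_vs_wt_name(genotype: str, icd: str) -> str:
    return f"{genotype}.{icd}_vs_WT.Cre"


def standard_contrasts(include_wt_icd: bool = True) -> list[ContrastSpec]:
    """Every contrast the rescue/effect/vWT statistics consume.

    Per non-WT genotype: its Cre baseline vs WT.Cre, each ICD vs its own
    Cre baseline, and each ICD vs WT.Cre.  With ``include_wt_icd`` the
    two WT overexpression contrasts (WT.ICD vs WT.Cre) are appended,
    mirroring the design's "every condition vs the WT-Cre reference".
    """
    specs: list[ContrastSpec] = []
    for geno in KO_GENOTYPES:
        specs.append(ContrastSpec(baseline_name(geno), REFERENCE, (geno, "Cre")))
        for icd in ICDS:
            specs.append(
                ContrastSpec(icd_vs_baseline_name(geno, icd), (geno, "Cre"), (geno, icd))
            )
            specs.append(
                ContrastSpec(icd_vs_wt_name(geno, icd), REFERENCE, (geno, icd))
            )
    if include_wt_icd:
        for icd in ICDS:
            specs.append(
                ContrastSpec(icd_vs_wt_name("WT", icd), REFERENCE, ("WT", icd))
            )
    return specs
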