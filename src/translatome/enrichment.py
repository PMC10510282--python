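"""Set-overlap partitioning and hypergeometric over-representation.

Database-free downstream summaries: exact exclusive-region counts for
up to six gene lists (the numbers a supervenn diagram displays) and a
one-sided hypergeometric over-representation test against user-supplied
annotation sets (GMT or two-column format) with Benjamini–Hochberg
correction.  This is deliberately not a reimplementation of any
web-based enrichment service; it computes the same statistic those
services report, on whatever gene sets the user provides.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ValidationError


def read_gmt(path) -> dict[str, set]:
    """Read GMT gene sets (set name, description, genes...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_two_column(path) -> dict[str, set]:
    """Read gene→set annotations from a two-column (gene, set) table."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["gene", "set"], dtype=str, comment="#")
    sets: dict[str, set] = {}
    for set_id, sub in df.groupby("set"):
        sets[str(set_id)] = set(sub["gene"])
    return sets


def read_gene_sets(path) -> dict[str, set]:
    """Dispatch on content: GMT if any line has >= 3 tab fields."""
    with open(path) as fh:
        first = fh.readline()
    if first.count("\t") >= 2:
        return read_gmt(path)
    return read_two_column(path)


def overlap_partition(named_sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Exclusive-region counts for every nonempty membership pattern.

    For m input sets, returns one row per each of the 2^m − 1 patterns
    (ordered by the binary pattern over the input set order), with one
    boolean column per set and a ``count`` column.  Counts sum to the
    size of the union.
    """
    names = list(named_sets)
    m = len(names)
    if not 2 <= m <= 6:
        raise ValidationError(f"overlap partition needs 2-6 sets, got {m}")
    sets = {n: set(named_sets[n]) for n in names}
    union = set().union(*sets.values())
    tally: dict[tuple[bool, ...], int] = {}
    for gene in union:
        pattern = tuple(gene in sets[n] for n in names)
        tally[pattern] = tally.get(pattern, 0) + 1
    rows = []
    for bits in product([True, False], repeat=m):
        if not any(bits):
            continue
        row = dict(zip(names, bits))
        row["count"] = tally.get(bits, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def hypergeom_enrichment(
    query: Iterable,
    annotation_sets: Mapping[str, Iterable],
    universe: Iterable,
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each annotation set.

    Genes are intersected with the universe first; p is the upper tail
    P(X >= k) of Hypergeometric(N, K, n), BH-adjusted across sets.
    Columns: set_id, k (overlap), K (set size), n (query size),
    N (universe size), p, padj_bh.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    q = set(query) & uni
    rows = []
    for set_id in sorted(annotation_sets):
        ann = set(annotation_sets[set_id]) & uni
        k = len(q & ann)
        # survival function at k-1 gives P(X >= k)
        p = float(hypergeom.sf(k - 1, len(uni), len(ann), len(q)))
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "K": len(ann),
                "n": len(q),
                "N": len(uni),
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["padj_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj_bh"] = []
    return table
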