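"""Single-sample gene-set scoring (ssGSEA) for immune / stromal signatures.

Scores are rank-based per sample: a weighted Kolmogorov–Smirnov-like sum of
differences between the in-set and out-of-set empirical CDFs over the
sample's expression ranking.  Because only within-sample ranks enter, the
scores are invariant to any per-sample monotone transform of expression.
No cross-sample normalisation is applied: downstream use is limited to
between-group contrasts and correlations, which are normalisation-free.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "score_group_test",
]


class GeneSetCollection(dict):
    """Named gene sets: mapping set name -> list of gene identifiers."""

    def __init__(self, sets: dict[str, list[str]], source: str = ""):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        super().__init__(sets)
        self.source = source


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
    return GeneSetCollection(sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def ssgsea_score(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    exponent: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA enrichment score of each gene set in each sample.

    Per sample, genes are ranked by expression (descending walk, average
    ranks for ties used as weights).  The score is the sum over the walk of
    the weighted in-set ECDF (weights = rank^exponent) minus the uniform
    out-of-set ECDF.

    Returns a samples x sets DataFrame; a column named ``immune`` (or
    ``stromal``) plays the role of the immune (stromal) score downstream.
    """
    gene_index = pd.Index(expr.index)
    memberships = {}
    for name, members in sets.items():
        mask = gene_index.isin(set(members)).astype(np.float64)
        if mask.sum() == 0:
            raise KeyError(f"gene set {name!r} has zero overlap with expression rows")
        memberships[name] = mask

    x = expr.to_numpy()
    n_genes, n_samples = x.shape
    # ascending average ranks, so the most expressed gene gets rank ~ n_genes
    ranks = stats.rankdata(x, axis=0)
    weights = ranks**exponent
    # walk order: descending expression
    order = np.argsort(-x, axis=0, kind="stable")

    out = np.zeros((n_samples, len(memberships)))
    for j, (name, mask) in enumerate(memberships.items()):
        n_out = n_genes - int(mask.sum())
        for s in range(n_samples):
            o = order[:, s]
            in_set = mask[o]
            w = weights[o, s] * in_set
            cum_in = np.cumsum(w)
            total_in = cum_in[-1]
            ecdf_in = cum_in / total_in if total_in > 0 else np.zeros(n_genes)
            if n_out > 0:
                ecdf_out = np.cumsum(1.0 - in_set) / n_out
            else:
                ecdf_out = np.zeros(n_genes)
            out[s, j] = np.sum(ecdf_in - ecdf_out)
    return pd.DataFrame(out, index=expr.columns, columns=list(memberships))


def score_group_test(
    scores: pd.DataFrame | pd.Series,
    groups: pd.Series | np.ndarray,
    column: str = "immune",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a score between two groups.

    Returns (rank-sum U statistic, p).  Exact p for small tie-free samples,
    normal approximation otherwise (scipy's default policy).
    """
    if isinstance(scores, pd.DataFrame):
        values = scores[column]
    else:
        values = scores
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
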