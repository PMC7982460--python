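"""Preranked GSEA, over-representation analysis, and PPI hub/intersection logic.

The GSEA enrichment score is the classic weighted Kolmogorov–Smirnov running
sum over a ranked gene list; significance comes from gene-label permutation
(random sets of matching size), NES is the ES normalised by the mean |null
ES| of matching sign, and FDR is Benjamini–Hochberg across sets.  ORA uses
the hypergeometric upper tail.  Network "hubs" are vertices whose degree
exceeds a threshold in a user-supplied interaction edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .signatures import GeneSetCollection
from .survival import RiskModel

__all__ = [
    "enrichment_score",
    "gsea_preranked",
    "ora_hypergeometric",
    "read_edge_list",
    "hub_genes",
    "intersect_key_genes",
    "rank_by_group_log2fc",
]


def rank_by_group_log2fc(
    expr: pd.DataFrame, groups: pd.Series, positive_label: str
) -> pd.Series:
    """Ranking metric: difference of group mean log2 expression.

    Score = mean(positive group) - mean(other group); descending scores put
    genes up-regulated in the positive group at the top of the list.
    """
    groups = groups.loc[expr.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2 or positive_label not in levels:
        raise ValueError(f"need two groups incl. {positive_label!r}, got {levels}")
    other = [g for g in levels if g != positive_label][0]
    pos = expr.loc[:, (groups == positive_label).to_numpy()].mean(axis=1)
    neg = expr.loc[:, (groups == other).to_numpy()].mean(axis=1)
    return (pos - neg).sort_values(ascending=False)


def _running_sum(hits: np.ndarray, w_abs: np.ndarray) -> np.ndarray:
    """Running KS sum for a boolean hit mask along a descending ranking."""
    n_miss = hits.size - int(hits.sum())
    inc = np.where(hits, w_abs, 0.0)
    total = inc.sum()
    if total == 0:  # all hit scores zero; fall back to uniform steps
        inc = hits.astype(float)
        total = inc.sum()
    return np.cumsum(inc / total - (~hits) / n_miss)


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, list[str]]:
    """Weighted KS enrichment score and leading edge of one gene set.

    ``ranked_genes`` must be ordered by descending score.  Hit increments are
    proportional to |score|^weight (uniform when weight = 0); misses decrement
    by 1/(N - |set|).  Returns the maximum-deviation running-sum value and the
    leading-edge genes (hits up to and including the extremum).
    """
    hits = np.fromiter((g in gene_set for g in ranked_genes), bool, len(ranked_genes))
    n_hit = int(hits.sum())
    if n_hit == 0 or n_hit == hits.size:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(np.asarray(scores, float)) ** weight
    running = _running_sum(hits, w)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(ranked_genes[: i_max + 1], hits[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked_genes[i_max:], hits[i_max:]) if h]
    return es, leading


def gsea_preranked(
    ranks: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA over a gene -> score series (descending order enforced).

    Null by gene-label permutation: for each set size, ``n_perm`` random sets
    are drawn and scored; p is the matching-sign permutation tail with
    add-one smoothing, NES = ES / mean(|null ES| of the same sign), FDR is BH
    across the tested sets.
    """
    ranks = ranks.sort_values(ascending=False)
    if ranks.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    genes = list(ranks.index)
    scores = ranks.to_numpy(float)
    universe = set(genes)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        overlap = set(members) & universe
        if len(overlap) < min_size:
            warnings.warn(f"set {name!r} overlap {len(overlap)} < {min_size}; skipped")
            continue
        es, leading = enrichment_score(genes, scores, overlap, weight)
        k = len(overlap)
        if k not in null_cache:
            null = np.empty(n_perm)
            w_abs = np.abs(scores) ** weight
            n_genes = len(genes)
            for i in range(n_perm):
                hit = np.zeros(n_genes, dtype=bool)
                hit[rng.choice(n_genes, k, replace=False)] = True
                running = _running_sum(hit, w_abs)
                null[i] = running[np.argmax(np.abs(running))]
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
            nes = es / np.mean(np.abs(same_sign))
        else:
            p, nes = 1.0 / (n_perm + 1), 0.0
        rows.append((name, es, float(nes), float(p), k, ",".join(leading)))

    out = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p_value", "size", "leading_edge"]
    ).set_index("set")
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["fdr"] = []
    return out


def ora_hypergeometric(
    hits: list[str], universe: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within each set."""
    uni = set(universe)
    stray = sorted(set(hits) - uni)
    if stray:
        raise ValueError(f"hit genes outside the universe: {stray[:10]}")
    hit_set = set(hits)
    m = len(uni)
    n_hits = len(hit_set)
    rows = []
    for name, members in sets.items():
        in_uni = set(members) & uni
        k = len(in_uni & hit_set)
        # upper tail: P(X >= k) for X ~ Hypergeom(M=m, n=|set|, N=n_hits)
        p = float(stats.hypergeom.sf(k - 1, m, len(in_uni), n_hits)) if in_uni else 1.0
        rows.append((name, k, len(in_uni), p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "p_value"]
    ).set_index("set")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of interaction partners (e.g. a STRING export)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line")
            edges.append((fields[0], fields[1]))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return edges


def hub_genes(
    edges: list[tuple[str, str]], min_degree: int = 10
) -> pd.Series:
    """Genes whose interaction degree strictly exceeds ``min_degree``.

    Self-loops are ignored and duplicate edges collapsed; result is sorted by
    degree descending (gene name breaks ties).
    """
    if not edges:
        raise ValueError("empty edge list")
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    deg = {node: d for node, d in g.degree() if d > min_degree}
    ordered = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(dict(ordered), name="degree", dtype=int)


def intersect_key_genes(hubs: list[str] | pd.Series, model: RiskModel) -> list[str]:
    """Hub genes that also appear in the risk model, sorted alphabetically."""
    if isinstance(hubs, pd.Series):
        hubs = list(hubs.index)
    return sorted(set(hubs) & set(model.genes))
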