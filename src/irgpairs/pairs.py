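"""Within-sample binary gene-pair features.

The central feature transform of the pipeline: for an (unordered) pair of
genes ``(a, b)`` and a sample ``s``, the indicator is 1 when ``a`` is
expressed more highly than ``b`` *within that sample*, else 0.  Because the
comparison never crosses samples, the features are invariant to any
per-sample monotone transform of expression — normalisation and platform
effects cancel, which is what makes the resulting risk model transferable
across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairIndicatorMatrix",
    "count_pairs",
    "build_pairs",
    "filter_pairs",
    "pair_indicators",
]

PAIR_SEP = "|"


@dataclass
class PairIndicatorMatrix:
    """Binary gene-pair × sample matrix.

    ``indicators`` is a DataFrame whose index is ``"geneA|geneB"`` and whose
    columns are sample IDs; ``pairs`` keeps the (gene_a, gene_b) tuples in
    row order.  ``minority_fraction`` is per pair min(freq of 0, freq of 1).
    """

    indicators: pd.DataFrame
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.pairs) != self.indicators.shape[0]:
            raise ValueError("pairs and indicator rows disagree in length")

    @property
    def samples(self) -> pd.Index:
        return self.indicators.columns

    @property
    def minority_fraction(self) -> pd.Series:
        n = self.indicators.shape[1]
        ones = self.indicators.sum(axis=1)
        return pd.concat([ones, n - ones], axis=1).min(axis=1) / n

    def to_tsv(self, path) -> None:
        self.indicators.to_csv(path, sep="\t", index_label="pair")

    @classmethod
    def from_tsv(cls, path) -> "PairIndicatorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = [tuple(p.split(PAIR_SEP, 1)) for p in df.index]
        return cls(df.astype(np.int8), pairs)


def count_pairs(n_genes: int) -> int:
    """Number of unordered pairs over ``n_genes`` distinct genes."""
    if n_genes < 0:
        raise ValueError(f"n_genes must be non-negative, got {n_genes}")
    return n_genes * (n_genes - 1) // 2


def pair_indicators(
    expr: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Indicator rows for explicitly oriented pairs.

    The orientation given in ``pairs`` is honoured as-is: indicator is 1 iff
    expression of the first gene strictly exceeds the second (ties -> 0).
    Used to score a fitted model on a new cohort, where the model's own
    (irg1, irg2) orientation must be preserved.
    """
    missing = sorted({g for p in pairs for g in p} - set(expr.index))
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    a = expr.loc[[p[0] for p in pairs]].to_numpy()
    b = expr.loc[[p[1] for p in pairs]].to_numpy()
    ind = (a > b).astype(np.int8)
    index = [f"{p[0]}{PAIR_SEP}{p[1]}" for p in pairs]
    return pd.DataFrame(ind, index=index, columns=expr.columns)


def build_pairs(expr: pd.DataFrame, genes: Sequence[str]) -> PairIndicatorMatrix:
    """All-pairs indicator matrix over ``genes``.

    Pairs are enumerated in canonical lexicographic order (gene_a < gene_b),
    so the output is unique regardless of the input gene order.
    """
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build pairs")
    missing = sorted(set(genes) - set(expr.index))
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    ordered = sorted(genes)
    pairs = list(combinations(ordered, 2))
    x = expr.loc[ordered].to_numpy()
    pos = {g: i for i, g in enumerate(ordered)}
    ia = np.fromiter((pos[a] for a, _ in pairs), dtype=np.intp, count=len(pairs))
    ib = np.fromiter((pos[b] for _, b in pairs), dtype=np.intp, count=len(pairs))
    ind = (x[ia] > x[ib]).astype(np.int8)
    index = [f"{a}{PAIR_SEP}{b}" for a, b in pairs]
    return PairIndicatorMatrix(
        pd.DataFrame(ind, index=index, columns=expr.columns), pairs
    )


def filter_pairs(
    pim: PairIndicatorMatrix, min_minority_fraction: float = 0.2
) -> PairIndicatorMatrix:
    """Drop near-constant pairs.

    Retains pairs whose minority state (0 or 1) occurs in at least
    ``min_minority_fraction`` of samples; the published filter removes pairs
    where either state falls strictly below 20%.  Constant pairs (MAD = 0)
    have minority fraction 0 and are removed whenever the threshold is
    positive.
    """
    if not 0.0 <= min_minority_fraction <= 0.5:
        raise ValueError("min_minority_fraction must be in [0, 0.5]")
    keep = pim.minority_fraction >= min_minority_fraction
    kept_pairs = [p for p, k in zip(pim.pairs, keep.to_numpy()) if k]
    return PairIndicatorMatrix(pim.indicators.loc[keep.to_numpy()], kept_pairs)
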