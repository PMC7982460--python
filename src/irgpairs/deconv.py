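"""Reference-based immune cell-fraction estimation.

Each sample's expression over the signature genes is regressed on the
cell-type signature matrix by non-negative least squares; coefficients are
normalised to fractions.  A Monte-Carlo permutation of the sample's
expression values yields a per-sample confidence p-value (how often a random
gene-to-value assignment reconstructs the signatures as well as the real
one), mirroring the confidence filter used with reference deconvolution in
practice.  Deconvolution operates on linear-scale expression; log2 input is
un-logged by the caller or via ``from_log2=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "DeconvolutionResult",
    "deconvolve",
    "filter_confident",
    "group_difference",
]


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    stats: pd.DataFrame  # samples x (p_value, rmse, correlation)

    @property
    def samples(self) -> pd.Index:
        return self.fractions.index


def _check_signature(sig: pd.DataFrame) -> None:
    if sig.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell types")
    if (sig.to_numpy() < 0).any():
        raise ValueError("signature matrix must be non-negative")
    zero_rows = sig.index[(sig.to_numpy() == 0).all(axis=1)]
    if len(zero_rows):
        raise ValueError(f"all-zero signature gene rows: {list(zero_rows[:5])}")
    if sig.columns.duplicated().any():
        raise ValueError("cell-type names must be unique")


def deconvolve(
    expr: pd.DataFrame,
    sig: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    from_log2: bool = False,
) -> DeconvolutionResult:
    """NNLS cell-fraction estimates with Monte-Carlo confidence.

    Parameters
    ----------
    expr : genes x samples expression (linear scale unless ``from_log2``).
    sig : genes x cell types signature matrix, non-negative.
    n_perm : permutations of each sample's expression values used for the
        confidence p (add-one smoothed, so min p = 1/(n_perm+1)).
    """
    _check_signature(sig)
    shared = [g for g in sig.index if g in expr.index]
    if len(shared) < 0.5 * sig.shape[0]:
        raise ValueError(
            f"only {len(shared)}/{sig.shape[0]} signature genes present in expression"
        )
    x_full = expr.to_numpy(float)
    if from_log2:
        x_full = np.power(2.0, x_full)
    a = sig.loc[shared].to_numpy(float)
    row_pos = expr.index.get_indexer(shared)

    rng = np.random.default_rng(seed)
    n_samples = expr.shape[1]
    frac = np.zeros((n_samples, sig.shape[1]))
    pvals = np.ones(n_samples)
    rmses = np.zeros(n_samples)
    cors = np.zeros(n_samples)
    n_genes_total = x_full.shape[0]

    ok = np.ones(n_samples, dtype=bool)
    for s in range(n_samples):
        y = x_full[row_pos, s]
        coef, _ = nnls(a, y)
        total = coef.sum()
        if total <= 0:
            # degenerate sample: flagged, not fatal
            ok[s] = False
            frac[s] = np.nan
            pvals[s] = 1.0
            continue
        frac[s] = coef / total
        fitted = a @ coef
        rmses[s] = float(np.sqrt(np.mean((fitted - y) ** 2)))
        obs_cor = _safe_cor(fitted, y)
        cors[s] = obs_cor
        # null: the same sample's expression values randomly reassigned to genes
        hits = 0
        for _ in range(n_perm):
            y_perm = rng.choice(x_full[:, s], size=len(shared), replace=False) \
                if n_genes_total >= len(shared) else rng.permutation(y)
            c_perm, _ = nnls(a, y_perm)
            if _safe_cor(a @ c_perm, y_perm) >= obs_cor:
                hits += 1
        pvals[s] = (hits + 1) / (n_perm + 1)

    fractions = pd.DataFrame(frac, index=expr.columns, columns=sig.columns)
    stats_df = pd.DataFrame(
        {"p_value": pvals, "rmse": rmses, "correlation": cors, "ok": ok},
        index=expr.columns,
    )
    return DeconvolutionResult(fractions, stats_df)


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def filter_confident(
    result: DeconvolutionResult, alpha: float = 0.05
) -> DeconvolutionResult:
    """Keep samples whose deconvolution confidence p is below ``alpha``."""
    keep = result.stats.index[result.stats["p_value"] < alpha]
    return DeconvolutionResult(
        result.fractions.loc[keep], result.stats.loc[keep]
    )


def group_difference(
    result: DeconvolutionResult, groups: pd.Series
) -> pd.DataFrame:
    """Per-cell-type Wilcoxon rank-sum comparison between two groups.

    ``groups`` maps sample -> label (e.g. high/low risk).  Direction is the
    sign of the median fraction difference, first label minus second in
    sorted label order ('high' - 'low' for risk groups).
    """
    groups = groups.loc[result.samples]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a_idx = groups.index[groups == levels[0]]
    b_idx = groups.index[groups == levels[1]]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs at least 2 retained samples")
    rows = []
    for ct in result.fractions.columns:
        a = result.fractions.loc[a_idx, ct]
        b = result.fractions.loc[b_idx, ct]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        direction = float(np.sign(a.median() - b.median()))
        rows.append((ct, float(res.statistic), float(res.pvalue), direction))
    return pd.DataFrame(
        rows, columns=["cell_type", "statistic", "p", "direction"]
    ).set_index("cell_type")
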