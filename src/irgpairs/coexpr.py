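"""Compact weighted co-expression network core.

Implements the parts of WGCNA the gene-pair pipeline consumes: the soft
threshold scan against a scale-free topology criterion, unsigned power
adjacency, the topological overlap matrix (TOM), average-linkage module
detection with a static tree cut, module eigengenes, module membership (MM),
gene significance (GS), and the module–trait correlation table.

Deliberate simplifications relative to the full WGCNA stack: a static cut at
a fixed fraction of the dendrogram's merge-height range (instead of the
dynamic hybrid tree cut), no module merging by eigengene similarity, and no
blockwise decomposition — adequate up to a few thousand genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdScan",
    "ModuleAssignment",
    "scale_free_fit",
    "adjacency_matrix",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_trait",
    "screen_genes",
]

# WGCNA-style colour labels, assigned to modules by decreasing size
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # index: power; columns: scale_free_r2, mean_connectivity
    chosen_power: int


@dataclass
class ModuleAssignment:
    module_labels: pd.Series  # gene -> label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    mm: pd.Series  # gene -> cor(gene, own module's eigengene); NaN for grey
    gs: pd.DataFrame | None = None  # genes x traits, signed correlations
    merge_heights: tuple[float, float] = (0.0, 0.0)

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"module": self.module_labels, "MM": self.mm})
        if self.gs is not None:
            for trait in self.gs.columns:
                out[f"GS_{trait}"] = self.gs[trait]
        return out


def _check_expression(expr: pd.DataFrame) -> None:
    sd = expr.to_numpy().std(axis=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"constant gene(s), correlation undefined: {list(expr.index[zero[:5]])}"
        )


def adjacency_matrix(expr: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned power adjacency |cor|^power with zero diagonal."""
    _check_expression(expr)
    a = np.abs(np.corrcoef(expr.to_numpy())) ** power
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned degree distribution.

    Connectivities are histogrammed into ``n_bins`` equal-width bins; within
    each non-empty bin the representative degree is the bin mean and the
    frequency is the fraction of genes in the bin.  The returned value is
    the signed fit index -sign(slope) * R^2 of the regression of
    log10(frequency) on log10(degree): a genuine scale-free topology has a
    decaying degree distribution, so fits with a positive slope count
    against the candidate power.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            dk.append(k[sel].mean())
            freq.append(sel.mean())
    if len(dk) < 3:
        return 0.0
    lk, lf = np.log10(dk), np.log10(freq)
    r = np.corrcoef(lk, lf)[0, 1]
    return float(-np.sign(r) * r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers for approximate scale-free topology.

    Chooses the smallest power whose fit R^2 reaches ``r2_target``.  If no
    power reaches the target — common when the correlation structure is
    block-like rather than scale-free — the conventional sample-size-based
    default for unsigned networks is used instead (10 below 20 samples, 9
    below 30, 8 below 40, 6 otherwise), with a warning; a spuriously large
    power would only erase the network.
    """
    if powers is None:
        powers = list(range(1, 21))
    if sorted(powers) != powers or len(set(powers)) != len(powers):
        raise ValueError("powers must be strictly increasing")
    if expr.shape[1] < 20:
        warnings.warn("fewer than 20 samples: correlations will be noisy")
    if expr.shape[0] < 30:
        raise ValueError("need at least 30 genes for a meaningful scan")
    _check_expression(expr)
    cor = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        a = cor**beta
        k = a.sum(axis=1)
        rows.append((beta, scale_free_fit(k, n_bins), float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["power", "scale_free_r2", "mean_connectivity"]
    ).set_index("power")
    hit = table.index[table["scale_free_r2"] >= r2_target]
    if len(hit):
        chosen = int(hit[0])
    else:
        n = expr.shape[1]
        chosen = 10 if n < 20 else 9 if n < 30 else 8 if n < 40 else 6
        warnings.warn(
            f"no power reached R^2 >= {r2_target}; "
            f"falling back to the sample-size default power {chosen}"
        )
    return SoftThresholdScan(table, chosen)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    with unit diagonal.  Inputs must be symmetric with entries in [0, 1];
    the diagonal is zeroed before the computation.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > 1e-8:
        raise ValueError("adjacency is not symmetric (tolerance 1e-8)")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component across samples of a (genes x samples) block."""
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    # right singular vector = PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    me = me / np.linalg.norm(me)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    return me


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.7,
) -> ModuleAssignment:
    """Average-linkage module detection on TOM dissimilarity.

    The dendrogram of 1 - TOM is cut at ``cut_height`` expressed as a
    fraction of the merge-height range; clusters below ``min_module_size``
    are relabelled grey.  Module labels are colour names assigned by
    decreasing module size.  Eigengenes are first principal components of
    the standardized module expression, sign-oriented to correlate
    positively with the module's mean expression profile.
    """
    n = expr.shape[0]
    if tom.shape != (n, n):
        raise ValueError("TOM and expression matrix disagree in gene count")
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    heights = z[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    threshold = lo + cut_height * (hi - lo)
    raw = fcluster(z, t=threshold, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index[sizes >= min_module_size]]
    kept.sort(key=lambda c: (-sizes[c], c))
    if not kept:
        warnings.warn("no module reached min_module_size; all genes grey")
    color_of = {
        c: (_COLORS[i] if i < len(_COLORS) else f"module{i + 1}")
        for i, c in enumerate(kept)
    }
    labels = pd.Series(
        [color_of.get(c, GREY) for c in raw], index=expr.index, name="module"
    )

    x = expr.to_numpy()
    me_cols: dict[str, np.ndarray] = {}
    for c in kept:
        rows = np.where(raw == c)[0]
        me_cols[color_of[c]] = _eigengene(x[rows])
    eigengenes = pd.DataFrame(me_cols, index=expr.columns)

    mm = pd.Series(np.nan, index=expr.index, name="MM")
    for mod in eigengenes.columns:
        genes = labels.index[labels == mod]
        block = expr.loc[genes].to_numpy()
        me = eigengenes[mod].to_numpy()
        mm.loc[genes] = _row_cor(block, me)

    gs = None
    if traits is not None:
        traits = traits.loc[expr.columns]
        gs = pd.DataFrame(
            {t: _row_cor(x, traits[t].to_numpy()) for t in traits.columns},
            index=expr.index,
        )
    return ModuleAssignment(labels, eigengenes, mm, gs, merge_heights=(lo, hi))


def _row_cor(block: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``block`` with vector ``v``."""
    bz = block - block.mean(axis=1, keepdims=True)
    vz = v - v.mean()
    denom = np.sqrt((bz**2).sum(axis=1) * (vz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, bz @ vz / denom, np.nan)


def module_trait(
    assign: ModuleAssignment, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation (+ two-sided p) of each eigengene with each trait."""
    missing = [s for s in assign.eigengenes.index if s not in traits.index]
    if missing:
        raise KeyError(f"traits missing samples: {missing[:5]}")
    traits = traits.loc[assign.eigengenes.index]
    n = len(traits)
    rows = []
    for mod in assign.eigengenes.columns:
        me = assign.eigengenes[mod].to_numpy()
        for t in traits.columns:
            r = float(np.corrcoef(me, traits[t].to_numpy())[0, 1])
            r_c = min(max(r, -0.9999999999), 0.9999999999)
            tstat = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
            p = 2.0 * stats.t.sf(abs(tstat), n - 2)
            rows.append((mod, t, r, p))
    return pd.DataFrame(rows, columns=["module", "trait", "correlation", "p_value"])


def screen_genes(
    assign: ModuleAssignment,
    target_module: str,
    trait: str,
    mm_min: float = 0.5,
    gs_min: float = 0.5,
    gs_method: str = "correlation",
) -> list[str]:
    """Genes of ``target_module`` passing |MM| > mm_min and |GS| > gs_min.

    ``gs_method='correlation'`` screens on the absolute gene–trait Pearson
    correlation; ``'neglogp'`` screens on -log10 of its p-value instead (an
    alternative gene-significance convention).  Result is sorted by |MM|
    descending.
    """
    if target_module == GREY or target_module not in assign.modules:
        raise KeyError(f"unknown or unassignable module {target_module!r}")
    if assign.gs is None or trait not in assign.gs.columns:
        raise KeyError(f"trait {trait!r} has no gene-significance column")
    genes = assign.module_labels.index[assign.module_labels == target_module]
    mm = assign.mm.loc[genes].abs()
    gs_r = assign.gs.loc[genes, trait]
    if gs_method == "correlation":
        gs_val = gs_r.abs()
    elif gs_method == "neglogp":
        n = assign.eigengenes.shape[0]
        r_c = gs_r.clip(-0.9999999999, 0.9999999999)
        tstat = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        gs_val = pd.Series(-np.log10(np.maximum(p, 1e-300)), index=genes)
    else:
        raise ValueError("gs_method must be 'correlation' or 'neglogp'")
    passed = genes[(mm > mm_min) & (gs_val > gs_min)]
    return sorted(passed, key=lambda g: -mm.loc[g])
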