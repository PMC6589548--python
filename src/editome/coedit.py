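"""Weighted co-editing network: soft-threshold selection, topological
overlap, module detection, eigengenes, and module-trait correlation.

The network follows the weighted co-expression methodology applied to
editing levels: unsigned adjacency a_ij = |cor(i,j)|^beta with the lowest
beta whose scale-free fit index exceeds the threshold, topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), average
linkage clustering of 1 - TOM with a static height cut, and iterative
merging of modules whose eigengenes correlate above the merge threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats import correlate


@dataclass
class NetworkParams:
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_threshold: float = 0.9
    merge_eigengene_cor: float = 0.8
    min_module_size: int = 30
    min_samples_edited: int = 10
    n_degree_bins: int = 10
    cut_height: float | None = None  # None: largest-gap calibration

    def __post_init__(self):
        if not 0 < self.scale_free_r2_threshold <= 1:
            raise ValueError("scale_free_r2_threshold must be in (0, 1]")
        if not 0 < self.merge_eigengene_cor <= 1:
            raise ValueError("merge_eigengene_cor must be in (0, 1]")
        if any(p < 1 for p in self.powers):
            raise ValueError("powers must be positive integers")


@dataclass
class ModuleAssignment:
    labels: pd.Series            # site -> "M1"... or "unassigned"
    eigengenes: pd.DataFrame     # samples x modules
    power: int
    cut_height: float

    @property
    def module_names(self) -> list[str]:
        return list(self.eigengenes.columns)


def select_network_sites(levels: pd.DataFrame,
                         params: NetworkParams | None = None) -> pd.DataFrame:
    """Sites with no missing values and editing (level > 0) in more than
    ``min_samples_edited`` samples."""
    params = params or NetworkParams()
    complete = levels.notna().all(axis=1)
    edited = (levels > 0).sum(axis=1) > params.min_samples_edited
    return levels[complete & edited]


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width degree bins.

    Positive-slope fits are reported as negative (a scale-free degree
    distribution must have decreasing frequency in k).
    """
    k = k[np.isfinite(k) & (k > 0)]
    if len(k) < 3 or np.ptp(k) == 0:
        return -np.inf
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return -np.inf
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = np.polyval([slope, intercept], xs)
    ss_res = np.sum((np.array(ys) - yhat) ** 2)
    ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2 if slope < 0 else -r2


def adjacency_matrix(levels: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^power with zero diagonal."""
    if len(levels) < 3:
        raise ValueError("network undefined below 3 nodes")
    cor = np.corrcoef(levels.to_numpy(float))
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_power(levels: pd.DataFrame,
                    params: NetworkParams | None = None) -> tuple[int, pd.DataFrame]:
    """Lowest power with scale-free fit above threshold; else argmax + warning."""
    params = params or NetworkParams()
    rows = []
    for beta in params.powers:
        a = adjacency_matrix(levels, beta)
        k = a.sum(axis=0)
        fit = _scale_free_fit(k, params.n_degree_bins)
        rows.append({"power": beta, "fit_r2": fit, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table[table.fit_r2 > params.scale_free_r2_threshold]
    if len(qualifying):
        return int(qualifying.index[0]), table
    warnings.warn(
        "no power reached the scale-free fit threshold; using the best fit"
    )
    finite = table.fit_r2.replace(-np.inf, np.nan)
    if finite.notna().any():
        return int(finite.idxmax()), table
    return int(table.index[0]), table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; diagonal is 1 by convention."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(levels: pd.DataFrame) -> pd.Series:
    """First principal component of the standardised member submatrix.

    The sign is fixed so that the mean member correlation with the
    eigengene is positive.
    """
    x = levels.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    cors = z @ eig / (np.linalg.norm(z, axis=1) * np.linalg.norm(eig) + 1e-300)
    if cors.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=levels.columns)


def _cut_height_largest_gap(merge_heights: np.ndarray) -> float:
    """Midpoint of the largest jump in the sorted merge-height sequence."""
    h = np.sort(merge_heights)
    if len(h) < 2:
        return float(h[-1]) + 1e-9 if len(h) else 1.0
    gaps = np.diff(h)
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return float(h[-1]) + 1e-9
    return float((h[i] + h[i + 1]) / 2.0)


def detect_modules(tom: np.ndarray, levels: pd.DataFrame,
                   params: NetworkParams | None = None) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters below ``min_module_size`` are left unassigned; modules whose
    eigengenes correlate above ``merge_eigengene_cor`` are merged
    iteratively until no pair qualifies.
    """
    params = params or NetworkParams()
    if len(levels) != tom.shape[0]:
        raise ValueError("TOM and level matrix disagree on the number of sites")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    h = params.cut_height if params.cut_height is not None else \
        _cut_height_largest_gap(z[:, 2])
    raw = hierarchy.fcluster(z, t=h, criterion="distance")

    groups: dict[int, list[int]] = {}
    for i, g in enumerate(raw):
        groups.setdefault(int(g), []).append(i)
    modules = [idx for idx in groups.values() if len(idx) >= params.min_module_size]

    # iterative eigengene merging, strictly decreasing module count
    while len(modules) > 1:
        eigs = [module_eigengene(levels.iloc[idx]) for idx in modules]
        best = None
        for i in range(len(modules)):
            for jj in range(i + 1, len(modules)):
                r, _ = correlate(eigs[i], eigs[jj])
                if np.isfinite(r) and r > params.merge_eigengene_cor:
                    if best is None or r > best[0]:
                        best = (r, i, jj)
        if best is None:
            break
        _, i, jj = best
        modules[i] = modules[i] + modules[jj]
        del modules[jj]

    modules.sort(key=len, reverse=True)
    labels = pd.Series("unassigned", index=levels.index, dtype=object)
    eig_cols = {}
    for m, idx in enumerate(modules, 1):
        name = f"M{m}"
        labels.iloc[idx] = name
        eig_cols[name] = module_eigengene(levels.iloc[idx])
    eigengenes = pd.DataFrame(eig_cols, index=levels.columns)
    return ModuleAssignment(labels=labels, eigengenes=eigengenes,
                            power=0, cut_height=float(h))


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) of each module eigengene against each trait column."""
    rows = []
    for module in eigengenes.columns:
        for trait in traits.columns:
            try:
                r, p = correlate(eigengenes[module], traits[trait])
            except ValueError:
                r = p = np.nan
            rows.append({"module": module, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows).set_index(["module", "trait"])


def build_network(levels: pd.DataFrame,
                  params: NetworkParams | None = None) -> ModuleAssignment:
    """select sites -> pick power -> adjacency -> TOM -> modules."""
    params = params or NetworkParams()
    selected = select_network_sites(levels, params)
    power, _ = pick_soft_power(selected, params)
    a = adjacency_matrix(selected, power)
    tom = tom_similarity(a)
    assignment = detect_modules(tom, selected, params)
    assignment.power = power
    return assignment
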