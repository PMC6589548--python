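"""Editing-level quantification, matrix assembly, imputation, and MDS.

The editing level of a site in one sample is the fraction of reads
carrying the edited base among reads carrying either the reference or the
edited base (G / (A + G) for an A-to-I site on the sense strand). The
overall editing rate of a sample pools reads across sites (read-weighted,
not a mean of per-site levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import filter_read_end
from .formats import read_pileup


def editing_level(g_reads: int, a_reads: int) -> float:
    """g / (g + a); NaN (missing) when no informative reads cover the site."""
    if g_reads < 0 or a_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = g_reads + a_reads
    if total == 0:
        return math.nan
    return g_reads / total


def overall_rate(g_reads, a_reads) -> float:
    """Pooled editing rate: sum(G) / sum(A + G) over all covered sites."""
    g = np.asarray(g_reads, dtype=float)
    a = np.asarray(a_reads, dtype=float)
    mask = np.isfinite(g) & np.isfinite(a)
    total = (g[mask] + a[mask]).sum()
    if total == 0:
        return math.nan
    return float(g[mask].sum() / total)


@dataclass
class EditingMatrix:
    """Sites x samples editing levels with per-cell read support.

    ``levels`` holds values in [0, 1] with NaN for missing cells; a cell is
    missing when the site has no informative reads or raw depth below the
    calling threshold in that sample.
    """

    levels: pd.DataFrame
    g: pd.DataFrame
    a: pd.DataFrame
    depth: pd.DataFrame
    samples: pd.DataFrame

    def overall_rates(self) -> pd.Series:
        """Read-weighted overall editing rate per sample."""
        return pd.Series(
            {s: overall_rate(self.g[s], self.a[s]) for s in self.levels.columns},
            name="overall_rate",
        )

    def subset(self, site_ids) -> "EditingMatrix":
        return EditingMatrix(
            levels=self.levels.loc[site_ids],
            g=self.g.loc[site_ids],
            a=self.a.loc[site_ids],
            depth=self.depth.loc[site_ids],
            samples=self.samples,
        )


def quantify_levels(sites: pd.DataFrame, pileup_paths: dict[str, object],
                    samples: pd.DataFrame, min_depth: int = 10,
                    read_end_exclusion_bp: int = 6) -> EditingMatrix:
    """Compute per-sample editing levels for the called sites.

    Read support counts use the same read-end exclusion as calling, so the
    level is consistent with the evidence that made the site callable.
    """
    wanted = {}
    for idx, r in zip(sites.index, sites.itertuples()):
        if hasattr(r, "change"):
            ref, alt = r.change.split(">")
        else:
            ref, alt = r.ref, r.alt
        wanted[(r.chrom, r.pos)] = (idx, ref, alt)
    n, m = len(sites), len(samples)
    g = np.zeros((n, m))
    a = np.zeros((n, m))
    depth = np.zeros((n, m), dtype=int)
    row_of = {idx: i for i, idx in enumerate(sites.index)}
    col_of = {s: j for j, s in enumerate(samples.index)}
    for sample, path in pileup_paths.items():
        j = col_of[sample]
        for site in read_pileup(path):
            info = wanted.get((site.chrom, site.pos))
            if info is None:
                continue
            idx, ref, alt = info
            i = row_of[idx]
            depth[i, j] = site.depth
            ref_kept = filter_read_end(site.observations(ref), read_end_exclusion_bp)
            alt_kept = filter_read_end(site.observations(alt), read_end_exclusion_bp)
            a[i, j] = len(ref_kept)
            g[i, j] = len(alt_kept)
    levels = np.where((g + a) > 0, g / np.maximum(g + a, 1), np.nan)
    levels = np.where(depth >= min_depth, levels, np.nan)
    cols = list(samples.index)
    return EditingMatrix(
        levels=pd.DataFrame(levels, index=sites.index, columns=cols),
        g=pd.DataFrame(g, index=sites.index, columns=cols),
        a=pd.DataFrame(a, index=sites.index, columns=cols),
        depth=pd.DataFrame(depth, index=sites.index, columns=cols),
        samples=samples,
    )


def missingness_filter(levels: pd.DataFrame,
                       max_missing_frac: float = 1 / 3) -> pd.DataFrame:
    """Keep sites missing in at most floor(n_samples * frac) samples.

    With 81 samples and the default one-third rule the threshold is 27:
    a site missing in 27 samples is kept, in 28 dropped.
    """
    threshold = math.floor(levels.shape[1] * max_missing_frac)
    n_missing = levels.isna().sum(axis=1)
    return levels[n_missing <= threshold]


def impute(levels: pd.DataFrame, method: str = "mean",
           n_neighbors: int = 10) -> pd.DataFrame:
    """Fill missing cells; observed cells are never touched.

    mean: per-site mean over observed samples (deterministic default).
    knn:  k-nearest-neighbour over samples (scikit-learn KNNImputer).
    """
    if method == "mean":
        row_means = levels.mean(axis=1)
        fallback = levels.stack().mean() if levels.isna().all(axis=1).any() else 0.0
        filled = levels.T.fillna(row_means.fillna(fallback)).T
        return filled
    if method == "knn":
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=min(n_neighbors, max(levels.shape[1] - 1, 1)))
        arr = imp.fit_transform(levels.T.to_numpy())
        out = pd.DataFrame(arr.T, index=levels.index, columns=levels.columns)
        return out.where(levels.isna(), levels)
    raise ValueError(f"unknown imputation method {method!r}")


def classical_mds(matrix: pd.DataFrame, n_dims: int = 2) -> tuple[pd.DataFrame,
                                                                  np.ndarray]:
    """Classical (Torgerson) MDS of samples using Euclidean distance over sites.

    Double-centre -1/2 D^2, eigendecompose, scale the top eigenvectors by
    the square root of their eigenvalues. The variance fraction of each
    returned dimension is its eigenvalue over the sum of positive
    eigenvalues.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x sites
    if not np.isfinite(x).all():
        raise ValueError("MDS requires a complete (imputed) matrix")
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12
    total = evals[pos].sum()
    k = min(n_dims, int(pos.sum())) if total > 0 else 0
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    var_frac = (evals[:k] / total) if total > 0 else np.zeros(0)
    if k < n_dims:  # degenerate input: pad with zero dimensions
        coords = np.hstack([coords, np.zeros((n, n_dims - k))])
        var_frac = np.concatenate([var_frac, np.zeros(n_dims - k)])
    out = pd.DataFrame(
        coords, index=matrix.columns,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )
    return out, var_frac
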