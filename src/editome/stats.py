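"""Developmental differential-editing statistics.

Per-site ordinary least squares of editing level on developmental age
(days post-conception) and sex, Benjamini-Hochberg FDR control, group
enrichment of significant sites (risk ratio, Wald CI on the log scale,
Fisher exact p), and host-expression correlation.

The regression uses observed cells only; imputed values are reserved for
MDS and network construction, where completeness is structural rather
than inferential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EnrichmentRow:
    group: str
    total_sites: int
    significant_sites: int
    percent: float
    enrichment: float
    ci_low: float
    ci_high: float
    p_value: float


def _ols_block(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of many responses (columns of y) on one design matrix.

    Returns (beta, p) with shape (n_params, n_responses); two-sided t-tests.
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, pvals


def fit_site_regression(levels: np.ndarray, stage_days: np.ndarray,
                        sex01: np.ndarray, min_obs: int = 6) -> dict:
    """OLS for one site: level ~ 1 + stage_days + sex.

    Missing cells are dropped row-wise. With a single sex among the
    observed samples the design is rank-deficient; the sex coefficient is
    reported NA and the stage effect is fit without it.
    """
    mask = np.isfinite(levels)
    out = {"beta_stage": math.nan, "p_stage": math.nan,
           "beta_sex": math.nan, "p_sex": math.nan, "n_observed": int(mask.sum())}
    if mask.sum() < min_obs:
        return out
    y = levels[mask][:, None]
    d = stage_days[mask]
    s = sex01[mask]
    if len(np.unique(s)) < 2:
        x = np.column_stack([np.ones(mask.sum()), d])
        beta, p = _ols_block(y, x)
        out.update(beta_stage=float(beta[1, 0]), p_stage=float(p[1, 0]))
        return out
    x = np.column_stack([np.ones(mask.sum()), d, s])
    beta, p = _ols_block(y, x)
    out.update(
        beta_stage=float(beta[1, 0]), p_stage=float(p[1, 0]),
        beta_sex=float(beta[2, 0]), p_sex=float(p[2, 0]),
    )
    return out


def differential_editing(levels: pd.DataFrame, samples: pd.DataFrame,
                         stage_col: str = "stage_days",
                         min_obs: int = 6) -> pd.DataFrame:
    """Per-site regression over a sites x samples level matrix + BH FDR.

    Complete sites share one design matrix and are fit in a single
    vectorised pass; sites with missing cells are fit individually.
    """
    days = samples.loc[levels.columns, stage_col].to_numpy(float)
    sex01 = (samples.loc[levels.columns, "sex"] == "F").to_numpy(float)
    y = levels.to_numpy(float)
    complete = np.isfinite(y).all(axis=1)
    records = pd.DataFrame(
        index=levels.index,
        columns=["beta_stage", "p_stage", "beta_sex", "p_sex", "n_observed"],
        dtype=float,
    )
    if complete.any() and len(np.unique(sex01)) == 2:
        x = np.column_stack([np.ones(len(days)), days, sex01])
        beta, p = _ols_block(y[complete].T, x)
        records.loc[complete, "beta_stage"] = beta[1]
        records.loc[complete, "p_stage"] = p[1]
        records.loc[complete, "beta_sex"] = beta[2]
        records.loc[complete, "p_sex"] = p[2]
        records.loc[complete, "n_observed"] = len(days)
        rest = np.flatnonzero(~complete)
    else:
        rest = np.arange(len(levels))
    for i in rest:
        res = fit_site_regression(y[i], days, sex01, min_obs)
        records.iloc[i] = [res["beta_stage"], res["p_stage"],
                           res["beta_sex"], res["p_sex"], res["n_observed"]]
    records["n_observed"] = records["n_observed"].astype("Int64")
    records["q_stage"] = bh_fdr(records["p_stage"].to_numpy(float))
    records["q_sex"] = bh_fdr(records["p_sex"].to_numpy(float))
    return records


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs yield NaN outputs and are excluded from the number of tests.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def enrichment_test(sig_in_group: int, total_in_group: int,
                    sig_overall: int, total_overall: int,
                    group: str = "") -> EnrichmentRow:
    """Enrichment of significant sites in a group versus the overall set.

    percent      100 * sig/total within the group
    enrichment   (sig_g/total_g) / (sig_all/total_all)
    95% CI       Wald interval on the log risk ratio of group vs complement
    p            two-sided Fisher exact test on the group-vs-complement 2x2
    """
    if not (0 <= sig_in_group <= total_in_group <= total_overall):
        raise ValueError("inconsistent counts")
    if sig_in_group > sig_overall:
        raise ValueError("group cannot contain more significant sites than overall")
    percent = 100.0 * sig_in_group / total_in_group if total_in_group else math.nan
    if sig_overall == 0 or total_overall == 0:
        return EnrichmentRow(group, total_in_group, sig_in_group, percent,
                             math.nan, math.nan, math.nan, math.nan)
    enrich = (sig_in_group / total_in_group) / (sig_overall / total_overall)
    a, n1 = sig_in_group, total_in_group
    c = sig_overall - sig_in_group
    n0 = total_overall - total_in_group
    if a > 0 and c > 0 and n0 > 0:
        rr = (a / n1) / (c / n0)
        se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
        ci_low, ci_high = (rr * math.exp(-1.96 * se), rr * math.exp(1.96 * se))
    else:
        ci_low = ci_high = math.nan
    table = [[a, n1 - a], [c, n0 - c]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1]) if n0 > 0 else math.nan
    return EnrichmentRow(group, total_in_group, sig_in_group, percent,
                         enrich, ci_low, ci_high, p)


def enrichment_table(annotated: pd.DataFrame, significant: pd.Series,
                     by: str) -> pd.DataFrame:
    """Per-group enrichment rows over a column of the annotated site table."""
    sig = significant.reindex(annotated.index).fillna(False)
    total_overall = len(annotated)
    sig_overall = int(sig.sum())
    rows = []
    for group, sub in annotated.groupby(by, sort=True):
        r = enrichment_test(int(sig[sub.index].sum()), len(sub),
                            sig_overall, total_overall, group=str(group))
        rows.append(r.__dict__)
    return pd.DataFrame(rows).set_index("group")


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with pairwise-complete handling of missing data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p)


def host_expression_correlation(levels: pd.DataFrame, expression: pd.DataFrame,
                                site_gene: pd.Series) -> pd.DataFrame:
    """Correlation of each site's editing level with its host-gene expression."""
    common = [s for s in levels.columns if s in expression.columns]
    rows = []
    for sid, gid in site_gene.items():
        if not gid or gid not in expression.index or sid not in levels.index:
            continue
        try:
            r, p = correlate(levels.loc[sid, common], expression.loc[gid, common])
        except ValueError:
            continue
        if math.isnan(r):
            continue
        rows.append({"site_id": sid, "gene_id": gid, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "r", "p"]).set_index(
        "site_id"
    )


def correlation_histogram(r_values, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of correlation coefficients over [-1, 1]."""
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    return np.histogram(r, bins=bins, range=(-1.0, 1.0))
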