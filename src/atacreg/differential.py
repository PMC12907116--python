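"""Negative-binomial Wald differential testing with a sex covariate.

The same engine serves ATAC peak counts and RNA gene counts.  Counts are
normalized with median-of-ratios size factors, a per-feature NB dispersion
is estimated by method of moments within design cells, and a negative
binomial GLM (log link) is fitted per feature by iteratively reweighted
least squares with the dispersion held fixed.  The Wald z statistic on the
group coefficient (centenarian vs control) gives the p-value; BH adjustment
and the study's significance thresholds (padj < 0.05, |fold change| > 1.5)
produce the opening/closing (or up/down) calls.

Deliberate simplifications relative to shrinkage-based tools: no
empirical-Bayes dispersion or fold-change shrinkage, no independent
filtering, no outlier replacement.  See the methods note for the rationale
and consequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import CountsMatrix

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

GROUP_LEVELS = ("control", "centenarian")
SEX_LEVELS = ("F", "M")


@dataclass
class DesignInfo:
    """Sample-level design: group (control/centenarian) and sex (F/M).

    The model is intercept + group (+ sex when ``include_sex``).  Stratified
    (single-sex) runs use a group-only design on the subset sample sheet.
    """

    sample_ids: list[str]
    group: list[str]
    sex: list[str]
    include_sex: bool = True

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.group) != n or len(self.sex) != n:
            raise ValueError("sample_ids, group and sex must have equal length")
        bad = set(self.group) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(f"unknown group levels: {sorted(bad)}")
        bad = set(self.sex) - set(SEX_LEVELS)
        if bad:
            raise ValueError(f"unknown sex levels: {sorted(bad)}")
        if len(set(self.group)) < 2:
            raise ValueError("both groups must be present in the design")
        if self.include_sex and len(set(self.sex)) < 2:
            # a single-sex subset cannot support a sex coefficient
            self.include_sex = False

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame, include_sex: bool = True):
        return cls(
            sample_ids=list(sheet["sample_id"]),
            group=list(sheet["group"]),
            sex=list(sheet["sex"]),
            include_sex=include_sex,
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def matrix(self) -> np.ndarray:
        """Design matrix: intercept, group indicator, optional sex indicator."""
        g = np.array([1.0 if x == "centenarian" else 0.0 for x in self.group])
        cols = [np.ones(self.n_samples), g]
        if self.include_sex:
            cols.append(np.array([1.0 if x == "M" else 0.0 for x in self.sex]))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X

    def cells(self) -> list[np.ndarray]:
        """Index arrays of the design cells (group x sex, or group only)."""
        keys = (
            list(zip(self.group, self.sex)) if self.include_sex else list(self.group)
        )
        uniq: dict = {}
        for i, k in enumerate(keys):
            uniq.setdefault(k, []).append(i)
        return [np.asarray(v) for v in uniq.values()]


def estimate_size_factors(counts: CountsMatrix) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Computed over features with all-positive counts; when none exist, falls
    back to library-size ratios with a warning.  A single sample gets
    factor 1.
    """
    values = counts.values.astype(float)
    if values.shape[1] == 1:
        return np.ones(1)
    positive = np.all(values > 0, axis=1)
    if not positive.any():
        warnings.warn(
            "no feature with all-positive counts; falling back to "
            "library-size ratio size factors",
            stacklevel=2,
        )
        totals = values.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    sub = values[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    log_ratios = np.log(sub) - log_ref[:, None]
    return np.exp(np.median(log_ratios, axis=0))


def estimate_dispersion(
    counts: CountsMatrix,
    size_factors: np.ndarray,
    design: DesignInfo,
    floor: float = DISPERSION_FLOOR,
) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion (alpha) on normalized counts.

    Within each design cell the excess variance (s^2 - m) / m^2 estimates
    alpha; estimates are pooled across cells weighting by degrees of freedom
    and floored at ``floor``.
    """
    norm = counts.values / size_factors[np.newaxis, :]
    cells = [c for c in design.cells() if len(c) >= 2]
    if not cells:
        raise ValueError("dispersion estimation requires >=2 samples in a design cell")
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for idx in cells:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        w = len(idx) - 1
        alpha_c = np.zeros_like(m)
        alpha_c[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        num[ok] += w * alpha_c[ok]
        den[ok] += w
    alpha = np.full(counts.shape[0], floor)
    seen = den > 0
    alpha[seen] = np.maximum(floor, num[seen] / den[seen])
    return alpha


def _nb_irls(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Batched IRLS for NB GLMs with log link and fixed per-feature dispersion.

    Fits ``log mu = X beta + offset`` for every row of ``Y`` simultaneously.
    Returns (beta, se, converged) with se the Wald standard errors from the
    expected information ``X' W X``, W = mu / (1 + alpha mu).
    """
    n_feat, n_samp = Y.shape
    n_par = X.shape[1]
    # start from the saturated-ish mean on the offset scale
    mu = np.maximum(Y, 0.5)
    eta = np.log(mu)
    beta = np.zeros((n_feat, n_par))
    # initial beta via one weighted LS on the working response
    active = np.ones(n_feat, dtype=bool)
    converged = np.zeros(n_feat, dtype=bool)
    alpha = alpha[:, None]
    ridge = 1e-10 * np.eye(n_par)
    info = None
    for _ in range(max_iter):
        W = mu / (1.0 + alpha * mu)  # (F, S)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("sp,fs,sq->fpq", X, W, X)
        b = np.einsum("sp,fs,fs->fp", X, W, z)
        new_beta = np.linalg.solve(A + ridge[None, :, :], b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
        info = A
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("sp,fs,sq->fpq", X, W, X)
    cov = np.linalg.inv(A + ridge[None, :, :])
    se = np.sqrt(np.maximum(np.einsum("fpp->fp", cov), 0.0))
    return beta, se, converged


def nb_wald_table(
    counts: CountsMatrix,
    design: DesignInfo,
    size_factors: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the NB GLM per feature and Wald-test the group coefficient.

    Returns a frame with feature_id, base_mean (mean of normalized counts),
    log2fc (centenarian vs control, = beta_group / ln 2), se (on the log2
    scale), wald_p, and a convergence flag.  All-zero and non-converged
    features get NA p-values.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if alpha is None:
        alpha = estimate_dispersion(counts, size_factors, design)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(counts.shape[0], float(alpha))
    X = design.matrix()
    Y = counts.values.astype(float)
    offset = np.log(size_factors)
    nonzero = Y.sum(axis=1) > 0

    beta = np.full((counts.shape[0], X.shape[1]), np.nan)
    se = np.full_like(beta, np.nan)
    conv = np.zeros(counts.shape[0], dtype=bool)
    if nonzero.any():
        b, s, c = _nb_irls(Y[nonzero], X, offset, alpha[nonzero])
        beta[nonzero] = b
        se[nonzero] = s
        conv[nonzero] = c

    log2fc = beta[:, 1] / LN2
    se_log2 = se[:, 1] / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, 1] / se[:, 1]
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p[~conv] = np.nan
    base_mean = (Y / size_factors[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_log2,
            "wald_p": wald_p,
            "converged": conv,
        }
    )


def nb_wald_test(
    counts_row,
    design: DesignInfo,
    size_factors: np.ndarray,
    alpha: float,
) -> pd.Series:
    """Single-feature convenience wrapper around :func:`nb_wald_table`."""
    cm = CountsMatrix(["feature"], design.sample_ids, np.asarray(counts_row)[None, :])
    table = nb_wald_table(cm, design, size_factors, np.array([alpha]))
    return table.iloc[0]


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NA propagated, excluded from m."""
    p = np.asarray(pvals, dtype=float)
    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return padj
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    padj[ok] = out
    return padj


def call_differential(
    results: pd.DataFrame,
    padj_max: float = 0.05,
    fc_min: float = 1.5,
    up_label: str = "opening",
    down_label: str = "closing",
) -> pd.DataFrame:
    """Set the significance call: padj < padj_max and |fold change| > fc_min.

    The fold-change threshold is on the linear scale (|log2fc| > log2(fc_min),
    strict), matching the study's "absolute fold change > 1.5".
    """
    df = results.copy()
    lfc_min = np.log2(fc_min)
    sig = df["padj"] < padj_max
    df["call"] = "ns"
    df.loc[sig & (df["log2fc"] > lfc_min), "call"] = up_label
    df.loc[sig & (df["log2fc"] < -lfc_min), "call"] = down_label
    return df


def run_differential(
    counts: CountsMatrix,
    sample_sheet: pd.DataFrame,
    include_sex: bool = True,
    padj_max: float = 0.05,
    fc_min: float = 1.5,
    up_label: str = "opening",
    down_label: str = "closing",
    alpha: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Full differential run: size factors, dispersion, Wald tests, BH, calls."""
    sheet = sample_sheet.set_index("sample_id").loc[counts.sample_ids].reset_index()
    design = DesignInfo.from_sample_sheet(sheet, include_sex=include_sex)
    size_factors = estimate_size_factors(counts)
    if alpha is None:
        alpha = estimate_dispersion(counts, size_factors, design)
    table = nb_wald_table(counts, design, size_factors, alpha)
    table["padj"] = adjust_bh(table["wald_p"])
    return call_differential(
        table, padj_max=padj_max, fc_min=fc_min,
        up_label=up_label, down_label=down_label,
    )
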