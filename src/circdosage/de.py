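"""Moderated differential expression.

One precision-weighted moderated linear-model stage serves both circRNAs and
genes.  Counts are transformed to log2-CPM, a mean-variance trend supplies
per-observation precision weights (with per-sample quality weights for
heterogeneous libraries), features are fit by weighted least squares against
a design with group, batch and optional subject covariates, and residual
variances are shrunk toward a common prior by closed-form empirical Bayes,
giving a moderated t-statistic with augmented degrees of freedom.

Call rules: circRNAs are significant at BH-adjusted p < 0.05 AND
|log2FC| > 1 (both strict); genes at BH-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

_SD_FLOOR = 1e-6


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison within one tissue (log2FC = case minus control)."""

    case: str
    control: str
    tissue: str

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValueError("case and control karyotypes must differ")

    @property
    def label(self) -> str:
        return f"{self.case}_vs_{self.control}_{self.tissue}"


@dataclass
class DESettings:
    """Thresholds and smoothing knobs for the DE stage."""

    gene_min_count: int = 20
    gene_min_samples_strict: int = 3  # "more than three" -> >= 4 samples
    lowess_span: float = 0.5
    sd_floor: float = _SD_FLOOR
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.gene_min_count < 0 or self.gene_min_samples_strict < 0:
            raise ValueError("thresholds must be non-negative")


def build_design(metadata: pd.DataFrame, contrast: ContrastSpec,
                 subject_covariate: bool = False
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix for a contrast: intercept, group, batch (reference-coded).

    Restricts ``metadata`` to the contrast's tissue and karyotypes, requires
    >= 2 samples per group, and drops batch (or subject) columns aliased with
    the columns already present, warning when it does.  Returns
    ``(design, sample_index)`` where ``sample_index`` selects the used rows
    of ``metadata``.
    """
    sel = metadata[(metadata["tissue"] == contrast.tissue)
                   & metadata["karyotype"].isin([contrast.case, contrast.control])]
    for group in (contrast.case, contrast.control):
        n = int((sel["karyotype"] == group).sum())
        if n < 2:
            raise ValueError(f"group {group} has {n} sample(s) in tissue "
                             f"{contrast.tissue}; need >= 2")
    design = pd.DataFrame(index=sel["sample_id"])
    design["intercept"] = 1.0
    design["group"] = (sel["karyotype"] == contrast.case).astype(float).to_numpy()

    def try_add(name: str, col: np.ndarray) -> None:
        trial = np.column_stack([design.to_numpy(), col])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(design.to_numpy()):
            design[name] = col
        else:
            warnings.warn(f"design column {name!r} aliased with existing columns; "
                          "dropped", UserWarning, stacklevel=3)

    batches = sorted(sel["batch"].unique())
    for b in batches[1:]:  # first batch is the reference
        try_add(f"batch_{b}", (sel["batch"] == b).astype(float).to_numpy())
    if subject_covariate:
        subjects = sorted(sel["subject_id"].unique())
        for s in subjects[1:]:
            try_add(f"subject_{s}",
                    (sel["subject_id"] == s).astype(float).to_numpy())
    return design, sel.index.to_numpy()


def log_cpm_transform(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((count + 0.5) / (libsize + 1) * 1e6)``.

    Library size is the per-sample column sum of the input matrix (for
    circRNAs: the circRNA-read total, consistent with circCPM).
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    y = np.log2((counts.to_numpy(dtype=float) + prior_count) / (lib + 1.0)[None, :] * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature OLS: returns (beta, fitted, residuals). y is features x samples."""
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    return beta, fitted, y - fitted


def estimate_precision_weights(y: pd.DataFrame, design: pd.DataFrame | np.ndarray,
                               span: float = 0.5, sd_floor: float = _SD_FLOOR,
                               quality_weights: bool = True,
                               ) -> pd.DataFrame:
    """Per-observation precision weights from the log-CPM mean-variance trend.

    Fits each feature by OLS, regresses sqrt residual SD on mean log-CPM with
    lowess (fraction ``span``), predicts each observation's SD from its fitted
    value and sets weight = predicted-sqrt-SD^(-4) (i.e. inverse predicted
    variance).  With ``quality_weights`` a per-sample factor downweights
    samples with systematically inflated standardized residuals (one
    moment-based refinement pass).
    """
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    ymat = y.to_numpy(dtype=float)
    n_feat, n_samp = ymat.shape
    p = X.shape[1]
    if n_feat < p + 1:
        raise ValueError(f"need more features ({n_feat}) than design columns ({p})")
    dof = n_samp - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    _, fitted, resid = _ols_fit(ymat, X)
    s = np.sqrt((resid ** 2).sum(axis=1) / dof)
    s = np.maximum(s, sd_floor)
    sqrt_s = np.sqrt(s)
    xbar = ymat.mean(axis=1)

    if np.ptp(xbar) < 1e-10 or np.ptp(sqrt_s) < 1e-12:
        # degenerate trend (e.g. all-equal input): flat at the floor-respecting mean
        pred = np.full_like(fitted, float(np.mean(sqrt_s)))
    else:
        trend = lowess(sqrt_s, xbar, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        tx, uniq = np.unique(tx, return_index=True)
        ty = ty[uniq]
        pred = np.interp(fitted, tx, ty)
    pred = np.maximum(pred, np.sqrt(sd_floor))
    w = pred ** -4.0

    if quality_weights:
        for _ in range(2):
            Xw_resid = _wls_residuals(ymat, X, w)
            s2 = np.maximum((w * Xw_resid ** 2).sum(axis=1) / dof, sd_floor ** 2)
            std2 = w * Xw_resid ** 2 / s2[:, None]
            m = std2.mean(axis=0) * n_samp / dof  # leverage-average correction
            qw = 1.0 / np.maximum(m, 1e-8)
            qw = qw / np.exp(np.mean(np.log(qw)))  # geometric-mean 1
            w = w * qw[None, :]
    return pd.DataFrame(w, index=y.index, columns=y.columns)


def _wls_residuals(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    XtWX = np.einsum("sp,fs,sq->fpq", X, w, X)
    XtWy = np.einsum("sp,fs,fs->fp", X, w, y)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
    return y - beta @ X.T


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def squeeze_variances(s2: np.ndarray, dof: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Method-of-moments on log s^2: with z = log(s2) - digamma(d/2) + log(d/2),
    the excess of var(z) over trigamma(d/2) estimates trigamma(d0/2), giving
    the prior df d0 and prior variance s0^2.  Returns
    ``(d0, s0^2, posterior variances)`` where the posterior is
    (d0*s0^2 + d*s^2) / (d0 + d).  Infinite d0 collapses every posterior to
    s0^2.
    """
    s2 = np.maximum(np.asarray(s2, float), _SD_FLOOR ** 2)
    z = np.log(s2)
    e = z - float(digamma(dof / 2.0)) + np.log(dof / 2.0)
    emean = float(np.mean(e))
    n = len(s2)
    if n < 2:
        return np.inf, float(np.exp(emean)), np.full(n, np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, dof / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0)))
        post = (d0 * s02 + dof * s2) / (d0 + dof)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        post = np.full(n, s02)
    return d0, s02, post


def fit_moderated(y: pd.DataFrame, weights: pd.DataFrame | None,
                  design: pd.DataFrame, contrast_column: str = "group",
                  prior_df: float | None = None) -> pd.DataFrame:
    """Weighted least squares per feature with empirical-Bayes moderated t.

    Returns a DataFrame (index = features) with columns log2fc, avg_log2_expr,
    t, p, plus the shrinkage diagnostics d0 and s2_post.  ``prior_df=0``
    switches moderation off (ordinary WLS t-statistics).
    """
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    if contrast_column not in cols:
        raise ValueError(f"contrast column {contrast_column!r} not in design")
    j = cols.index(contrast_column)
    ymat = y.to_numpy(dtype=float)
    n_feat, n_samp = ymat.shape
    p = X.shape[1]
    dof = n_samp - p
    if dof <= 0:
        raise ValueError("residual degrees of freedom <= 0")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    w = (np.ones_like(ymat) if weights is None
         else weights.to_numpy(dtype=float))
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")

    XtWX = np.einsum("sp,fs,sq->fpq", X, w, X)
    XtWy = np.einsum("sp,fs,fs->fp", X, w, ymat)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
    resid = ymat - beta @ X.T
    rss = (w * resid ** 2).sum(axis=1)
    s2 = rss / dof
    v = np.linalg.inv(XtWX)[:, j, j]

    if prior_df is None:
        d0, s02, s2_post = squeeze_variances(s2, dof)
    elif prior_df == 0:
        d0, s02, s2_post = 0.0, float("nan"), np.maximum(s2, _SD_FLOOR ** 2)
    elif np.isinf(prior_df):
        _, s02, _ = squeeze_variances(s2, dof)
        d0, s2_post = np.inf, np.full(n_feat, s02)
    else:
        _, s02, _ = squeeze_variances(s2, dof)
        d0 = float(prior_df)
        s2_post = (d0 * s02 + dof * s2) / (d0 + dof)

    se = np.sqrt(np.maximum(s2_post, _SD_FLOOR ** 2) * v)
    t = beta[:, j] / se
    df_total = dof + (d0 if np.isfinite(d0) else 0.0)
    if np.isinf(d0):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame({
        "log2fc": beta[:, j],
        "avg_log2_expr": ymat.mean(axis=1),
        "t": t,
        "p": pvals,
        "d0": d0,
        "s2_post": s2_post,
    }, index=y.index)


def bh_adjust(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(k) = min_{j >= k} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def prefilter_genes(counts: pd.DataFrame, settings: DESettings | None = None
                    ) -> pd.DataFrame:
    """Keep genes with >= gene_min_count counts in MORE THAN
    gene_min_samples_strict samples (default: >= 20 counts in >= 4 samples)."""
    settings = settings or DESettings()
    n_ok = (counts >= settings.gene_min_count).sum(axis=1)
    return counts.loc[n_ok > settings.gene_min_samples_strict]


def call_decs(results: pd.DataFrame, lfc: float = 1.0, alpha: float = 0.05
              ) -> pd.DataFrame:
    """Significant circRNAs: adjusted p strictly below alpha AND |log2FC|
    strictly above lfc.  Expects columns log2fc and p_adj."""
    mask = (results["p_adj"] < alpha) & (results["log2fc"].abs() > lfc)
    return results.loc[mask]


def call_degs(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant genes: adjusted p strictly below alpha."""
    return results.loc[results["p_adj"] < alpha]


def run_de(counts: pd.DataFrame, metadata: pd.DataFrame, contrast: ContrastSpec,
           settings: DESettings | None = None, feature_kind: str = "circ",
           subject_covariate: bool = False) -> pd.DataFrame:
    """End-to-end DE for one contrast: design, transform, weights, moderated fit.

    Returns per-feature log2fc, avg_log2_expr, t, p, p_adj and ``significant``
    (circRNA rule: adj p < alpha and |log2FC| > lfc; gene rule: adj p < alpha).
    """
    settings = settings or DESettings()
    design, rows = build_design(metadata, contrast, subject_covariate=subject_covariate)
    sub = counts.loc[:, metadata.loc[rows, "sample_id"]]
    if feature_kind == "gene":
        sub = prefilter_genes(sub, settings)
    y = log_cpm_transform(sub)
    w = estimate_precision_weights(y, design, span=settings.lowess_span,
                                   sd_floor=settings.sd_floor)
    res = fit_moderated(y, w, design, "group")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    if feature_kind == "gene":
        res["significant"] = res["p_adj"] < settings.alpha
    else:
        res["significant"] = ((res["p_adj"] < settings.alpha)
                              & (res["log2fc"].abs() > settings.lfc_threshold))
    return res
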