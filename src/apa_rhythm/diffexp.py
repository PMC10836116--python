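"""Differential PAC expression between sleep-deprivation recovery groups and
time-matched controls.

Per contrast the pipeline is: depth normalization (median-of-ratios size
factors) -> log2 transform -> removal of the first principal component ->
back-transform -> per-PAC negative-binomial dispersion (method of moments
shrunk to a mean--dispersion trend) -> NB Wald test -> empirical-Bayes LFC
shrinkage under a zero-centered Cauchy prior -> BH adjustment and an
empirical-null local FDR on the Wald z-scores.

This is a transparent reimplementation of the essential statistical core of
the mainstream NB DE toolchain: no Cook's-distance outlier handling and no
independent filtering.  The NB parameterization is var = mu + alpha*mu^2
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contrast",
    "DEFAULT_CONTRASTS",
    "size_factors",
    "remove_pc1",
    "remove_pc1_protected",
    "estimate_dispersion",
    "nb_wald",
    "nb_wald_matrix",
    "shrink_lfc",
    "local_fdr",
    "run_contrasts",
]

_ALPHA_FLOOR = 1e-8


@dataclass(frozen=True)
class Contrast:
    treatment: str
    control: str

    @property
    def name(self) -> str:
        return f"{self.treatment}_vs_{self.control}"


DEFAULT_CONTRASTS = (
    Contrast("R0", "ZT6"),
    Contrast("R2", "ZT8"),
    Contrast("R4", "ZT10"),
    Contrast("R8", "ZT14"),
)


# ---------------------------------------------------------------------------
# normalization and PC1 removal


def size_factors(counts: np.ndarray, min_informative: int = 50) -> np.ndarray:
    """Median-of-ratios size factors (fallback: library totals).

    Uses PACs with all-nonzero counts as the reference set; if fewer than
    ``min_informative`` such rows exist, falls back to column totals scaled
    to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    nonzero = np.all(counts > 0, axis=1)
    if nonzero.sum() >= min_informative:
        ref = counts[nonzero]
        log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    else:
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("sample with zero total counts; cannot compute size factors")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def remove_pc1(matrix: np.ndarray, back_transform: bool = False) -> np.ndarray:
    """Subtract the first principal component of a (PAC x sample) log matrix.

    Rows are centered, the rank-1 term of the leading singular triplet is
    subtracted, and row means are restored -- per-PAC means are preserved and
    the operation is idempotent on the log scale.  With ``back_transform``
    the result is mapped back to the count scale as ``2**x - 1`` floored at
    zero for downstream NB fitting.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    row_means = X.mean(axis=1, keepdims=True)
    C = X - row_means
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    C1 = s[0] * np.outer(U[:, 0], Vt[0])
    corrected = C - C1 + row_means
    if back_transform:
        return np.maximum(np.exp2(corrected) - 1.0, 0.0)
    return corrected


def remove_pc1_protected(
    matrix: np.ndarray, groups: np.ndarray, back_transform: bool = False
) -> np.ndarray:
    """Design-protected variant of :func:`remove_pc1`.

    The nuisance direction is the leading right singular vector of the
    residuals after removing per-PAC group means, then orthogonalized
    against the group-indicator subspace, so projecting it out leaves every
    group mean exactly unchanged -- a planted treatment effect cannot be
    absorbed even when it dominates the variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    groups = np.asarray(groups)
    resid = X.copy()
    design_cols = []
    for g in np.unique(groups):
        mask = groups == g
        resid[:, mask] -= X[:, mask].mean(axis=1, keepdims=True)
        design_cols.append(mask.astype(float))
    _, _, Vt = np.linalg.svd(resid, full_matrices=False)
    v = Vt[0]
    D, _ = np.linalg.qr(np.column_stack(design_cols))
    v = v - D @ (D.T @ v)
    norm = np.linalg.norm(v)
    corrected = X if norm < 1e-8 else X - np.outer(X @ (v / norm), v / norm)
    if back_transform:
        return np.maximum(np.exp2(corrected) - 1.0, 0.0)
    return corrected


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(
    matrix: np.ndarray,
    groups: np.ndarray,
    trend_weight: float = 0.2,
    var_inflation: float = 1.0,
) -> np.ndarray:
    """Per-PAC NB dispersion alpha (var = mu + alpha*mu^2).

    Method of moments within each group, pooled across groups, then shrunk
    (geometric interpolation with weight ``trend_weight`` on the raw value)
    toward a fitted ``a1 + a0/mean`` mean--dispersion trend.  The default
    weight leans heavily on the trend because per-PAC moments are very noisy
    at 5 replicates/group and noisy dispersions make the Wald test
    anti-conservative.  Floored at 1e-8; zero-mean PACs get NaN (tested
    downstream with p = 1).

    ``var_inflation`` rescales the observed group variances; callers that
    have projected out a nuisance direction pass the lost-degree-of-freedom
    correction ``d/(d-1)`` so dispersion is not deflated.
    """
    Y = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    num = np.zeros(Y.shape[0])
    wsum = 0.0
    mean_all = np.zeros(Y.shape[0])
    for g in labels:
        sub = Y[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g!r} has < 2 replicates")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1) * var_inflation
        w = sub.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            num += w * (v - m) / m**2
        mean_all += sub.sum(axis=1)
        wsum += w
    mean_all /= Y.shape[1]
    alpha_raw = np.maximum(num / wsum, 0.0)
    ok = np.isfinite(alpha_raw) & (mean_all > 0)

    # mean--dispersion trend alpha ~ a1 + a0/mean, least squares on raw values
    alpha_trend = np.full_like(alpha_raw, _ALPHA_FLOOR)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_raw[ok], rcond=None)
        alpha_trend = np.maximum(coef[0] + coef[1] / np.maximum(mean_all, 1e-8), _ALPHA_FLOOR)

    log_raw = np.log(np.maximum(alpha_raw, _ALPHA_FLOOR))
    log_trend = np.log(alpha_trend)
    alpha = np.exp(trend_weight * log_raw + (1.0 - trend_weight) * log_trend)
    alpha = np.maximum(alpha, _ALPHA_FLOOR)
    alpha[~ok] = np.nan
    return alpha


# ---------------------------------------------------------------------------
# NB Wald test


def nb_wald_matrix(
    counts: np.ndarray,
    groups: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Vectorized two-group NB log-linear Wald test.

    Model per PAC: log mu = b0 + b1*[treatment] + log(size factor); Fisher
    scoring with NB2 working weights mu/(1 + alpha*mu); Wald z = b1/SE(b1)
    with a two-sided normal p; log2fc = b1/ln 2.  PACs that are all-zero (or
    have undefined dispersion) report lfc 0, p 1.
    """
    Y = np.asarray(counts, dtype=float)
    g = np.asarray(groups, dtype=float)  # 1 = treatment, 0 = control
    sf = np.asarray(sf, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if alpha.size == 1:
        alpha = np.full(Y.shape[0], float(alpha[0]))
    n_pac = Y.shape[0]
    off = np.log(sf)[None, :]

    bad = ~np.isfinite(alpha) | (Y.sum(axis=1) == 0)
    a = np.where(bad, 0.0, alpha)[:, None]

    # initialize from group means on the depth-normalized scale
    norm = Y / sf[None, :]
    m1 = norm[:, g == 1].mean(axis=1)
    m0 = norm[:, g == 0].mean(axis=1)
    b0 = np.log(np.maximum(m0, 1e-8))
    b1 = np.log(np.maximum(m1, 1e-8)) - b0

    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * g[None, :] + off
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + a * mu)
        z = (eta - off) + (Y - mu) / np.maximum(mu, 1e-12)
        sw = W.sum(axis=1)
        swg = (W * g).sum(axis=1)
        swgg = (W * g * g).sum(axis=1)
        swz = (W * z).sum(axis=1)
        swzg = (W * z * g).sum(axis=1)
        det = sw * swgg - swg**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (swgg * swz - swg * swzg) / det
        new_b1 = (sw * swzg - swg * swz) / det
        new_b0 = np.clip(np.nan_to_num(new_b0, nan=0.0), -30.0, 30.0)
        new_b1 = np.clip(np.nan_to_num(new_b1, nan=0.0), -30.0, 30.0)
        delta = np.max(np.abs(new_b0 - b0) + np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break

    eta = b0[:, None] + b1[:, None] * g[None, :] + off
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + a * mu)
    sw = W.sum(axis=1)
    swg = (W * g).sum(axis=1)
    swgg = (W * g * g).sum(axis=1)
    det = sw * swgg - swg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(np.maximum(var_b1, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(wald_z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    ln2 = np.log(2.0)
    out = {
        "log2fc_mle": b1 / ln2,
        "se": se / ln2,
        "wald_z": wald_z,
        "p": p,
        "base_mean": norm.mean(axis=1),
    }
    for key in ("log2fc_mle", "wald_z"):
        out[key] = np.where(bad, 0.0, out[key])
    out["p"] = np.where(bad, 1.0, out["p"])
    out["se"] = np.where(bad, np.inf, out["se"])
    return out


def nb_wald(
    counts: np.ndarray,
    groups: np.ndarray,
    size_factors_: np.ndarray,
    alpha: float | np.ndarray,
) -> dict[str, float]:
    """Scalar convenience wrapper for one PAC (see :func:`nb_wald_matrix`)."""
    r = nb_wald_matrix(np.atleast_2d(counts), groups, size_factors_, alpha)
    return {k: float(v[0]) for k, v in r.items()}


# ---------------------------------------------------------------------------
# LFC shrinkage


def _fit_prior_scale(lfc: np.ndarray, se: np.ndarray, floor: float = 0.05) -> float:
    """Cauchy prior scale from the excess spread of the MLEs over their SEs."""
    ok = np.isfinite(lfc) & np.isfinite(se)
    if not ok.any():
        return floor
    excess = np.quantile(lfc[ok] ** 2, 0.95) - np.quantile(se[ok] ** 2, 0.95)
    return float(max(np.sqrt(max(excess, 0.0)), floor))


def shrink_lfc(
    lfc_mle: np.ndarray,
    se: np.ndarray,
    prior_scale: float | None = None,
) -> np.ndarray:
    """Posterior-mode LFC under a zero-centered Cauchy prior.

    Normal approximation to the likelihood at the MLE; the mode solves the
    cubic stationarity condition of ``(b - bhat)^2/(2 se^2) +
    log(1 + (b/A)^2)`` and always lies between 0 and the MLE, so shrinkage
    can never flip the sign.  Non-finite SEs (all-zero groups) shrink to 0.
    """
    lfc = np.asarray(lfc_mle, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_scale is None:
        prior_scale = _fit_prior_scale(lfc, se)
    A2 = prior_scale**2
    out = np.zeros_like(lfc)
    for k in range(lfc.size):
        b, s = lfc[k], se[k]
        if b == 0.0 or not np.isfinite(s):
            continue
        if s == 0.0:
            out[k] = b
            continue
        # (beta - b)(A^2 + beta^2) + 2 s^2 beta = 0
        roots = np.roots([1.0, -b, A2 + 2.0 * s**2, -b * A2])
        real = roots[np.abs(roots.imag) < 1e-9].real
        lo, hi = (0.0, b) if b > 0 else (b, 0.0)
        cand = real[(real >= lo - 1e-12) & (real <= hi + 1e-12)]
        if cand.size == 0:
            # fallback: normal-prior closed form
            out[k] = b * A2 / (A2 + s**2)
            continue
        obj = (cand - b) ** 2 / (2 * s**2) + np.log1p(cand**2 / A2)
        out[k] = float(np.clip(cand[np.argmin(obj)], lo, hi))
    return out


# ---------------------------------------------------------------------------
# local FDR


def local_fdr(z_values: np.ndarray, min_n: int = 200) -> np.ndarray:
    """Empirical-null local FDR on z-scores.

    Null N(delta, sigma) by central matching (median / scaled MAD), mixture
    density by Gaussian KDE, pi0 from the mass of the central +-1 sigma
    region; lfdr = clip(pi0 * f0 / f, 0, 1).  With fewer than ``min_n``
    values the estimate is unstable: returns NaN with a warning (callers
    fall back to BH only).
    """
    z = np.asarray(z_values, dtype=float)
    if z.size < min_n:
        warnings.warn(
            f"only {z.size} z-values (< {min_n}); local FDR not estimated",
            stacklevel=2,
        )
        return np.full(z.size, np.nan)
    delta = float(np.median(z))
    sigma = float(stats.median_abs_deviation(z, scale="normal"))
    if sigma == 0:
        return np.full(z.size, np.nan)
    central = np.abs(z - delta) <= sigma
    pi0 = min(1.0, central.mean() / (stats.norm.cdf(1) - stats.norm.cdf(-1)))
    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    f0 = stats.norm.pdf(z, delta, sigma)
    return np.clip(pi0 * f0 / f, 0.0, 1.0)


# ---------------------------------------------------------------------------
# contrast driver


def run_contrasts(
    matrix: pd.DataFrame,
    samples: list,
    contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.5,
    multi_apa_genes: set[str] | None = None,
    pac_gene: dict[str, str] | None = None,
    pc1_removal: bool = True,
) -> pd.DataFrame:
    """Full DE pipeline for each treatment/control contrast.

    ``matrix`` is the raw (PAC x sample) count table with sample-id columns.
    Flags PACs passing (p < ``p_threshold`` and |shrunk log2FC| >
    ``lfc_threshold``); when gene annotations are supplied, additionally
    flags those in multi-APA genes.  Returns the concatenated per-contrast
    table.
    """
    by_cond: dict[str, list[str]] = {}
    for s in samples:
        by_cond.setdefault(s.condition, []).append(s.sample_id)
    tables = []
    for contrast in contrasts:
        for cond in (contrast.treatment, contrast.control):
            if cond not in by_cond:
                raise ValueError(f"missing condition group {cond!r} for contrast {contrast.name}")
        cols = by_cond[contrast.control] + by_cond[contrast.treatment]
        groups = np.array(
            [0] * len(by_cond[contrast.control]) + [1] * len(by_cond[contrast.treatment])
        )
        raw = matrix[cols].to_numpy(dtype=float)
        sf = size_factors(raw)
        norm = raw / sf[None, :]
        if pc1_removal:
            corrected = remove_pc1_protected(
                np.log2(norm + 1.0), groups, back_transform=True
            )
            # one residual direction was projected out of the
            # (samples - groups) residual degrees of freedom
            d = len(cols) - len(np.unique(groups))
            var_inflation = d / (d - 1) if d > 1 else 1.0
        else:
            corrected = norm
            var_inflation = 1.0
        alpha = estimate_dispersion(corrected, groups, var_inflation=var_inflation)
        res = nb_wald_matrix(corrected, groups, np.ones(len(cols)), alpha)
        shrunk = shrink_lfc(res["log2fc_mle"], res["se"])
        p_bh = stats.false_discovery_control(res["p"], method="bh")
        lfdr = local_fdr(res["wald_z"])
        df = pd.DataFrame(
            {
                "pac_id": matrix.index,
                "contrast": contrast.name,
                "base_mean": res["base_mean"],
                "log2fc_mle": res["log2fc_mle"],
                "log2fc_shrunk": shrunk,
                "se": res["se"],
                "wald_z": res["wald_z"],
                "p": res["p"],
                "p_bh": p_bh,
                "lfdr": lfdr,
            }
        )
        df["significant"] = (df["p"] < p_threshold) & (
            df["log2fc_shrunk"].abs() > lfc_threshold
        )
        if multi_apa_genes is not None and pac_gene is not None:
            df["significant_multi_apa"] = df["significant"] & df["pac_id"].map(
                lambda pid: pac_gene.get(pid) in multi_apa_genes
            )
        tables.append(df)
    return pd.concat(tables, ignore_index=True)
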