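"""Single-series rhythm detectors and their meta-integration.

Three detectors share amplitude/phase conventions (acrophase = clock time of
the fitted peak, on the period circle):

* :func:`cosinor_fit` — harmonic least squares with an F-test against the
  constant model;
* :func:`lomb_scargle` — classical normalized periodogram power at the single
  target frequency, ``p = exp(-P)``;
* :func:`jtk_cycle` — best Kendall tau-b against a grid of phase-lagged
  cosine references, exact enumeration null, Bonferroni over lags.

Detector p-values are combined per series by Fisher's method
(:func:`integrate_meta`); phases by the circular mean.

Scalar entry points wrap vectorized ``*_matrix`` implementations that operate
on a (series x timepoint) matrix at once; the heavy pipeline stages call the
matrix forms directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeries",
    "DetectorResult",
    "cosinor_fit",
    "lomb_scargle",
    "jtk_cycle",
    "integrate_meta",
    "jtk_exact_null",
    "circular_mean",
    "cosinor_matrix",
    "lomb_scargle_matrix",
    "jtk_matrix",
    "fisher_matrix",
]

_TINY = np.finfo(float).tiny


@dataclass
class TimeSeries:
    """One trial's series: strictly increasing times (ZT hours) and values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) < 4:
            raise ValueError("need >= 4 timepoints for any fit")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DetectorResult:
    method: str
    p: float
    phase_h: float
    amplitude: float
    statistic: float


def circular_mean(phases: np.ndarray, period: float) -> float:
    """Circular mean of phases (hours) on the period circle, in [0, period)."""
    ang = 2.0 * np.pi * np.asarray(phases, dtype=float) / period
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    out = (mean_ang * period / (2.0 * np.pi)) % period
    return float(out if out < period else 0.0)


# ---------------------------------------------------------------------------
# cosinor


def cosinor_matrix(
    times: np.ndarray, values: np.ndarray, period_h: float
) -> dict[str, np.ndarray]:
    """Harmonic regression y = M + A*cos(2*pi*(t - phi)/period) per row.

    Returns arrays ``p``, ``phase``, ``amplitude``, ``statistic`` (the F
    statistic with (2, n-3) df against the constant model).  Constant rows
    get A=0, F=0, p=1; perfect fits get p at the floating-point minimum.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n = t.size
    omega = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, nser)
    fitted = (X @ beta).T
    rss1 = np.sum((Y - fitted) ** 2, axis=1)
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    scale = np.maximum(rss0, 1.0) * 1e-12
    df2 = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    p = np.ones_like(f_stat)
    perfect = (rss1 <= scale) & (rss0 > scale)
    constant = rss0 <= scale
    regular = ~perfect & ~constant
    p[regular] = stats.f.sf(f_stat[regular], 2, df2)
    p[perfect] = _TINY
    f_stat[perfect] = np.inf
    f_stat[constant] = 0.0
    p = np.clip(p, _TINY, 1.0)

    amp = np.hypot(beta[1], beta[2])
    amp[constant] = 0.0
    phase = (np.arctan2(beta[2], beta[1]) / omega) % period_h
    phase[constant] = 0.0
    return {"p": p, "phase": phase, "amplitude": amp, "statistic": f_stat}


def cosinor_fit(series: TimeSeries, period_h: float = 24.0) -> DetectorResult:
    """Least-squares cosinor fit; F-test with (2, n-3) df vs the constant model."""
    r = cosinor_matrix(series.times, series.values, period_h)
    return DetectorResult(
        "COSINOR", float(r["p"][0]), float(r["phase"][0]),
        float(r["amplitude"][0]), float(r["statistic"][0]),
    )


# ---------------------------------------------------------------------------
# Lomb-Scargle


def lomb_scargle_matrix(
    times: np.ndarray, values: np.ndarray, period_h: float, p_mode: str = "exact"
) -> dict[str, np.ndarray]:
    """Classical normalized periodogram power at one frequency, per row.

    Power uses the per-frequency time offset tau and is normalized by the
    sample variance (ddof=1), so a noiseless sinusoid on an even grid gives
    P = (n-1)/2.  The default single-frequency p-value is the exact
    finite-sample null ``p = (1 - 2P/(n-1))**((n-3)/2)``; the large-n
    asymptotic form ``p = exp(-P)`` is available as ``p_mode="asymptotic"``
    but is anti-conservative for short series.  Phase and amplitude come
    from the equivalent least-squares sinusoid fit.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n = t.size
    omega = 2.0 * np.pi / period_h
    tau = np.arctan2(np.sum(np.sin(2 * omega * t)), np.sum(np.cos(2 * omega * t))) / (
        2 * omega
    )
    c = np.cos(omega * (t - tau))
    s = np.sin(omega * (t - tau))
    yc = Y - Y.mean(axis=1, keepdims=True)
    var = np.sum(yc**2, axis=1) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = (
            (yc @ c) ** 2 / np.sum(c**2) + (yc @ s) ** 2 / np.sum(s**2)
        ) / (2.0 * var)
    power = np.where(var > 0, power, 0.0)
    if p_mode == "exact":
        base = np.maximum(1.0 - 2.0 * power / (n - 1), 0.0)
        p = np.clip(base ** ((n - 3) / 2.0), _TINY, 1.0)
    elif p_mode == "asymptotic":
        p = np.clip(np.exp(-power), _TINY, 1.0)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    cos_fit = cosinor_matrix(t, Y, period_h)
    return {
        "p": p,
        "phase": cos_fit["phase"],
        "amplitude": cos_fit["amplitude"],
        "statistic": power,
    }


def lomb_scargle(
    series: TimeSeries, period_h: float = 24.0, p_mode: str = "exact"
) -> DetectorResult:
    r = lomb_scargle_matrix(series.times, series.values, period_h, p_mode)
    return DetectorResult(
        "LS", float(r["p"][0]), float(r["phase"][0]),
        float(r["amplitude"][0]), float(r["statistic"][0]),
    )


# ---------------------------------------------------------------------------
# JTK-style Kendall tau test


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i, j


@lru_cache(maxsize=64)
def _null_cache(ref_key: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted |tau-b| null values and exact tau values over all n! orderings.

    The null enumerates every ordering of a tie-free data vector against the
    (possibly tied) reference; data ties in observed series are handled by
    tau-b but share this tie-free null (a conservative approximation).
    """
    ref = np.array(ref_key)
    n = ref.size
    if n > 10:
        raise ValueError("exact enumeration null limited to n <= 10")
    i, j = _pair_indices(n)
    ref_sign = np.sign(ref[i] - ref[j])
    n0 = i.size
    n2 = int(np.sum(ref_sign == 0))
    denom = np.sqrt(n0 * (n0 - n2))
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    data_sign = np.sign(perms[:, i] - perms[:, j])
    taus = (data_sign @ ref_sign) / denom
    return np.sort(np.abs(taus)), taus


def jtk_exact_null(ref: np.ndarray) -> np.ndarray:
    """Exact null distribution of tau-b vs ``ref`` over all orderings of tie-free data."""
    ref = np.round(np.asarray(ref, dtype=float), 9)
    return _null_cache(tuple(ref))[1].copy()


def _jtk_references(times: np.ndarray, period_h: float, phase_grid_h) -> list[tuple[float, np.ndarray]]:
    # default grid at the sampling resolution over half the period: the
    # reference at lag phi + period/2 is the negation of the one at phi, so
    # with a two-sided tau test the second half adds no new tests and would
    # only inflate the Bonferroni correction
    if phase_grid_h is None:
        step = float(np.median(np.diff(times)))
        phase_grid_h = np.arange(0.0, period_h / 2.0, step)
    return [
        (float(lag), np.cos(2.0 * np.pi * (times - lag) / period_h))
        for lag in phase_grid_h
    ]


def jtk_matrix(
    times: np.ndarray,
    values: np.ndarray,
    period_h: float,
    phase_grid_h=None,
) -> dict[str, np.ndarray]:
    """Vectorized JTK-style test: best |tau-b| over phase-lagged cosine references.

    Per-lag two-sided p from the exact enumeration null; the reported p is
    Bonferroni-adjusted for the number of lags and capped at 1.  All-tied
    rows get tau = 0, p = 1.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n = t.size
    refs = _jtk_references(t, period_h, phase_grid_h)
    n_lags = len(refs)
    i, j = _pair_indices(n)
    n0 = i.size
    data_sign = np.sign(Y[:, i] - Y[:, j])
    n1 = np.sum(data_sign == 0, axis=1)

    best_abs_tau = np.zeros(Y.shape[0])
    best_tau = np.zeros(Y.shape[0])
    best_p = np.ones(Y.shape[0])
    best_lag = np.zeros(Y.shape[0])
    for lag, ref in refs:
        ref = np.round(ref, 9)
        ref_sign = np.sign(ref[i] - ref[j])
        n2 = int(np.sum(ref_sign == 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt((n0 - n1).astype(float) * (n0 - n2))
            tau = (data_sign @ ref_sign) / denom
        tau = np.where(denom > 0, tau, 0.0)
        null_abs, _ = _null_cache(tuple(ref))
        # two-sided exact p: fraction of enumerated |tau| >= |tau_obs|
        idx = np.searchsorted(null_abs, np.abs(tau) - 1e-9, side="left")
        p_lag = (null_abs.size - idx) / null_abs.size
        better = np.abs(tau) > best_abs_tau
        best_abs_tau = np.where(better, np.abs(tau), best_abs_tau)
        best_tau = np.where(better, tau, best_tau)
        best_p = np.where(better, p_lag, best_p)
        best_lag = np.where(better, lag, best_lag)

    p = np.minimum(best_p * n_lags, 1.0)
    # peak of the best-matching reference: the lag itself for tau>0, the
    # antiphase for tau<0
    phase = np.where(best_tau >= 0, best_lag, (best_lag + period_h / 2.0)) % period_h
    cos_fit = cosinor_matrix(t, Y, period_h)
    return {
        "p": p,
        "phase": phase,
        "amplitude": cos_fit["amplitude"],
        "statistic": best_tau,
    }


def jtk_cycle(
    series: TimeSeries, period_h: float = 24.0, phase_grid_h=None
) -> DetectorResult:
    """Exact-null Kendall-tau cosine-reference test (n <= 10)."""
    r = jtk_matrix(series.times, series.values, period_h, phase_grid_h)
    return DetectorResult(
        "JTK", float(r["p"][0]), float(r["phase"][0]),
        float(r["amplitude"][0]), float(r["statistic"][0]),
    )


# ---------------------------------------------------------------------------
# meta-integration


def fisher_matrix(p_matrix: np.ndarray) -> np.ndarray:
    """Fisher's method row-wise: X2 = -2*sum(ln p) ~ chi2 with 2k df."""
    P = np.clip(np.atleast_2d(np.asarray(p_matrix, dtype=float)), _TINY, 1.0)
    x2 = -2.0 * np.sum(np.log(P), axis=1)
    return np.clip(stats.chi2.sf(x2, 2 * P.shape[1]), _TINY, 1.0)


def integrate_meta(
    results: list[DetectorResult], period_h: float = 24.0
) -> tuple[float, float, float]:
    """Combine detector results: Fisher meta-p, circular mean phase, cosinor amplitude."""
    if not results:
        raise ValueError("need at least one detector result")
    meta_p = fisher_matrix(np.array([[r.p for r in results]]))[0]
    phases = np.array([r.phase_h for r in results])
    meta_phase = circular_mean(phases, period_h)
    cos = [r for r in results if r.method == "COSINOR"]
    meta_amp = cos[0].amplitude if cos else float(np.mean([r.amplitude for r in results]))
    return float(meta_p), meta_phase, meta_amp
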