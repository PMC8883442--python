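"""Logistic fits to liquid-culture OD595 time series.

Batch yeast growth over 24 h is summarised by a four-parameter logistic,
``OD(t) = baseline + (K - baseline) / (1 + exp(-r (t - t0)))``: starting
density ``baseline``, carrying capacity ``K`` (both OD units), growth rate
``r`` (per hour), and inflection time ``t0`` (hours).  Wild-type versus
kinase-dead comparisons are made on a scalar metric per curve — the area
under the curve by default, because it remains well defined for strongly
inhibited, non-sigmoid curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class GrowthCurve:
    """One OD595 time series (times in hours, strictly increasing)."""

    sample: str
    condition: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.od.size:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass
class LogisticFit:
    """Result of a least-squares logistic fit."""

    K: float
    r: float
    t0: float
    baseline: float
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def logistic(t: np.ndarray, K: float, r: float, t0: float, baseline: float) -> np.ndarray:
    return baseline + (K - baseline) / (1.0 + np.exp(-r * (t - t0)))


def fit_logistic(curve: GrowthCurve, init: dict | None = None) -> LogisticFit:
    """Least-squares logistic fit of a growth curve.

    Default initialisation: baseline = first OD, K = max OD, t0 = time at
    which OD first crosses half the observed range, r = 0.5/h.  A curve with
    essentially no amplitude (range below 2% of its maximum or 0.02 OD) is
    flagged degenerate without fitting; optimizer failure is reported via
    ``converged=False``, never silently.
    """
    t, od = curve.times, curve.od
    if t.size < 8:
        raise ValueError(f"need at least 8 time points, got {t.size}")

    od_range = float(od.max() - od.min())
    if od_range < max(0.02, 0.02 * float(od.max())):
        return LogisticFit(
            K=float(od.mean()),
            r=0.0,
            t0=float(t.mean()),
            baseline=float(od.mean()),
            rss=float(np.sum((od - od.mean()) ** 2)),
            converged=False,
            degenerate=True,
            message="flat curve: amplitude below detection",
        )

    if init is None:
        half = od.min() + od_range / 2.0
        crossing = np.flatnonzero(od >= half)
        t0_init = float(t[crossing[0]]) if crossing.size else float(t[t.size // 2])
        init = dict(K=float(od.max()), r=0.5, t0=t0_init, baseline=float(od[0]))
    p0 = [init["K"], init["r"], init["t0"], init["baseline"]]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(logistic, t, od, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return LogisticFit(
            K=float("nan"),
            r=float("nan"),
            t0=float("nan"),
            baseline=float("nan"),
            rss=float("nan"),
            converged=False,
            message=f"optimizer failed: {exc}",
        )

    K, r, t0, baseline = (float(v) for v in popt)
    # canonical orientation: a logistic with r<0 and swapped asymptotes is the
    # same function; report the increasing-rate parameterisation
    if r < 0:
        K, baseline, r = baseline, K, -r
    rss = float(np.sum((logistic(t, K, r, t0, baseline) - od) ** 2))
    ok = bool(np.isfinite([K, r, t0, baseline]).all() and r > 0 and K > baseline)
    return LogisticFit(
        K=K,
        r=r,
        t0=t0,
        baseline=baseline,
        rss=rss,
        converged=ok,
        degenerate=False,
        message="" if ok else "fit did not satisfy K > baseline, r > 0",
    )


def curve_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the curve, in OD * hours."""
    if curve.times.size < 2:
        raise ValueError("need at least 2 points for an integral")
    return float(np.trapezoid(curve.od, curve.times))


@dataclass
class EffectSummary:
    """Wild-type vs kinase-dead growth comparison on a scalar metric."""

    metric: str
    effect: float  # mean(kd) - mean(wt); positive = WT kinase inhibits growth
    wt_values: list[float]
    kd_values: list[float]
    wt_sd: float
    kd_sd: float


def _metric_values(curves: list[GrowthCurve], metric: str) -> list[float] | None:
    if metric == "auc":
        return [curve_auc(c) for c in curves]
    if metric == "max_od":
        return [float(c.od.max()) for c in curves]
    if metric == "K":
        values = []
        for c in curves:
            fit = fit_logistic(c)
            if not fit.converged:
                return None
            values.append(fit.K)
        return values
    raise ValueError(f"unknown metric {metric!r}")


def compare_wt_kd(
    wt: list[GrowthCurve],
    kd: list[GrowthCurve],
    metric: str = "auc",
) -> EffectSummary:
    """Compare wild-type and kinase-dead replicate curves.

    ``effect = mean(metric_kd) - mean(metric_wt)``; a positive effect means
    the active (wild-type) kinase inhibits growth.  When ``metric="K"`` and
    any fit fails to converge, the comparison falls back to AUC with a
    warning.
    """
    if not wt or not kd:
        raise ValueError("need at least one replicate curve per group")
    wt_vals = _metric_values(wt, metric)
    kd_vals = _metric_values(kd, metric) if wt_vals is not None else None
    if wt_vals is None or kd_vals is None:
        warnings.warn(
            "non-converged logistic fit; falling back to AUC metric", stacklevel=2
        )
        metric = "auc"
        wt_vals = _metric_values(wt, metric)
        kd_vals = _metric_values(kd, metric)
    assert wt_vals is not None and kd_vals is not None
    return EffectSummary(
        metric=metric,
        effect=float(np.mean(kd_vals) - np.mean(wt_vals)),
        wt_values=wt_vals,
        kd_values=kd_vals,
        wt_sd=float(np.std(wt_vals, ddof=1)) if len(wt_vals) > 1 else 0.0,
        kd_sd=float(np.std(kd_vals, ddof=1)) if len(kd_vals) > 1 else 0.0,
    )
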