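"""Critical performance measures (CPMs), tuning cost and statistics.

Conventions: glucose series are the sampled trajectories (one sample per
minute), ``Gref`` is the setpoint (80 mg/dL).  Timing metrics are
reported in minutes.

* ``E_rms``  root-mean-square glucose error (mg/dL)
* ``E_sa``   sum of absolute glucose errors (mg/dL)
* ``T_fall`` first time BG falls to within +10% of Gref
* ``T_set``  first time after which BG stays within +/-5% of Gref
* ``T_rec``  settling time of the post-disturbance window, measured from
             the event
* ``OS``     overshoot above Gref after a transient disturbance (mg/dL)
* ``U_ms``   mean-square insulin rate ((mU/min)^2)
* ``U_p``    peak insulin rate in a window (mU/min)
* ``J``      offline tuning cost |T_set| + int(e^2 + u^2) dt
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "CPMReport",
    "TTestResult",
    "MetricUndefinedError",
    "e_rms",
    "e_sa",
    "u_ms",
    "t_fall",
    "t_set",
    "t_rec",
    "overshoot",
    "u_peak",
    "objective_j",
    "cpm_report",
    "confidence_interval",
    "welch_t_test",
    "render_cpm_table",
]


class MetricUndefinedError(ValueError):
    """Raised when a timing metric is undefined for the given series."""


def e_rms(errors: Sequence[float]) -> float:
    """Root-mean-square of the sampled glucose error."""
    e = np.asarray(errors, float)
    if e.size == 0:
        raise ValueError("empty error series")
    return float(np.sqrt(np.mean(e**2)))


def e_sa(errors: Sequence[float]) -> float:
    """Sum of absolute sampled glucose errors."""
    e = np.asarray(errors, float)
    if e.size == 0:
        raise ValueError("empty error series")
    return float(np.sum(np.abs(e)))


def u_ms(u: Sequence[float]) -> float:
    """Mean-square insulin infusion rate."""
    u = np.asarray(u, float)
    if u.size == 0:
        raise ValueError("empty input series")
    return float(np.mean(u**2))


def _times(G, t):
    G = np.asarray(G, float)
    t = np.arange(G.size, dtype=float) if t is None else np.asarray(t, float)
    if t.size != G.size:
        raise ValueError("time and glucose series lengths differ")
    return G, t


def t_fall(G: Sequence[float], Gref: float = 80.0, t: Optional[Sequence[float]] = None) -> float:
    """First sample time at which G <= 1.1 * Gref."""
    G, t = _times(G, t)
    idx = np.nonzero(G <= 1.1 * Gref)[0]
    if idx.size == 0:
        raise MetricUndefinedError(f"BG never falls to {1.1 * Gref:g} mg/dL")
    return float(t[idx[0]])


def t_set(G: Sequence[float], Gref: float = 80.0, t: Optional[Sequence[float]] = None,
          band: float = 0.05) -> float:
    """First time after which G remains within (1 +/- band) * Gref."""
    G, t = _times(G, t)
    inside = (G >= (1 - band) * Gref) & (G <= (1 + band) * Gref)
    if not inside[-1]:
        raise MetricUndefinedError("BG is outside the settling band at the end of the run")
    # last excursion outside the band decides the settling instant
    outside = np.nonzero(~inside)[0]
    return float(t[0] if outside.size == 0 else t[outside[-1] + 1])


def t_rec(G: Sequence[float], t_event: float, Gref: float = 80.0,
          t: Optional[Sequence[float]] = None, band: float = 0.05) -> float:
    """Settling time of the post-event window, measured from the event."""
    G, t = _times(G, t)
    mask = t >= t_event
    if not mask.any():
        raise MetricUndefinedError(f"no samples at or after t_event={t_event}")
    return t_set(G[mask], Gref, t[mask], band) - t_event


def overshoot(G: Sequence[float], t_event: float, Gref: float = 80.0,
              t: Optional[Sequence[float]] = None) -> float:
    """Max of (G - Gref) after the event; 0 when BG never exceeds Gref."""
    G, t = _times(G, t)
    mask = t > t_event
    if not mask.any():
        raise MetricUndefinedError(f"no samples after t_event={t_event}")
    return float(max(np.max(G[mask] - Gref), 0.0))


def u_peak(u: Sequence[float], t: Optional[Sequence[float]] = None,
           window: Optional[tuple] = None) -> float:
    """Peak |u| within the window (t_lo, t_hi); None bounds are open."""
    u = np.asarray(u, float)
    t = np.arange(u.size, dtype=float) if t is None else np.asarray(t, float)
    mask = np.ones(u.size, bool)
    if window is not None:
        lo, hi = window
        if lo is not None:
            mask &= t >= lo
        if hi is not None:
            mask &= t <= hi
    if not mask.any():
        raise MetricUndefinedError("empty peak window")
    return float(np.max(np.abs(u[mask])))


def objective_j(errors: Sequence[float], u: Sequence[float],
                t: Optional[Sequence[float]] = None,
                Tset: Optional[float] = None, duration: Optional[float] = None) -> float:
    """Tuning cost J = |T_set| + int(e^2 + u^2) dt (trapezoidal).

    When the run never settles, ``T_set`` is replaced by the run duration
    (maximal, finite penalty) so the cost stays monotone and comparable.
    """
    e = np.asarray(errors, float)
    u = np.asarray(u, float)
    if e.size != u.size:
        raise ValueError("error and input series lengths differ")
    t = np.arange(e.size, dtype=float) if t is None else np.asarray(t, float)
    if Tset is None:
        Tset = duration if duration is not None else float(t[-1]) if t.size else 0.0
    integral = float(np.trapezoid(e**2 + u**2, t)) if e.size > 1 else 0.0
    return abs(Tset) + integral


@dataclass(frozen=True)
class CPMReport:
    """One run's critical performance measures (None = not applicable)."""

    E_rms: float
    E_sa: float
    U_ms: float
    T_fall: Optional[float] = None
    T_set: Optional[float] = None
    T_rec: Optional[float] = None
    OS: Optional[float] = None
    U_p_start: Optional[float] = None
    U_p_dist: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def cpm_report(result, t_event: Optional[float] = None) -> CPMReport:
    """Compute the CPM set for one `SimResult`.

    Without an event the start-up metrics (T_fall, T_set, U_p_start) are
    reported; with ``t_event`` the recovery metrics (T_rec, OS, U_p_dist)
    are added.  Timing metrics that are undefined for the series are
    reported as None rather than raising.
    """
    G = result.G_true
    t = result.t
    u = result.u
    Gref = result.provenance.get("Gss", 80.0)
    err = result.error()

    def _try(f, *a, **kw):
        try:
            return f(*a, **kw)
        except MetricUndefinedError:
            return None

    tfall = _try(t_fall, G, Gref, t)
    tset = _try(t_set, G, Gref, t)
    up_start = _try(u_peak, u, t, (None, tset if tset is not None else None))
    rep = dict(
        E_rms=e_rms(err), E_sa=e_sa(err), U_ms=u_ms(u),
        T_fall=tfall, T_set=tset, U_p_start=up_start,
    )
    if t_event is not None:
        rep["T_rec"] = _try(t_rec, G, t_event, Gref, t)
        rep["OS"] = _try(overshoot, G, t_event, Gref, t)
        rep["U_p_dist"] = _try(u_peak, u, t, (t_event, None))
    return CPMReport(**rep)


def confidence_interval(samples: Sequence[float], level: float = 0.95):
    """Normal-approximation CI: mean +/- z * sd / sqrt(N).

    Returns (mean, half_width, lo, hi).  At the 95% level z = 1.96.
    """
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("confidence interval needs at least 2 samples")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = float(scipy.stats.norm.ppf((1 + level) / 2))
    mean = float(np.mean(x))
    half = z * float(np.std(x, ddof=1)) / np.sqrt(x.size)
    return mean, half, mean - half, mean + half


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    t_critical: float  # exact two-tailed critical value at the Welch df
    t_critical_normal: float  # large-sample 1.96-style critical value
    alpha: float
    reject: bool

    def __post_init__(self) -> None:
        # internal consistency: reject <=> |t| > t_crit <=> p < alpha
        assert self.reject == (abs(self.t_stat) > self.t_critical) == (self.p_value < self.alpha)


def welch_t_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Two-sample two-tailed Welch t-test (unequal variances).

    Reports both the exact critical value at the Welch degrees of freedom
    and the large-sample normal critical value (1.96 at alpha = 0.05).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"significance level must be in (0, 1), got {alpha}")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    df = float(res.df)
    tcrit = float(scipy.stats.t.ppf(1 - alpha / 2, df))
    zcrit = float(scipy.stats.norm.ppf(1 - alpha / 2))
    p = float(res.pvalue)
    return TTestResult(
        t_stat=float(res.statistic), df=df, p_value=p, t_critical=tcrit,
        t_critical_normal=zcrit, alpha=alpha, reject=bool(p < alpha),
    )


def render_cpm_table(rows: dict[str, CPMReport], title: str = "") -> str:
    """Aligned-text table of CPM reports keyed by label."""
    metrics = ["E_rms", "E_sa", "T_fall", "T_set", "T_rec", "OS", "U_ms", "U_p_start", "U_p_dist"]
    units = dict(E_rms="mg/dL", E_sa="mg/dL", T_fall="min", T_set="min", T_rec="min",
                 OS="mg/dL", U_ms="(mU/min)^2", U_p_start="mU/min", U_p_dist="mU/min")
    used = [m for m in metrics if any(getattr(r, m) is not None for r in rows.values())]
    labels = list(rows)
    w = max(12, *(len(l) for l in labels)) + 2
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Metric':<12}{'Unit':<12}" + "".join(f"{l:>{w}}" for l in labels))
    for m in used:
        vals = []
        for l in labels:
            v = getattr(rows[l], m)
            vals.append("-" if v is None else f"{v:.2f}")
        lines.append(f"{m:<12}{units[m]:<12}" + "".join(f"{v:>{w}}" for v in vals))
    return "\n".join(lines)
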