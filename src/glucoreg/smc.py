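"""Integral-type sliding-mode layer driven by the LQIR input.

The hybrid law adds a switching term to the nominal LQIR command,

    u = u_lq + m * u_s,

acting on the sliding variable

    s(t) = G x(t) + z(t),        dz/dt = -G (A x + B u_lq + H Gss),
                                 z(0) = -G x(0),

where ``G = [g1 g2 g3 g4]`` is a positive weighting row.  By construction
``s(0) = 0``, so the loop starts on the surface and has no reaching phase.
On the surface the residual dynamics reduce to

    ds/dt = (G B) m u_s + (G F) d,

and with ``m = g1/g3`` the two channel gains coincide, ``G B m = G F =
g1/V1``, so the switching input ``u_s = -beta * sgn(s)`` (or the smoothed
``-beta * tanh(s)``) rejects any disturbance bounded by ``|d| < beta``.

The adaptive variant (LQ-ASMC) modulates the fixed gain ``Mo = m*beta``
with a hyperbolic-secant window of the glucose error ``e = Gss - G``:

    M(e) = Mo * (1 - sech(gamma * e)),

which is zero at zero error (quiet pump near the setpoint, hence little
chattering) and approaches ``Mo`` for large excursions.

Published tuning: g = (0.0088, 0.0051, 0.0052, 3.65e-4), beta = 4.48,
gamma = 0.06 and m = 1.59 -- note the published m differs from g1/g3 =
1.692; `strict=True` recomputes m from the surface weights and warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .patient_model import LinearModel
from .lqir import GainVector, lqir_control

__all__ = [
    "SlidingConfig",
    "SurfaceState",
    "init_surface",
    "surface_rate",
    "surface_step",
    "reaching_law",
    "adaptive_gain",
    "hybrid_control",
    "stability_condition",
    "reduced_surface_rate",
    "published_sliding_config",
]

#: admissible range for the switching gain beta (mU/min)
BETA_RANGE = (4.0, 10.0)


@dataclass(frozen=True)
class SlidingConfig:
    """Surface weights and switching-law parameters.

    ``mode`` selects the hard (``sgn``) or smoothed (``tanh``) limiter for
    the non-adaptive law; the adaptive law always uses ``tanh``.
    ``d_max`` is the assumed disturbance bound (mU/min-equivalent) against
    which `stability_condition` checks ``beta``.
    """

    g1: float = 0.0088
    g2: float = 0.0051
    g3: float = 0.0052
    g4: float = 3.65e-4
    m: float = 1.59
    beta: float = 4.48
    Mo: float = field(default=None)  # type: ignore[assignment]
    gamma: float = 0.06
    mode: str = "tanh"
    adaptive: bool = True
    d_max: float = 4.0

    def __post_init__(self) -> None:
        for key in ("g1", "g2", "g3", "g4"):
            if getattr(self, key) <= 0:
                raise ValueError(f"surface weight {key} must be > 0")
        if self.beta <= 0:
            raise ValueError("switching gain beta must be > 0")
        if self.gamma <= 0:
            raise ValueError("HSF variation rate gamma must be > 0")
        if self.mode not in ("sgn", "tanh"):
            raise ValueError(f"mode must be 'sgn' or 'tanh', got {self.mode!r}")
        if self.Mo is None:
            object.__setattr__(self, "Mo", self.m * self.beta)
        elif abs(self.Mo - self.m * self.beta) > 1e-12 * max(1.0, abs(self.Mo)):
            raise ValueError(f"Mo={self.Mo} inconsistent with m*beta={self.m * self.beta}")
        lo, hi = BETA_RANGE
        if not lo <= self.beta <= hi:
            warnings.warn(
                f"switching gain beta={self.beta} outside the admissible range "
                f"[{lo}, {hi}] mU/min",
                stacklevel=2,
            )

    @property
    def G(self) -> np.ndarray:
        return np.array([self.g1, self.g2, self.g3, self.g4])

    def strict(self) -> "SlidingConfig":
        """Recompute m = g1/g3 (warns if it differs from the stored m)."""
        m = self.g1 / self.g3
        if abs(m - self.m) > 1e-9:
            warnings.warn(
                f"stored m={self.m} differs from g1/g3={m:.6g}; using the ratio",
                stacklevel=2,
            )
        return replace(self, m=m, Mo=None)

    def to_dict(self) -> dict:
        return dict(
            g1=self.g1, g2=self.g2, g3=self.g3, g4=self.g4, m=self.m,
            beta=self.beta, Mo=self.Mo, gamma=self.gamma, mode=self.mode,
            adaptive=self.adaptive,
        )


def published_sliding_config(adaptive: bool = True, mode: str = "tanh") -> SlidingConfig:
    """The tuned sliding configuration of the published design."""
    return SlidingConfig(adaptive=adaptive, mode=mode)


@dataclass
class SurfaceState:
    """Integrator state of the sliding surface."""

    z: float
    s: float
    zdot: Optional[float] = None  # last rate, for trapezoidal stepping


def _zdot(cfg: SlidingConfig, x: np.ndarray, u_lq: float, model: LinearModel) -> float:
    return float(-cfg.G @ (model.A @ x + model.B * u_lq + model.affine()))


def surface_rate(cfg: SlidingConfig, x, u_lq: float, model: LinearModel) -> float:
    """dz/dt = -G (A x + B u_lq + H Gss)."""
    return _zdot(cfg, np.asarray(x, float), u_lq, model)


def init_surface(
    cfg: SlidingConfig,
    x0,
    u_lq0: Optional[float] = None,
    model: Optional[LinearModel] = None,
) -> SurfaceState:
    """Initialize z = -G x0 so that s = G x0 + z = 0 exactly."""
    x0 = np.asarray(x0, float)
    z = float(-cfg.G @ x0)
    zdot = None
    if u_lq0 is not None and model is not None:
        zdot = _zdot(cfg, x0, u_lq0, model)
    return SurfaceState(z=z, s=0.0, zdot=zdot)


def surface_step(
    state: SurfaceState,
    x,
    u_lq: float,
    model: LinearModel,
    dt: float,
    cfg: SlidingConfig,
    rule: str = "trapezoid",
) -> SurfaceState:
    """Advance z by one controller step and re-evaluate s = G x + z.

    Trapezoidal quadrature of dz/dt between the previous and current
    sample (falls back to a rectangle when no previous rate is stored).
    ``rule='euler'`` uses the previous rate only (first order; exposed for
    the quadrature-order tests).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    x = np.asarray(x, float)
    zdot_new = _zdot(cfg, x, u_lq, model)
    zdot_old = state.zdot if state.zdot is not None else zdot_new
    if rule == "trapezoid":
        z = state.z + dt * (zdot_old + zdot_new) / 2.0
    elif rule == "euler":
        z = state.z + dt * zdot_old
    else:
        raise ValueError(f"rule must be 'trapezoid' or 'euler', got {rule!r}")
    return SurfaceState(z=z, s=float(cfg.G @ x + z), zdot=zdot_new)


def reaching_law(s: float, beta: float, mode: str = "tanh") -> float:
    """Switching input u_s = -beta*sgn(s) or -beta*tanh(s); sgn(0) = 0."""
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if mode == "sgn":
        return float(-beta * np.sign(s))
    if mode == "tanh":
        return float(-beta * np.tanh(s))
    raise ValueError(f"mode must be 'sgn' or 'tanh', got {mode!r}")


def adaptive_gain(Mo: float, gamma: float, err: float) -> float:
    """Hyperbolic-secant gain window M = Mo*(1 - sech(gamma*err)).

    Even in ``err``, zero at zero error, strictly increasing in |err| and
    bounded in [0, Mo).
    """
    if Mo <= 0:
        raise ValueError(f"Mo must be > 0, got {Mo}")
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    # sech(x) = 2 e^{-|x|} / (1 + e^{-2|x|}), overflow-free for large |x|
    ax = abs(gamma * err)
    sech = 2.0 * np.exp(-ax) / (1.0 + np.exp(-2.0 * ax))
    return float(Mo * (1.0 - sech))


def hybrid_control(
    K: GainVector,
    x,
    surface: SurfaceState,
    cfg: SlidingConfig,
    err: Optional[float] = None,
) -> float:
    """Combined (unsaturated) control command.

    Non-adaptive (LQ-SMC):  u = u_lq - Mo * limiter(s)  with the limiter
    chosen by ``cfg.mode``.  Adaptive (LQ-ASMC):
    u = u_lq - M(err) * tanh(s), requiring the glucose error ``err``.
    """
    u_lq = lqir_control(K, x)
    if cfg.adaptive:
        if err is None:
            raise ValueError("adaptive law needs the glucose error err = Gss - G")
        M = adaptive_gain(cfg.Mo, cfg.gamma, err)
        return u_lq - M * float(np.tanh(surface.s))
    if cfg.mode == "sgn":
        return u_lq - cfg.Mo * float(np.sign(surface.s))
    return u_lq - cfg.Mo * float(np.tanh(surface.s))


def stability_condition(cfg: SlidingConfig, d_max: Optional[float] = None) -> bool:
    """Reachability condition beta > d_max (strict).

    Warns (again) when beta falls outside the admissible [4, 10] mU/min
    range; the condition itself only compares against the disturbance
    bound.
    """
    if d_max is None:
        d_max = cfg.d_max
    if d_max < 0:
        raise ValueError(f"disturbance bound must be >= 0, got {d_max}")
    lo, hi = BETA_RANGE
    if not lo <= cfg.beta <= hi:
        warnings.warn(
            f"switching gain beta={cfg.beta} outside the admissible range [{lo}, {hi}]",
            stacklevel=2,
        )
    return cfg.beta > d_max


def reduced_surface_rate(
    cfg: SlidingConfig, model: LinearModel, s: float, d: float, mode: str = "sgn"
) -> float:
    """Sliding dynamics on the surface: ds/dt = (G B) m u_s + (G F) d."""
    u_s = reaching_law(s, cfg.beta, mode)
    GB = float(cfg.G @ model.B)
    GF = float(cfg.G @ model.F)
    return GB * cfg.m * u_s + GF * d
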