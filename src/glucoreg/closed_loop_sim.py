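"""Sampled-data closed-loop glucose-regulation simulator.

The plant (nonlinear BMM) is integrated continuously with an adaptive
high-order ODE method; the controller runs at a fixed 60-s period.  At
each sample the glucose sensor reading is formed (true G plus Gaussian
noise, plus the drift/bias fault when enabled), the controller-side error
integral, sliding surface and adaptive gain are updated from the measured
error, and the insulin command is computed, clamped to [u_min, u_max] and
held (zero-order hold) until the next sample.

Information set: X and I are fed back as true plant states (the control
laws assume full state feedback); only the glucose channel is corrupted
by noise, and the controller's error integral accumulates the *measured*
error.  There is no anti-windup on the integral -- the early phase, where
the pump saturates at zero, relies on the integral winding up to build
the insulin drive.

Scenarios:

A  `scenario_hyperglycemia` -- 500 min, sensor noise, no events; the loop
   must bring BG from 200 mg/dL down to the 80 mg/dL setpoint.
B  `scenario_meal`          -- 1000 min; an 80 mg/dL meal impulse at
   t = 500 min (realized as an instantaneous jump of the glucose state;
   a one-sample rectangular pulse through the Gm/V1 channel is available
   as an alternative realization).
C  `scenario_stress`        -- 1000 min; at t = 500 min the plant's
   kinetic rates switch to p1 = 8.0e-3, p2 = 25.0e-3, p3 = 2.5e-6 min^-1
   (stress hormones: reduced glucose effectiveness and insulin
   sensitivity, faster insulin-action clearance).
   `scenario_sensor_fault`  -- 500 min; the measurement is corrupted by
   a 5 mg/dL bias plus a 2 mg/dL sinusoidal drift, 5 + 2*sin(0.2 t).

Identical seeds give bit-identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .patient_model import PatientParams, LinearModel, linearize, plant_derivatives
from .lqir import GainVector, published_gains, lqir_control
from .smc import (
    SlidingConfig,
    published_sliding_config,
    init_surface,
    surface_step,
    adaptive_gain,
    hybrid_control,
    stability_condition,
)

__all__ = [
    "ScenarioConfig",
    "SimResult",
    "CONTROLLERS",
    "scenario_hyperglycemia",
    "scenario_meal",
    "scenario_stress",
    "scenario_sensor_fault",
    "sensor_fault_signal",
    "run_closed_loop",
]

log = logging.getLogger(__name__)

CONTROLLERS = ("lqir", "lq-smc", "lq-asmc")

#: controller sampling period, minutes (samples every 60 s)
DT_SAMPLE = 1.0

#: printed stress-condition kinetic rates, min^-1
STRESS_RATES = (8.0e-3, 25.0e-3, 2.5e-6)


@dataclass(frozen=True)
class MealEvent:
    time: float = 500.0
    amplitude: float = 80.0  # mg/dL
    realization: str = "jump"  # 'jump' (state impulse) or 'pulse' (Gm channel)


@dataclass(frozen=True)
class StressEvent:
    time: float = 500.0
    p1: float = STRESS_RATES[0]
    p2: float = STRESS_RATES[1]
    p3: float = STRESS_RATES[2]


@dataclass(frozen=True)
class SensorFault:
    bias: float = 5.0  # mg/dL
    amplitude: float = 2.0  # mg/dL
    rate: float = 0.2  # sinusoid angular rate, per minute of simulation time


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    duration: float  # min
    dt_sample: float = DT_SAMPLE
    noise_variance: float = 0.2  # (mg/dL)^2; 0 disables noise
    meal: Optional[MealEvent] = None
    stress: Optional[StressEvent] = None
    sensor_fault: Optional[SensorFault] = None
    u_min: float = 0.0
    u_max: float = 100.0  # mU/min

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be > 0")
        if self.u_min >= self.u_max:
            raise ValueError(f"need u_min < u_max, got [{self.u_min}, {self.u_max}]")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")

    @property
    def n_samples(self) -> int:
        """Number of controller steps N (arrays hold N + 1 samples)."""
        return int(round(self.duration / self.dt_sample))

    def to_dict(self) -> dict:
        return asdict(self)


def scenario_hyperglycemia(duration: float = 500.0, noise: bool = True) -> ScenarioConfig:
    """Scenario A: initial hyperglycemia (200 mg/dL) down to the setpoint."""
    return ScenarioConfig(
        name="hyperglycemia",
        duration=duration,
        noise_variance=0.2 if noise else 0.0,
    )


def scenario_meal(
    duration: float = 1000.0, time: float = 500.0, amplitude: float = 80.0,
    realization: str = "jump", noise: bool = True,
) -> ScenarioConfig:
    """Scenario B: transient meal disturbance at t = 500 min."""
    return ScenarioConfig(
        name="meal",
        duration=duration,
        noise_variance=0.2 if noise else 0.0,
        meal=MealEvent(time=time, amplitude=amplitude, realization=realization),
    )


def scenario_stress(duration: float = 1000.0, time: float = 500.0, noise: bool = True) -> ScenarioConfig:
    """Scenario C: stress-induced parameter change at t = 500 min."""
    return ScenarioConfig(
        name="stress",
        duration=duration,
        noise_variance=0.2 if noise else 0.0,
        stress=StressEvent(time=time),
    )


def scenario_sensor_fault(duration: float = 500.0, noise: bool = True) -> ScenarioConfig:
    """Sensor drift-and-bias robustness test: measurement + 5 + 2 sin(0.2 t)."""
    return ScenarioConfig(
        name="sensor_fault",
        duration=duration,
        noise_variance=0.2 if noise else 0.0,
        sensor_fault=SensorFault(),
    )


def sensor_fault_signal(t, fault: SensorFault = SensorFault()):
    """Additive measurement corruption bias + amp*sin(rate*t), t in minutes."""
    return fault.bias + fault.amplitude * np.sin(fault.rate * np.asarray(t, float))


@dataclass
class SimResult:
    """Sampled closed-loop trajectories (one entry per 60-s sample)."""

    t: np.ndarray
    G_true: np.ndarray
    G_meas: np.ndarray
    X: np.ndarray
    I: np.ndarray
    eps: np.ndarray  # controller-side error integral (from measured error)
    s: np.ndarray
    M: np.ndarray  # switching gain actually applied (0 for pure LQIR)
    u: np.ndarray  # applied (saturated) insulin rate
    nonphysical: bool
    saturation_fraction: float
    provenance: dict = field(default_factory=dict)

    def error(self, measured: bool = False) -> np.ndarray:
        """Glucose error e = Gss - G at the samples."""
        Gss = self.provenance.get("Gss", 80.0)
        return Gss - (self.G_meas if measured else self.G_true)

    def to_csv(self, path: str | Path) -> Path:
        """Write trajectories as CSV plus a JSON provenance sidecar."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(
            dict(t_min=self.t, G_true=self.G_true, G_meas=self.G_meas, X=self.X,
                 I=self.I, eps=self.eps, s=self.s, M=self.M, u=self.u)
        )
        df.to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            dict(provenance=self.provenance, nonphysical=self.nonphysical,
                 saturation_fraction=self.saturation_fraction), indent=2))
        return sidecar


def _integrate_segment(x, t0, t1, u, Gm, params, form, insulin, rtol, atol):
    sol = solve_ivp(
        lambda t, y: plant_derivatives(y, u, Gm, params, form=form, insulin=insulin),
        (t0, t1), x, method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"plant integration failed on [{t0}, {t1}]: {sol.message}; last state {sol.y[:, -1]}"
        )
    xe = sol.y[:, -1]
    if not np.all(np.isfinite(xe)):
        raise RuntimeError(f"non-finite plant state at t={t1}: {xe}")
    return xe


def run_closed_loop(
    patient: PatientParams,
    controller: Optional[str],
    scenario: ScenarioConfig,
    seed: int = 0,
    gains: Optional[GainVector] = None,
    sliding: Optional[SlidingConfig] = None,
    model: Optional[LinearModel] = None,
    plant_form: str = "deviation",
    insulin: str = "basal",
    affine: str = "setpoint",
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> SimResult:
    """Run one sampled-data closed loop and return the sampled trajectories.

    ``controller`` is one of ``'lqir'``, ``'lq-smc'``, ``'lq-asmc'`` or
    ``None`` (open loop, zero insulin).  ``gains`` defaults to the
    published tuned gain vector and ``sliding`` to the published sliding
    configuration (its ``adaptive`` flag is overridden to match the
    controller).  The sliding surface's internal model defaults to the
    patient's linearization with the chosen affine convention.
    """
    if controller is not None and controller not in CONTROLLERS:
        raise ValueError(f"unknown controller {controller!r}; choose from {CONTROLLERS} or None")
    if gains is None:
        gains = published_gains()
    uses_smc = controller in ("lq-smc", "lq-asmc")
    if uses_smc:
        if sliding is None:
            sliding = published_sliding_config()
        sliding = SlidingConfig(**{**sliding.to_dict(), "adaptive": controller == "lq-asmc"})
        if not stability_condition(sliding):
            raise ValueError(
                f"reachability condition violated: beta={sliding.beta} <= d_max={sliding.d_max}"
            )
    if model is None:
        model = linearize(patient, affine=affine, insulin=insulin)

    rng = np.random.default_rng(seed)
    cfg = scenario
    N = cfg.n_samples
    dt = cfg.dt_sample
    sigma = float(np.sqrt(cfg.noise_variance))

    x = patient.initial_state()
    pars = patient
    eps_c = patient.eps0
    e_prev = None
    surf = None

    t_arr = np.arange(N + 1) * dt
    out = {k: np.empty(N + 1) for k in ("G_true", "G_meas", "X", "I", "eps", "s", "M", "u")}
    nonphysical = False
    n_saturated = 0
    Gm_pulse = 0.0

    for k in range(N + 1):
        t = t_arr[k]
        # events fire exactly at their nominal time (sample-aligned)
        if cfg.stress is not None and np.isclose(t, cfg.stress.time):
            pars = pars.with_rates(cfg.stress.p1, cfg.stress.p2, cfg.stress.p3)
            log.info("stress event at t=%.0f min: rates -> (%g, %g, %g)",
                     t, pars.p1, pars.p2, pars.p3)
        Gm_pulse = 0.0
        if cfg.meal is not None and np.isclose(t, cfg.meal.time):
            if cfg.meal.realization == "jump":
                x = x.copy()
                x[0] += cfg.meal.amplitude
            else:  # rectangular pulse of one sample width through Gm/V1
                Gm_pulse = cfg.meal.amplitude
            log.info("meal event at t=%.0f min (%s, %g mg/dL)",
                     t, cfg.meal.realization, cfg.meal.amplitude)

        G_meas = x[0] + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        if cfg.sensor_fault is not None:
            G_meas += float(sensor_fault_signal(t, cfg.sensor_fault))
        err = patient.Gss - G_meas

        # controller-side error integral (trapezoid over the measured error)
        if e_prev is not None:
            eps_c += dt * (e_prev + err) / 2.0
        e_prev = err

        xc = np.array([G_meas, x[1], x[2], eps_c])
        u_cmd = 0.0
        M_applied = 0.0
        s_val = 0.0
        if controller == "lqir":
            u_cmd = lqir_control(gains, xc)
        elif uses_smc:
            u_lq = lqir_control(gains, xc)
            if surf is None:
                surf = init_surface(sliding, xc, u_lq0=u_lq, model=model)
            else:
                surf = surface_step(surf, xc, u_lq, model, dt, sliding)
            s_val = surf.s
            u_cmd = hybrid_control(gains, xc, surf, sliding, err=err)
            M_applied = (
                adaptive_gain(sliding.Mo, sliding.gamma, err)
                if sliding.adaptive
                else sliding.Mo
            )
        u_applied = float(np.clip(u_cmd, cfg.u_min, cfg.u_max))
        if u_cmd < cfg.u_min or u_cmd > cfg.u_max:
            n_saturated += 1

        out["G_true"][k] = x[0]
        out["G_meas"][k] = G_meas
        out["X"][k] = x[1]
        out["I"][k] = x[2]
        out["eps"][k] = eps_c
        out["s"][k] = s_val
        out["M"][k] = M_applied
        out["u"][k] = u_applied

        if x[0] < 0 or x[2] < -pars.Ib:
            nonphysical = True

        if k < N:
            x = _integrate_segment(
                x, t, t + dt, u_applied, Gm_pulse, pars, plant_form, insulin, rtol, atol
            )

    if nonphysical:
        log.warning("nonphysical state reached (G < 0 or I < -Ib)")

    prov = dict(
        patient=patient.name,
        patient_params=patient.to_dict(),
        controller=controller,
        scenario=cfg.to_dict(),
        gains=gains.to_dict(),
        sliding=sliding.to_dict() if uses_smc else None,
        plant_form=plant_form,
        insulin=insulin,
        affine=affine,
        seed=int(seed),
        Gss=patient.Gss,
        software="glucoreg 0.1.0",
    )
    return SimResult(
        t=t_arr,
        nonphysical=nonphysical,
        saturation_fraction=n_saturated / (N + 1),
        provenance=prov,
        **out,
    )
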