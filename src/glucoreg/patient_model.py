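"""Bergman-minimal-model (BMM) virtual patients.

The BMM describes short-term glucose--insulin kinetics with three states:
plasma glucose ``G`` (mg/dL), remote-compartment insulin action ``X``
(min^-1) and plasma insulin ``I`` (mU/L).  For integral-action control a
fourth state ``eps`` accumulates the glucose error,
``d(eps)/dt = Gss - G``.  Exogenous insulin is infused at rate ``v``
(mU/min) into a distribution volume ``V1`` (L); meals enter as a glucose
appearance input ``Gm``.

Two readings of the glucose balance are supported (``form``):

``deviation`` (default)
    ``dG/dt = -(p1 + X) * (G - Gss) + Gm/V1``.  Glucose relaxes toward the
    basal level ``Gss``; insulin action accelerates the relaxation.  This
    is the only reading for which ``Gss`` is an equilibrium of the
    uncontrolled glucose subsystem, i.e. for which "steady-state BG"
    means what it says.

``literal``
    ``dG/dt = -p1*G - X*(G - Gss) + Gm/V1``, the equation exactly as it is
    usually typeset.  It has no equilibrium at ``Gss`` and the closed loop
    settles at a nonphysical negative glucose level; it is retained for
    comparison only.

Likewise two readings of the plasma-insulin balance (``insulin``):

``basal`` (default)
    ``dI/dt = -n * (I - Ib) + v/V1`` -- insulin decays toward the basal
    concentration ``Ib``, the standard minimal-model convention.

``printed``
    ``dI/dt = -n * (I + Ib) + v/V1`` -- insulin decays toward ``-Ib``.
    Under this reading plasma insulin goes negative whenever the pump
    runs below ``n*Ib*V1`` and, for insulin-sensitive patients
    (large ``p3/p2``), the deviation-form closed loop is unstable.

The linearized state-space model ``dx/dt = A x + B u + F d + H*Gss`` uses
state order ``(G, X, I, eps)`` with the insulin-action column evaluated at
the basal glucose level ``Gb = Gss`` (the bilinear term ``X*G`` linearized
at ``G = Gb``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "PatientParams",
    "PlantState",
    "LinearModel",
    "PATIENT_IDS",
    "preset_patient",
    "plant_derivatives",
    "linearize",
]

#: order of the state vector everywhere in this package
STATE_NAMES = ("G", "X", "I", "eps")

PATIENT_IDS = ("healthy", "patient1", "patient2", "patient3")


@dataclass(frozen=True)
class PatientParams:
    """One virtual patient: BMM rate constants, volumes and initial state.

    Units: ``p1, p2, n`` in min^-1; ``p3`` in min^-2 per (mU/L); ``Ib`` in
    mU/L; ``Gss`` in mg/dL; ``V1`` in L.  ``G0, X0, I0, eps0`` are the
    initial state in (mg/dL, min^-1, mU/L, mg*min/dL).
    """

    p1: float
    p2: float
    p3: float
    n: float
    Ib: float
    Gss: float
    V1: float
    G0: float = 200.0
    X0: float = 0.0
    I0: float = 50.0
    eps0: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for key in ("p1", "p2", "p3", "n"):
            if getattr(self, key) <= 0:
                raise ValueError(f"rate constant {key} must be > 0, got {getattr(self, key)}")
        if self.V1 <= 0:
            raise ValueError(f"blood volume V1 must be > 0, got {self.V1}")
        if self.Gss <= 0:
            raise ValueError(f"setpoint Gss must be > 0, got {self.Gss}")
        if self.Ib < 0:
            raise ValueError(f"basal insulin Ib must be >= 0, got {self.Ib}")

    # -- config serialization (flat key/value block, Table-symbol keys) ----
    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("name")
        return d

    @classmethod
    def from_dict(cls, d: dict, name: str = "custom") -> "PatientParams":
        return cls(name=name, **{k: float(v) for k, v in d.items() if k != "name"})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, name: str = "custom") -> "PatientParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()), name=name)

    def initial_state(self) -> np.ndarray:
        return np.array([self.G0, self.X0, self.I0, self.eps0], dtype=float)

    def with_rates(self, p1: float, p2: float, p3: float) -> "PatientParams":
        """Copy with replaced kinetic rates (used by the stress scenario)."""
        return replace(self, p1=p1, p2=p2, p3=p3)


@dataclass
class PlantState:
    """Plant state (G, X, I, eps); ``G >= 0`` is *not* enforced."""

    G: float
    X: float
    I: float
    eps: float

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.X, self.I, self.eps], dtype=float)

    @classmethod
    def from_array(cls, x: Iterable[float]) -> "PlantState":
        G, X, I, eps = np.asarray(x, dtype=float)
        return cls(G, X, I, eps)


# Table of printed presets: one healthy individual and three T1D patients.
_PRESETS: dict[str, dict] = {
    "healthy": dict(p1=0.0317, p2=12.3e-3, p3=4.92e-6, n=0.2659),
    "patient1": dict(p1=0.012, p2=20e-3, p3=5.3e-6, n=0.3),
    "patient2": dict(p1=0.011, p2=7.2e-3, p3=2.16e-6, n=0.2465),
    "patient3": dict(p1=0.015, p2=14.2e-3, p3=99.4e-6, n=0.2814),
}
_SHARED = dict(Ib=7.0, Gss=80.0, V1=12.0, G0=200.0, X0=0.0, I0=50.0, eps0=0.0)


def preset_patient(patient_id: str) -> PatientParams:
    """Return the printed parameter column for one of the four presets.

    Raises ``KeyError`` (naming the valid ids) for anything else.
    """
    if patient_id not in _PRESETS:
        raise KeyError(
            f"unknown patient id {patient_id!r}; valid ids: {', '.join(PATIENT_IDS)}"
        )
    return PatientParams(name=patient_id, **_PRESETS[patient_id], **_SHARED)


def plant_derivatives(
    state,
    v: float,
    Gm: float,
    params: PatientParams,
    form: str = "deviation",
    insulin: str = "basal",
) -> np.ndarray:
    """Time derivatives (dG, dX, dI, deps) of the BMM plant.

    ``state`` is a (G, X, I, eps) array or :class:`PlantState`; ``v`` is the
    insulin infusion rate (mU/min, must be finite and >= 0); ``Gm`` the meal
    input.  ``form`` selects the glucose-balance reading, ``insulin`` the
    plasma-insulin reading (see module docstring).
    """
    if isinstance(state, PlantState):
        state = state.as_array()
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite plant state: {x}")
    if v < 0:
        raise ValueError(f"insulin infusion rate must be >= 0, got {v}")
    G, X, I, _ = x
    p = params
    if form == "deviation":
        dG = -(p.p1 + X) * (G - p.Gss) + Gm / p.V1
    elif form == "literal":
        dG = -p.p1 * G - X * (G - p.Gss) + Gm / p.V1
    else:
        raise ValueError(f"form must be 'deviation' or 'literal', got {form!r}")
    dX = -p.p2 * X + p.p3 * I
    if insulin == "basal":
        dI = -p.n * (I - p.Ib) + v / p.V1
    elif insulin == "printed":
        dI = -p.n * (I + p.Ib) + v / p.V1
    else:
        raise ValueError(f"insulin must be 'basal' or 'printed', got {insulin!r}")
    deps = p.Gss - G
    return np.array([dG, dX, dI, deps])


@dataclass(frozen=True)
class LinearModel:
    """State-space matrices of ``dx/dt = A x + B u + F d + H*Gss``.

    ``A`` is 4x4; ``B`` (control), ``F`` (disturbance) and ``H`` (affine
    setpoint term) are 4-vectors; ``C = [1 0 0 0]`` picks glucose as the
    output and ``D = 0``.
    """

    A: np.ndarray
    B: np.ndarray
    F: np.ndarray
    H: np.ndarray
    C: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    D: float = 0.0
    Gss: float = 80.0

    def affine(self) -> np.ndarray:
        """The constant drift H*Gss of the model."""
        return self.H * self.Gss

    def controllability_rank(self) -> int:
        n = self.A.shape[0]
        cols = [self.B]
        for _ in range(n - 1):
            cols.append(self.A @ cols[-1])
        return int(np.linalg.matrix_rank(np.column_stack(cols)))


def linearize(
    params: PatientParams,
    affine: str = "setpoint",
    insulin: str = "basal",
) -> LinearModel:
    """Linear state-space model of one patient.

    ``A`` uses the fixed layout (state order G, X, I, eps)::

        row G:   (-p1, -Gb,  0,  0)     Gb = Gss; insulin action lowers G
        row X:   (  0, -p2, p3,  0)
        row I:   (  0,   0, -n,  0)
        row eps: ( -1,   0,  0,  0)

    ``B = (0, 0, 1/V1, 0)`` and ``F = (1/V1, 0, 0, 0)``.

    ``affine`` selects the constant drift vector ``H``:

    ``setpoint`` (default)
        ``H = (p1, 0, n*Ib/Gss, 1)`` so that ``H*Gss`` reproduces the
        plant's own balance at the setpoint: the glucose row reads
        ``-p1*(G - Gss) - Gb*X`` and the insulin row carries the basal
        replenishment ``n*Ib``.  With this choice the model's drift
        vanishes at the regulated equilibrium, which is what the
        sliding-surface construction assumes.

    ``printed``
        ``H = (1, 0, 0, 1)`` exactly as typeset.  The resulting drift
        ``(Gss, 0, 0, Gss)`` exceeds the plant's glucose balance by
        roughly ``(1 - p1)*Gss`` ~ 79 mg/dL/min, which makes the sliding
        variable ramp without bound (see the sliding-mode module notes).

    ``insulin`` must match the plant reading so the affine insulin term is
    consistent (``printed`` flips the sign of the basal term).
    """
    p = params
    Gb = p.Gss
    A = np.array(
        [
            [-p.p1, -Gb, 0.0, 0.0],
            [0.0, -p.p2, p.p3, 0.0],
            [0.0, 0.0, -p.n, 0.0],
            [-1.0, 0.0, 0.0, 0.0],
        ]
    )
    B = np.array([0.0, 0.0, 1.0 / p.V1, 0.0])
    F = np.array([1.0 / p.V1, 0.0, 0.0, 0.0])
    if affine == "setpoint":
        ib_term = p.n * p.Ib if insulin == "basal" else -p.n * p.Ib
        H = np.array([p.p1, 0.0, ib_term / p.Gss, 1.0])
    elif affine == "printed":
        H = np.array([1.0, 0.0, 0.0, 1.0])
    else:
        raise ValueError(f"affine must be 'setpoint' or 'printed', got {affine!r}")
    return LinearModel(A=A, B=B, F=F, H=H, Gss=p.Gss)
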