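"""Linear-Quadratic-Integral Regulator (LQIR) synthesis.

The baseline controller minimizes the quadratic performance index

    S = 1/2 * int( x' Q x + u' R u ) dt,   Q = diag(qG, qX, qI, qeps) >= 0,
                                           R = rho > 0,

over the four-state linearized glucose model (the error integral ``eps``
is the fourth state, hence the "I" in LQIR).  The solution is the
stabilizing root P of the continuous algebraic Riccati equation

    A'P + P A - P B R^-1 B' P + Q = 0,

and the state-feedback gain K = R^-1 B' P, applied as u_lq = -K x.

Synthesis is offline: K is computed once per (patient, weights) and the
controller only evaluates the dot product at run time.

`published_weights` / `published_gains` expose the tuned parameter set
reported for this control scheme.  Note that the published gain vector is
*not* the Riccati gain of the published model and weights (re-deriving it
gives a vector orders of magnitude larger); the published numbers are kept
verbatim because they, not the re-derived gains, produce insulin-infusion
profiles on the reported scale, and the closed-loop study treats them as
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .patient_model import LinearModel

__all__ = [
    "LQWeights",
    "RiccatiSolution",
    "GainVector",
    "care",
    "solve_care",
    "lqir_gain",
    "lqir_control",
    "verify_lyapunov",
    "published_weights",
    "published_gains",
]


@dataclass(frozen=True)
class LQWeights:
    """State penalties (>= 0) and control penalty (> 0)."""

    qG: float
    qX: float
    qI: float
    qeps: float
    rho: float

    def __post_init__(self) -> None:
        for key in ("qG", "qX", "qI", "qeps"):
            if getattr(self, key) < 0:
                raise ValueError(f"state penalty {key} must be >= 0")
        if self.rho <= 0:
            raise ValueError(f"control penalty rho must be > 0, got {self.rho}")

    @property
    def Q(self) -> np.ndarray:
        return np.diag([self.qG, self.qX, self.qI, self.qeps])

    @property
    def R(self) -> float:
        return self.rho

    def to_dict(self) -> dict:
        return dict(qG=self.qG, qX=self.qX, qI=self.qI, qeps=self.qeps, rho=self.rho)

    def scaled(self, c: float) -> "LQWeights":
        return LQWeights(c * self.qG, c * self.qX, c * self.qI, c * self.qeps, c * self.rho)


@dataclass(frozen=True)
class RiccatiSolution:
    P: np.ndarray
    residual: float  # relative Frobenius residual of the ARE


@dataclass(frozen=True)
class GainVector:
    kG: float
    kX: float
    kI: float
    keps: float

    def as_array(self) -> np.ndarray:
        return np.array([self.kG, self.kX, self.kI, self.keps])

    def to_dict(self) -> dict:
        return dict(kG=self.kG, kX=self.kX, kI=self.kI, keps=self.keps)


def care(A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray):
    """Stabilizing solution of A'P + PA - P B R^-1 B' P + Q = 0.

    Works for any dimensions (the scalar case reduces to a quadratic with
    closed-form root, used as an oracle in the tests).  Returns (P, rel_res).
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.asarray(B, float).reshape(A.shape[0], -1)
    Q = np.atleast_2d(np.asarray(Q, float))
    R = np.atleast_2d(np.asarray(R, float))
    try:
        P = scipy.linalg.solve_continuous_are(A, B, Q, R)
    except Exception as exc:  # non-stabilizable pair, indefinite weights, ...
        raise ValueError(f"Riccati solve failed: {exc}") from exc
    res = A.T @ P + P @ A - P @ B @ np.linalg.solve(R, B.T @ P) + Q
    scale = max(np.linalg.norm(Q, "fro"), np.linalg.norm(P, "fro"), 1.0)
    return P, float(np.linalg.norm(res, "fro") / scale)


def solve_care(model: LinearModel, w: LQWeights, tol: float = 1e-8) -> RiccatiSolution:
    """Solve the ARE for one patient model; validates the solution."""
    P, rel = care(model.A, model.B, w.Q, np.array([[w.rho]]))
    if rel > tol:
        raise ValueError(f"ARE residual {rel:.2e} exceeds tolerance {tol:.0e}")
    P = (P + P.T) / 2
    eigs = np.linalg.eigvalsh(P)
    if np.any(eigs < -tol * max(1.0, eigs.max())):
        raise ValueError(f"Riccati solution not positive semidefinite: eigs {eigs}")
    return RiccatiSolution(P=P, residual=rel)


def lqir_gain(P: RiccatiSolution | np.ndarray, model: LinearModel, w: LQWeights) -> GainVector:
    """K = rho^-1 * B' * P."""
    Pm = P.P if isinstance(P, RiccatiSolution) else np.asarray(P, float)
    K = (model.B @ Pm) / w.rho
    return GainVector(*K)


def lqir_control(K: GainVector, x) -> float:
    """Nominal LQIR law u_lq = -K x (unsaturated; may be negative)."""
    return float(-K.as_array() @ np.asarray(x, float))


@dataclass(frozen=True)
class LyapunovReport:
    ok: bool
    P_positive_definite: bool
    Wdot_negative_semidefinite: bool
    closed_loop_hurwitz: bool
    closed_loop_eigs: np.ndarray


def verify_lyapunov(
    model: LinearModel, w: LQWeights, P: RiccatiSolution | np.ndarray, K: GainVector
) -> LyapunovReport:
    """Check the quadratic Lyapunov certificate of the LQIR design.

    With W = x'Px the closed loop satisfies
    dW/dt = -x'Qx - x'(P B rho^-1 B' P)x, so the design is certified when
    P > 0, the matrix -Q - P B rho^-1 B' P is negative semidefinite and
    A - B K is Hurwitz.
    """
    if w.rho <= 0:
        raise ValueError("control penalty rho must be > 0")
    Pm = P.P if isinstance(P, RiccatiSolution) else np.asarray(P, float)
    pd = bool(np.all(np.linalg.eigvalsh((Pm + Pm.T) / 2) > 0))
    M = -w.Q - np.outer(Pm @ model.B, model.B @ Pm) / w.rho
    nsd = bool(np.all(np.linalg.eigvalsh((M + M.T) / 2) <= 1e-10))
    Acl = model.A - np.outer(model.B, K.as_array())
    eigs = np.linalg.eigvals(Acl)
    hurwitz = bool(np.all(eigs.real < 0))
    return LyapunovReport(
        ok=pd and nsd and hurwitz,
        P_positive_definite=pd,
        Wdot_negative_semidefinite=nsd,
        closed_loop_hurwitz=hurwitz,
        closed_loop_eigs=eigs,
    )


def published_weights() -> LQWeights:
    """Tuned QPI weights of the published design (state order G, X, I, eps)."""
    return LQWeights(qG=0.32, qX=0.25, qI=0.22, qeps=0.61, rho=1.05)


def published_gains() -> GainVector:
    """Published tuned feedback gains, used as inputs by the closed-loop study."""
    return GainVector(kG=0.0038, kX=0.0021, kI=0.0024, keps=1.12e-4)
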