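"""Generative model of the four-region prefrontal-amygdala DCM.

Neural dynamics are bilinear: ``dz/dt = (A~ + u_pos B_pos + u_neg B_neg) z
+ C u`` over the regions (FFA, LPFC, sgACC, AMY).  Off-diagonal entries
of ``A`` are coupling rates in Hz; diagonal entries are unitless
log-scaling parameters of a fixed -0.5 Hz self-decay, so the effective
self-connection ``-0.5 exp(A_ii)`` is always inhibitory.  The driving
input (all face trials, mean-centered) enters the FFA only; positive and
negative valence act as unit-boxcar modulators of the interregional
connections.

Each region's neural state drives a balloon-Windkessel hemodynamic
cascade (vasodilatory signal s, inflow f, venous volume nu,
deoxyhemoglobin q) observed through the static BOLD equation
``y = V0 (k1 (1-q) + k2 (1 - q/nu) + k3 (1 - nu))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels

REGIONS = ("FFA", "LPFC", "sgACC", "AMY")
INPUTS = ("faces", "positive", "negative")

#: fixed self-decay scaled by exp(A_ii), in Hz
SELF_DECAY = -0.5

#: sessions are expressed in percent signal change
PERCENT = 100.0

_FACE_CONDITIONS = ("positive", "negative", "neutral")


@dataclass
class DCMSpec:
    """A/B/C parameterisation of the four-region bilinear model."""

    A: np.ndarray
    B_pos: np.ndarray
    B_neg: np.ndarray
    C: np.ndarray = None
    c_faces: float = None  # convenience: driving weight onto FFA

    def __post_init__(self):
        self.A = np.asarray(self.A, float).reshape(4, 4)
        self.B_pos = np.asarray(self.B_pos, float).reshape(4, 4)
        self.B_neg = np.asarray(self.B_neg, float).reshape(4, 4)
        if self.C is None:
            C = np.zeros((4, 3))
            C[0, 0] = 0.15 if self.c_faces is None else self.c_faces
            self.C = C
        else:
            self.C = np.asarray(self.C, float).reshape(4, 3)
        if np.any(np.diag(self.B_pos) != 0) or np.any(np.diag(self.B_neg) != 0):
            raise ValueError("modulatory B matrices must have zero diagonals")
        mask = np.ones((4, 3), bool)
        mask[0, 0] = False
        if np.any(self.C[mask] != 0):
            raise ValueError("C may be nonzero only for the FFA driving input")

    @property
    def A_effective(self) -> np.ndarray:
        """A with the diagonal replaced by -0.5 exp(A_ii) Hz."""
        Ae = self.A.copy()
        np.fill_diagonal(Ae, SELF_DECAY * np.exp(np.diag(self.A)))
        return Ae

    @classmethod
    def zeros(cls) -> "DCMSpec":
        return cls(A=np.zeros((4, 4)), B_pos=np.zeros((4, 4)),
                   B_neg=np.zeros((4, 4)), c_faces=0.0)


@dataclass
class HemoParams:
    """Balloon-Windkessel constants (standard neurovascular values)."""

    kappa: float = 0.64      # signal decay, 1/s
    gamma_h: float = 0.32    # flow feedback, 1/s
    tau: float | np.ndarray = 2.0  # venous transit time, s (per region)
    alpha: float = 0.32      # Grubb exponent
    E0: float = 0.4          # resting oxygen extraction
    V0: float = 0.04         # resting venous volume fraction

    def __post_init__(self):
        self.tau = np.broadcast_to(np.asarray(self.tau, float), (4,)).copy()
        for name in ("kappa", "gamma_h", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")

    @property
    def k(self) -> tuple:
        """Observation constants (k1, k2, k3) = (7 E0, 4 E0, E0)."""
        return 7.0 * self.E0, 4.0 * self.E0, self.E0


@dataclass
class BoldSession:
    """Region-by-volume BOLD matrix with acquisition metadata."""

    data: np.ndarray            # (4, n_volumes)
    tr: float = 1.6
    inputs: np.ndarray = None   # (nt_micro, 3)
    micro_dt: float = None
    seed: int = None
    noise_sd: float = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# drift functions (reference implementations; the integrator is compiled)
# ---------------------------------------------------------------------------

def neural_drift(z, u, spec: DCMSpec) -> np.ndarray:
    """dz/dt of the bilinear neural model, in Hz."""
    z = np.asarray(z, float)
    u = np.asarray(u, float)
    J = spec.A_effective + u[1] * spec.B_pos + u[2] * spec.B_neg
    return J @ z + spec.C @ u


def hemo_drift(h, z, p: HemoParams) -> np.ndarray:
    """Balloon-Windkessel state derivatives for one region.

    ``h = (s, f, nu, q)`` with f, nu, q > 0.  The resting point
    (0, 1, 1, 1) with z = 0 is a fixed point.
    """
    s, f, nu, q = h
    if f <= 0 or nu <= 0 or q <= 0:
        raise ValueError("hemodynamic states f, nu, q must stay positive")
    tau = float(np.atleast_1d(p.tau)[0])
    fv = nu ** (1.0 / p.alpha)
    ff = (1.0 - (1.0 - p.E0) ** (1.0 / f)) / p.E0
    return np.array([
        z - p.kappa * s - p.gamma_h * (f - 1.0),
        s,
        (f - fv) / tau,
        (f * ff - fv * q / nu) / tau,
    ])


def bold_observe(nu, q, p: HemoParams):
    """Static BOLD observation; zero at rest (nu = q = 1)."""
    if np.any(np.asarray(nu) <= 0) or np.any(np.asarray(q) <= 0):
        raise ValueError("nu and q must be positive")
    k1, k2, k3 = p.k
    return p.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / nu) + k3 * (1.0 - nu))


# ---------------------------------------------------------------------------
# task inputs
# ---------------------------------------------------------------------------

def build_task_inputs(events: pd.DataFrame, micro_dt: float,
                      total_time: float) -> np.ndarray:
    """Micro-time input matrix (nt, 3) from a trial-event table.

    ``events`` needs columns ``onset``, ``duration`` and ``condition``
    (or ``trial_type``).  Channel 0 is the union boxcar over all face
    trials, mean-centered over the session; channels 1 and 2 are unit
    boxcars over positive and negative trials (not centered).  Shape
    trials drive no channel.
    """
    cond_col = "condition" if "condition" in events.columns else "trial_type"
    nt = int(round(total_time / micro_dt))
    U = np.zeros((nt, 3))
    overlap = False
    for _, ev in events.iterrows():
        i0 = int(np.floor(ev["onset"] / micro_dt))
        i1 = int(np.ceil((ev["onset"] + ev["duration"]) / micro_dt))
        i0, i1 = max(i0, 0), min(i1, nt)
        cond = ev[cond_col]
        if cond in _FACE_CONDITIONS:
            if np.any(U[i0:i1, 0] > 0):
                overlap = True
            U[i0:i1, 0] = 1.0
        if cond == "positive":
            U[i0:i1, 1] = 1.0
        elif cond == "negative":
            U[i0:i1, 2] = 1.0
    if overlap:
        warnings.warn("overlapping face events merged into a single boxcar")
    U[:, 0] -= U[:, 0].mean()
    return U


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

class IntegrationError(RuntimeError):
    pass


def simulate_session(spec: DCMSpec, hemo: HemoParams, events: pd.DataFrame,
                     tr: float = 1.6, n_volumes: int = 335,
                     noise_sd: float = 0.0, seed: int = 0,
                     oversample: int = 16) -> BoldSession:
    """Simulate one BOLD session from the bilinear DCM.

    Integrates the neural and hemodynamic ODEs with fixed-step RK4 at
    ``tr / oversample`` micro-time resolution, reads out BOLD at the end
    of every volume, and adds white Gaussian noise with SD ``noise_sd``.
    Session data (and ``noise_sd``) are in percent signal change.
    Deterministic given ``seed``.
    """
    dt = tr / oversample
    total = n_volumes * tr
    U = build_task_inputs(events, dt, total)
    y = integrate_bold(spec, hemo, U, dt, oversample, n_volumes) * PERCENT
    if not np.all(np.isfinite(y)):
        raise IntegrationError(
            f"DCM integration diverged (|state| > 1e6) for spec with "
            f"max |A| = {np.abs(spec.A).max():.3f}")
    rng = np.random.default_rng(seed)
    data = y.T + (noise_sd * rng.standard_normal(y.T.shape) if noise_sd > 0
                  else 0.0)
    return BoldSession(data=np.asarray(data), tr=tr, inputs=U, micro_dt=dt,
                       seed=seed, noise_sd=noise_sd)


def integrate_bold(spec: DCMSpec, hemo: HemoParams, U: np.ndarray,
                   dt: float, oversample: int, n_volumes: int) -> np.ndarray:
    """Noise-free BOLD (n_volumes, 4) for a given micro-time input."""
    k1, k2, k3 = hemo.k
    return _kernels.integrate_session(
        spec.A_effective, spec.B_pos, spec.B_neg, spec.C,
        np.ascontiguousarray(U, dtype=float), dt, oversample, n_volumes,
        hemo.kappa, hemo.gamma_h, np.asarray(hemo.tau, float),
        hemo.alpha, hemo.E0, hemo.V0, k1, k2, k3)


def integrate_neural_trajectory(spec: DCMSpec, U: np.ndarray,
                                dt: float) -> np.ndarray:
    """Neural states at every micro-step (for linear-regime validation)."""
    return _kernels.integrate_neural(
        spec.A_effective, spec.B_pos, spec.B_neg, spec.C,
        np.ascontiguousarray(U, dtype=float), dt)
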