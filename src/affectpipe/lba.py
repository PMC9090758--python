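"""Linear ballistic accumulator (LBA) core.

The LBA models a two-choice decision as a race between two independent,
linearly accumulating evidence totals.  On each trial accumulator ``i``
starts at a point drawn uniformly from ``[0, A]`` and accumulates at a
rate drawn from a normal distribution ``N(v_i, sv_i)``; a response is
issued when the first accumulator reaches the threshold ``b = A + B``,
after a non-decision offset ``t0``.

Accumulators are coded by accuracy (match vs. mismatch), not by response
side: the matching accumulator has mean drift ``v_true[c]`` for condition
``c`` and between-trial drift SD ``sv_true``, while the mismatching
accumulator has mean ``v_false[c]`` and its SD fixed at 1 to identify the
model.  Drifts are truncated to the positive half line and the densities
renormalised accordingly (the "posdrift" convention), so both accumulators
finish with probability one and the defective densities of the two
responses integrate to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import ndtr

CONDITIONS = ("positive", "negative", "neutral", "shapes")

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: floor applied to log-densities so MCMC arithmetic stays finite
LOGLIK_FLOOR = -1e10


def _phi(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _check_domain(**kwargs):
    for name, (val, ok) in kwargs.items():
        if not np.all(ok):
            raise ValueError(f"parameter {name!r} outside its domain (got {val})")


# ---------------------------------------------------------------------------
# single-accumulator first-passage distributions
# ---------------------------------------------------------------------------

def accumulator_cdf(t, A, b, v, sv):
    """P(first passage <= t) for one accumulator, positive-drift truncation.

    Start point ~ Uniform(0, A), drift ~ Normal(v, sv) truncated to
    (0, inf).  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    _check_domain(A=(A, A >= 0), b=(b, b > A), sv=(sv, sv > 0),
                  t=(t, t >= 0))
    return _acc_cdf_raw(t, A, b, v, sv)


def _acc_cdf_raw(t, A, b, v, sv):
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.shape(t))
    pos = t > 0
    ts = np.where(pos, t, 1.0)  # placeholder to avoid 0-division
    znorm = ndtr(v / sv)
    if A < 1e-9:
        # start point collapses to 0: T = b / drift
        F = ndtr((ts * v - b) / (ts * sv))
    else:
        z1 = (b - A - ts * v) / (ts * sv)
        z2 = (b - ts * v) / (ts * sv)
        F = (1.0
             + (b - A - ts * v) / A * ndtr(z1)
             - (b - ts * v) / A * ndtr(z2)
             + ts * sv / A * (_phi(z1) - _phi(z2)))
    out = np.where(pos, F / znorm, 0.0)
    return np.clip(out, 0.0, 1.0)


def accumulator_pdf(t, A, b, v, sv):
    """First-passage density (1/s) of one accumulator; 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    _check_domain(A=(A, A >= 0), b=(b, b > A), sv=(sv, sv > 0))
    return _acc_pdf_raw(t, A, b, v, sv)


def _acc_pdf_raw(t, A, b, v, sv):
    t = np.asarray(t, dtype=float)
    pos = t > 0
    ts = np.where(pos, t, 1.0)
    znorm = ndtr(v / sv)
    if A < 1e-9:
        zz = (b - ts * v) / (ts * sv)
        f = b / (ts * ts * sv) * _phi(zz)
    else:
        z1 = (b - A - ts * v) / (ts * sv)
        z2 = (b - ts * v) / (ts * sv)
        f = (-v * ndtr(z1) + sv * _phi(z1)
             + v * ndtr(z2) - sv * _phi(z2)) / A
    out = np.where(pos, f / znorm, 0.0)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# parameters and model variants
# ---------------------------------------------------------------------------

@dataclass
class LBAParams:
    """Subject-level LBA parameters.

    ``B`` and the drifts may be scalars (shared across conditions) or
    length-4 arrays ordered as :data:`CONDITIONS`.
    """

    A: float
    B: float | np.ndarray
    t0: float
    v_true: float | np.ndarray
    v_false: float | np.ndarray
    sv_true: float
    sv_false: float = 1.0

    def __post_init__(self):
        self.B = np.broadcast_to(np.asarray(self.B, float), (4,)).copy()
        self.v_true = np.broadcast_to(np.asarray(self.v_true, float), (4,)).copy()
        self.v_false = np.broadcast_to(np.asarray(self.v_false, float), (4,)).copy()
        _check_domain(A=(self.A, self.A >= 0),
                      B=(self.B, self.B > 0),
                      t0=(self.t0, self.t0 >= 0),
                      sv_true=(self.sv_true, self.sv_true > 0))
        if self.sv_false != 1.0:
            raise ValueError("sv_false is fixed at 1 for identifiability")

    @property
    def b(self) -> np.ndarray:
        """Response threshold b = A + B, per condition."""
        return self.A + self.B


@dataclass(frozen=True)
class ModelVariant:
    """Which LBA parameters vary with condition.

    ``M_v`` lets the drifts vary by condition (threshold shared), ``M_B``
    lets the threshold excursion vary (drifts shared) and ``M_null`` holds
    both constant.
    """

    name: str
    v_by_condition: bool
    b_by_condition: bool
    param_names: tuple = field(default=())

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def model_variant(name: str) -> ModelVariant:
    """Return the descriptor for variant ``name`` in {M_v, M_B, M_null}."""
    if name == "M_v":
        drift = [f"v_true.{c}" for c in CONDITIONS] + \
                [f"v_false.{c}" for c in CONDITIONS]
        rest = ["A", "B", "t0", "sv_true"]
        return ModelVariant(name, True, False, tuple(drift + rest))
    if name == "M_B":
        names = ["v_true", "v_false"] + [f"B.{c}" for c in CONDITIONS] + \
                ["A", "t0", "sv_true"]
        return ModelVariant(name, False, True, tuple(names))
    if name == "M_null":
        return ModelVariant(name, False, False,
                            ("v_true", "v_false", "A", "B", "t0", "sv_true"))
    raise ValueError(f"unknown model variant {name!r}; expected M_v, M_B or M_null")


# Sampling-scale transform: drifts are sampled on their natural scale,
# all strictly-positive parameters (A, B, t0, sv_true) on the log scale.

def _log_scaled(variant: ModelVariant) -> np.ndarray:
    return np.array([not n.startswith("v_") for n in variant.param_names])


def to_sampling_scale(theta_nat: np.ndarray, variant: ModelVariant) -> np.ndarray:
    theta = np.array(theta_nat, dtype=float, copy=True)
    mask = _log_scaled(variant)
    theta[..., mask] = np.log(theta[..., mask])
    return theta


def from_sampling_scale(psi: np.ndarray, variant: ModelVariant) -> np.ndarray:
    theta = np.array(psi, dtype=float, copy=True)
    mask = _log_scaled(variant)
    theta[..., mask] = np.exp(np.clip(theta[..., mask], -700.0, 700.0))
    return theta


def params_from_vector(theta_nat: np.ndarray, variant: ModelVariant) -> LBAParams:
    """Build :class:`LBAParams` from a natural-scale flat vector."""
    d = dict(zip(variant.param_names, np.asarray(theta_nat, float)))
    if variant.v_by_condition:
        v_true = np.array([d[f"v_true.{c}"] for c in CONDITIONS])
        v_false = np.array([d[f"v_false.{c}"] for c in CONDITIONS])
    else:
        v_true, v_false = d["v_true"], d["v_false"]
    if variant.b_by_condition:
        B = np.array([d[f"B.{c}"] for c in CONDITIONS])
    else:
        B = d["B"]
    return LBAParams(A=d["A"], B=B, t0=d["t0"], v_true=v_true,
                     v_false=v_false, sv_true=d["sv_true"])


def vector_from_params(params: LBAParams, variant: ModelVariant) -> np.ndarray:
    out = []
    for name in variant.param_names:
        if "." in name:
            base, cond = name.split(".")
            out.append(getattr(params, base)[CONDITIONS.index(cond)])
        else:
            val = getattr(params, name)
            out.append(float(np.atleast_1d(val)[0]))
    return np.array(out)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _defective_logpdf(dt, A, b, t0_unused, v_win, sv_win, v_lose, sv_lose):
    """log f_win(dt) + log(1 - F_lose(dt)) elementwise, dt = rt - t0."""
    f = _acc_pdf_raw(dt, A, b, v_win, sv_win)
    S = 1.0 - _acc_cdf_raw(dt, A, b, v_lose, sv_lose)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(f * S, 0.0))


def trial_loglik(response: str, rt: float, condition: str,
                 params: LBAParams) -> float:
    """Log defective density of one (response, RT) observation.

    ``response`` is coded by accuracy: ``"correct"`` means the matching
    accumulator won.  Omission trials are rejected (they are excluded from
    the likelihood upstream).  RTs at or below ``t0`` receive the floor
    :data:`LOGLIK_FLOOR`.
    """
    if response not in ("correct", "error"):
        raise ValueError(f"response must be 'correct' or 'error', got {response!r}")
    ci = CONDITIONS.index(condition)
    correct = np.array([response == "correct"])
    ll = loglik_trials(np.array([rt]), np.array([ci]), correct, params)
    return float(ll[0])


def loglik_trials(rt: np.ndarray, cond_idx: np.ndarray, correct: np.ndarray,
                  params: LBAParams) -> np.ndarray:
    """Vectorised per-trial log-likelihood for one subject."""
    dt = rt - params.t0
    b = params.b[cond_idx]
    vt = np.asarray(params.v_true)[cond_idx]
    vf = np.asarray(params.v_false)[cond_idx]
    v_win = np.where(correct, vt, vf)
    sv_win = np.where(correct, params.sv_true, params.sv_false)
    v_lose = np.where(correct, vf, vt)
    sv_lose = np.where(correct, params.sv_false, params.sv_true)
    ll = np.full(rt.shape, LOGLIK_FLOOR)
    ok = dt > 0
    if np.any(ok):
        vals = _defective_logpdf(dt[ok], params.A, b[ok], None,
                                 v_win[ok], sv_win[ok], v_lose[ok], sv_lose[ok])
        ll[ok] = np.maximum(vals, LOGLIK_FLOOR)
    return ll


def loglik_batch(theta_nat: np.ndarray, variant: ModelVariant,
                 rt: np.ndarray, cond_idx: np.ndarray,
                 correct: np.ndarray, pointwise: bool = False) -> np.ndarray:
    """Log-likelihood of one subject's trials for a batch of parameter vectors.

    ``theta_nat``: (m, p) natural-scale vectors.  Returns (m,) summed
    log-likelihoods, or (m, n_trials) if ``pointwise``.  Vectorised over
    both axes; invalid vectors (non-positive A+eps, B, t0, sv) get the floor.
    """
    theta = np.atleast_2d(np.asarray(theta_nat, float))
    m, p = theta.shape
    lay = _variant_layout(variant)
    from . import _lba_kernels
    out_pw = (np.empty((m, len(rt))) if pointwise
              else np.empty((1, 1)))
    sums = _lba_kernels.batch_loglik(
        np.ascontiguousarray(theta[:, lay["A"]]),
        np.ascontiguousarray(theta[:, lay["B"]]),
        np.ascontiguousarray(theta[:, lay["t0"]]),
        np.ascontiguousarray(theta[:, lay["sv_true"]]),
        np.ascontiguousarray(theta[:, lay["v_true"]]),
        np.ascontiguousarray(theta[:, lay["v_false"]]),
        np.ascontiguousarray(rt, dtype=float),
        np.ascontiguousarray(cond_idx, dtype=np.int64),
        np.ascontiguousarray(correct, dtype=np.bool_),
        bool(pointwise), out_pw)
    if pointwise:
        return out_pw
    return sums


def loglik_batch_subjects(theta_nat: np.ndarray, variant: ModelVariant,
                          rt_all: np.ndarray, cond_all: np.ndarray,
                          correct_all: np.ndarray,
                          offsets: np.ndarray) -> np.ndarray:
    """Cohort-wide log-likelihood in one compiled pass.

    ``theta_nat``: (m, n_subjects, p) natural-scale vectors; subject
    ``s`` owns trials ``offsets[s]:offsets[s+1]`` of the concatenated
    trial arrays.  Returns (m, n_subjects) summed log-likelihoods.
    """
    theta = np.asarray(theta_nat, float)
    m, n_subj, p = theta.shape
    flat = np.ascontiguousarray(theta.reshape(m * n_subj, p))
    lay = _variant_layout(variant)
    from . import _lba_kernels
    out = _lba_kernels.batch_loglik_stacked(
        np.ascontiguousarray(flat[:, lay["A"]]),
        np.ascontiguousarray(flat[:, lay["B"]]),
        np.ascontiguousarray(flat[:, lay["t0"]]),
        np.ascontiguousarray(flat[:, lay["sv_true"]]),
        np.ascontiguousarray(flat[:, lay["v_true"]]),
        np.ascontiguousarray(flat[:, lay["v_false"]]),
        np.ascontiguousarray(rt_all, dtype=float),
        np.ascontiguousarray(cond_all, dtype=np.int64),
        np.ascontiguousarray(correct_all, dtype=np.bool_),
        np.ascontiguousarray(offsets, dtype=np.int64), n_subj)
    return out.reshape(m, n_subj)


_LAYOUT_CACHE: dict = {}


def _variant_layout(variant: ModelVariant) -> dict:
    """Column indices mapping a flat vector to the kernel's arguments."""
    if variant.name in _LAYOUT_CACHE:
        return _LAYOUT_CACHE[variant.name]
    names = list(variant.param_names)

    def cols(base):
        if f"{base}.positive" in names:
            return np.array([names.index(f"{base}.{c}") for c in CONDITIONS])
        return np.array([names.index(base)] * 4)

    lay = {"A": names.index("A"), "t0": names.index("t0"),
           "sv_true": names.index("sv_true"),
           "B": cols("B"), "v_true": cols("v_true"),
           "v_false": cols("v_false")}
    _LAYOUT_CACHE[variant.name] = lay
    return lay


def _batch_pdf(t, A, b, v, sv):
    z1 = (b - A - t * v) / (t * sv)
    z2 = (b - t * v) / (t * sv)
    f = (-v * ndtr(z1) + sv * _phi(z1) + v * ndtr(z2) - sv * _phi(z2)) / A
    return np.maximum(f / ndtr(v / sv), 0.0)


def _batch_cdf(t, A, b, v, sv):
    z1 = (b - A - t * v) / (t * sv)
    z2 = (b - t * v) / (t * sv)
    F = (1.0 + (b - A - t * v) / A * ndtr(z1)
         - (b - t * v) / A * ndtr(z2)
         + t * sv / A * (_phi(z1) - _phi(z2)))
    return np.clip(F / ndtr(v / sv), 0.0, 1.0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _trunc_normal_pos(rng, mean, sd, size):
    """Draws from N(mean, sd) truncated to (0, inf) by inverse CDF."""
    lo = ndtr(-np.asarray(mean) / sd)  # P(Z <= -mean/sd)
    u = rng.uniform(size=size)
    from scipy.special import ndtri
    return mean + sd * ndtri(lo + u * (1.0 - lo))


def simulate_trials(params: LBAParams, design: pd.DataFrame, rng_seed: int,
                    response_window: float = 5.0) -> pd.DataFrame:
    """Simulate one subject's session given a trial design.

    ``design`` needs columns ``condition`` and ``onset`` (s); optional
    ``block`` and ``correct_side`` in {left, right}.  Returns a trial
    table with columns condition, block, onset, response, rt, correct.
    RTs beyond ``response_window`` are censored as omissions.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(design)
    cond_idx = np.array([CONDITIONS.index(c) for c in design["condition"]])
    b = params.b[cond_idx]
    vt = np.asarray(params.v_true)[cond_idx]
    vf = np.asarray(params.v_false)[cond_idx]

    start_t = rng.uniform(0.0, max(params.A, 1e-300), size=n) if params.A > 0 \
        else np.zeros(n)
    start_f = rng.uniform(0.0, max(params.A, 1e-300), size=n) if params.A > 0 \
        else np.zeros(n)
    drift_t = _trunc_normal_pos(rng, vt, params.sv_true, n)
    drift_f = _trunc_normal_pos(rng, vf, params.sv_false, n)
    tt = (b - start_t) / drift_t
    tf = (b - start_f) / drift_f
    correct = tt < tf
    rt = params.t0 + np.minimum(tt, tf)
    omit = rt > response_window

    if "correct_side" in design.columns:
        side = design["correct_side"].to_numpy()
    else:
        side = rng.choice(["left", "right"], size=n)
    other = np.where(side == "left", "right", "left")
    response = np.where(correct, side, other)
    response = np.where(omit, "omission", response)

    out = pd.DataFrame({
        "condition": design["condition"].to_numpy(),
        "block": design["block"].to_numpy() if "block" in design.columns
                 else np.zeros(n, int),
        "onset": design["onset"].to_numpy(),
        "response": response,
        "rt": np.where(omit, np.nan, rt),
        "correct": np.where(omit, False, correct),
    })
    return out


def defective_prob_correct(params: LBAParams, condition: str,
                           t_max: float = 60.0, n_grid: int = 20000) -> float:
    """P(correct response) by numerical integration of the defective density."""
    ci = CONDITIONS.index(condition)
    t = np.linspace(1e-6, t_max, n_grid)
    b = params.b[ci]
    f = _acc_pdf_raw(t, params.A, b, np.asarray(params.v_true)[ci], params.sv_true)
    S = 1.0 - _acc_cdf_raw(t, params.A, b, np.asarray(params.v_false)[ci],
                           params.sv_false)
    return float(np.trapezoid(f * S, t))
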