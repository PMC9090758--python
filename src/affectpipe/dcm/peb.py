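"""Parametric empirical Bayes over subject-level DCM posteriors.

The second level places a GLM over the subjects' connectivity
parameters: ``theta_i = (x_i^T kron I) beta + eps_i`` with random
effects ``eps_i ~ N(0, exp(-lambda) V)`` and each subject contributing
the Gaussian likelihood implied by their first-level posterior (their
posterior with the first-level prior divided out).  ``beta`` is
integrated out analytically; the random-effects log-precision is
optimised by maximising the resulting free energy.

Bayesian model reduction (BMR) evaluates any model that differs from
the full one only in its prior (here: second-level effects switched
off) analytically from the full posterior.  A greedy search discards
effects that do not contribute to the evidence, the surviving
neighbourhood is enumerated, and parameters are Bayesian-model-averaged
over the best 256 nested models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

#: prior variance of an effect that is "switched off" in a reduced model
OFF_VAR = 1e-8


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(table: pd.DataFrame,
                        covariates=("group", "SSRI", "sex", "age", "handedness"),
                        group_labels=("control", "MDD")) -> tuple[np.ndarray, list]:
    """Second-level design matrix: intercept, then mean-centered covariates.

    ``group`` is coded 0/1 by ``group_labels`` order before centering;
    other string columns are factor-coded 0/1 by sorted level.
    """
    cols = [np.ones(len(table))]
    names = ["common"]
    for cov in covariates:
        v = table[cov]
        if cov == "group":
            x = (v == group_labels[1]).astype(float).to_numpy()
        elif v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov!r} has more than two levels")
            x = (v == levels[-1]).astype(float).to_numpy()
        else:
            x = v.to_numpy(float)
        if np.ptp(x) == 0:
            log.warning("covariate %r is constant; dropped from the design",
                        cov)
            continue
        cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")
    return X, names


# ---------------------------------------------------------------------------
# implied subject-level observations
# ---------------------------------------------------------------------------

def implied_observation(post, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood over a parameter subset implied by a subject posterior.

    Dividing the first-level posterior ``N(m, S)`` by its prior
    ``N(m0, S0)`` gives a Gaussian likelihood with precision
    ``S^-1 - S0^-1``; returns its mean and covariance (jittered to PD
    when the posterior did not contract the prior in some direction).
    """
    m = post.mean[idx]
    S = post.cov[np.ix_(idx, idx)]
    m0 = post.prior_mean[idx]
    S0 = post.prior_cov[np.ix_(idx, idx)]
    Pi = np.linalg.inv(S)
    Pi0 = np.linalg.inv(S0)
    P = Pi - Pi0
    w = np.linalg.eigvalsh(0.5 * (P + P.T))
    if w.min() <= 0:
        P = P + (abs(w.min()) + 1e-6) * np.eye(len(idx))
    Q = np.linalg.inv(0.5 * (P + P.T))
    h = Q @ (Pi @ m - Pi0 @ m0)
    return h, Q


# ---------------------------------------------------------------------------
# PEB fit
# ---------------------------------------------------------------------------

@dataclass
class PEBResult:
    """Posterior over second-level effects, with optional BMA summary.

    ``beta_mean`` has length ``n_covariates * n_params`` laid out
    covariate-major: element ``j * n_params + k`` is the effect of
    design column ``j`` on parameter ``k``.
    """

    beta_mean: np.ndarray
    beta_cov: np.ndarray
    prior_mean: np.ndarray
    prior_cov: np.ndarray
    free_energy: float
    re_log_precision: float
    param_names: tuple
    covariate_names: tuple
    X: np.ndarray
    subject_obs: list                 # (h_i, Q_i) pairs
    re_cov: np.ndarray = None
    bma_mean: np.ndarray = None
    pp: np.ndarray = None
    searched_models: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def effect(self, covariate: str, which: str = "beta_mean") -> np.ndarray:
        j = self.covariate_names.index(covariate)
        p = self.n_params
        return getattr(self, which)[j * p:(j + 1) * p]

    def effect_pp(self, covariate: str) -> np.ndarray:
        return self.effect(covariate, "pp")


def _marginal_beta(X, obs, Sigma_re, beta_prior_var):
    """Integrate beta out of the linear-Gaussian second level.

    Returns (F_data, beta_mean, beta_cov) where F_data is the log
    evidence of the stacked subject observations (beta prior included).
    """
    n_sub = len(obs)
    p = obs[0][0].size
    c = X.shape[1]
    d = c * p
    Pb = np.diag(1.0 / beta_prior_var)
    Prec = Pb.copy()
    b = np.zeros(d)
    logdet_sum = 0.0
    quad_sum = 0.0
    n_tot = 0
    for i in range(n_sub):
        h, Q = obs[i]
        Qi = Q + Sigma_re
        Li = np.linalg.cholesky(0.5 * (Qi + Qi.T))
        Qinv = np.linalg.inv(Qi)
        Ai = np.kron(X[i], np.eye(p))          # (p, d)
        Prec += Ai.T @ Qinv @ Ai
        b += Ai.T @ (Qinv @ h)
        logdet_sum += 2 * np.sum(np.log(np.diag(Li)))
        quad_sum += h @ Qinv @ h
        n_tot += p
    Prec = 0.5 * (Prec + Prec.T)
    cov = np.linalg.inv(Prec)
    mean = cov @ b
    sign, logdet_prec = np.linalg.slogdet(Prec)
    F = (-0.5 * n_tot * np.log(2 * np.pi) - 0.5 * logdet_sum
         - 0.5 * quad_sum + 0.5 * b @ mean
         - 0.5 * np.sum(np.log(beta_prior_var)) - 0.5 * logdet_prec)
    return F, mean, cov


def peb_fit(posteriors, X, param_subset="A", covariate_names=None,
            beta_prior_scale: float = 1.0, re_scale: float = 16.0,
            re_lambda_prior=(0.0, 1.0)) -> PEBResult:
    """Empirical-Bayes GLM over subject posteriors.

    ``param_subset`` is a name prefix (``"A"``, ``"Bpos"``, ...), a list
    of names, or an index array selecting the first-level parameters to
    take to the second level.  Columns 2+ of ``X`` must be mean-centered.
    The random-effects covariance is ``exp(-lambda) * diag(prior)/re_scale``
    with the scalar ``lambda`` optimised under a N(0,1) prior.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != len(posteriors):
        raise ValueError("design matrix rows must match the subjects")
    if X.shape[1] > 1:
        centers = np.abs(X[:, 1:].mean(axis=0))
        if np.any(centers > 1e-8):
            raise ValueError("covariate columns of X must be mean-centered")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    ref = posteriors[0]
    if isinstance(param_subset, str):
        idx = ref.subset(param_subset)
        names = tuple(np.array(ref.param_names)[idx])
    elif all(isinstance(s, str) for s in param_subset):
        names = tuple(param_subset)
        idx = np.array([ref.param_names.index(n) for n in names])
    else:
        idx = np.asarray(param_subset, int)
        names = tuple(np.array(ref.param_names)[idx])
    p = len(idx)
    c = X.shape[1]
    if covariate_names is None:
        covariate_names = tuple(f"x{j}" for j in range(c))
    covariate_names = tuple(covariate_names)

    obs = [implied_observation(post, idx) for post in posteriors]
    prior_var_1st = np.diag(ref.prior_cov)[idx]
    beta_prior_var = np.tile(prior_var_1st * beta_prior_scale, c)
    V_re = np.diag(prior_var_1st) / re_scale
    lam_m, lam_v = re_lambda_prior

    def neg_F(lam):
        Sigma_re = np.exp(-lam) * V_re
        F, _, _ = _marginal_beta(X, obs, Sigma_re, beta_prior_var)
        return -(F - 0.5 * (lam - lam_m) ** 2 / lam_v)

    res = minimize_scalar(neg_F, bounds=(-5.0, 8.0), method="bounded",
                          options={"xatol": 1e-3})
    lam = float(res.x)
    Sigma_re = np.exp(-lam) * V_re
    F, mean, cov = _marginal_beta(X, obs, Sigma_re, beta_prior_var)
    F_total = F - 0.5 * (lam - lam_m) ** 2 / lam_v
    return PEBResult(beta_mean=mean, beta_cov=cov,
                     prior_mean=np.zeros(c * p),
                     prior_cov=np.diag(beta_prior_var),
                     free_energy=float(F_total), re_log_precision=lam,
                     param_names=names, covariate_names=covariate_names,
                     X=X, subject_obs=obs, re_cov=Sigma_re)


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def bayesian_model_reduction(post_mean, post_cov, prior_mean, prior_cov,
                             reduced_prior_mean, reduced_prior_cov):
    """Evidence change and posterior of a reduced model, analytically.

    For Gaussian prior/posterior and a reduced prior differing only in
    (shrunk or zeroed) entries, returns ``(dF, reduced_mean,
    reduced_cov)`` where ``dF = log evidence(reduced) - log
    evidence(full)``; no refit is required.
    """
    Pp = np.linalg.inv(post_cov)
    P0 = np.linalg.inv(prior_cov)
    Pr = np.linalg.inv(reduced_prior_cov)
    Prp = Pp + Pr - P0
    w = np.linalg.eigvalsh(0.5 * (Prp + Prp.T))
    if w.min() <= 0:
        jit = abs(w.min()) + 1e-10
        log.debug("BMR precision stabilised with jitter %.2e", jit)
        Prp = Prp + jit * np.eye(len(post_mean))
    bp = Pp @ post_mean
    b0 = P0 @ prior_mean
    br = Pr @ reduced_prior_mean
    brp = bp + br - b0
    red_cov = np.linalg.inv(0.5 * (Prp + Prp.T))
    red_mean = red_cov @ brp
    dF = 0.5 * (np.linalg.slogdet(Pp)[1] + np.linalg.slogdet(Pr)[1]
                - np.linalg.slogdet(P0)[1] - np.linalg.slogdet(Prp)[1]
                + brp @ red_mean
                - post_mean @ bp - reduced_prior_mean @ br + prior_mean @ b0)
    return float(dF), red_mean, red_cov


def _reduced_prior(peb: PEBResult, off: frozenset):
    var = np.diag(peb.prior_cov).copy()
    mean = peb.prior_mean.copy()
    for j in off:
        var[j] = OFF_VAR
        mean[j] = 0.0
    return mean, np.diag(var)


def greedy_prune_and_average(peb: PEBResult, pp_threshold: float = 0.95,
                             n_best: int = 256, max_enum: int = 2 ** 16,
                             borderline_dF: float = 3.0) -> PEBResult:
    """Greedy BMR search over second-level effects with BMA.

    Repeatedly switches off the single effect whose removal most
    improves (or least harms, while non-negative) the model evidence;
    stops when every single removal would decrease it.  All on/off
    combinations of the parameters touched during the search (capped at
    ``max_enum`` models) are then scored, the best ``n_best`` retained,
    and the posterior averaged over them weighted by posterior model
    probability.  An effect's posterior probability of being present is
    the summed weight of retained models that keep it on.
    """
    d = len(peb.beta_mean)

    def score(off: frozenset):
        rm, rc = _reduced_prior(peb, off)
        return bayesian_model_reduction(peb.beta_mean, peb.beta_cov,
                                        peb.prior_mean, peb.prior_cov, rm, rc)

    off = frozenset()
    F_cur = 0.0
    touched = set()
    while True:
        best_j, best_dF = None, 0.0
        for j in range(d):
            if j in off:
                continue
            dF, _, _ = score(off | {j})
            if dF - F_cur >= best_dF:
                best_j, best_dF = j, dF - F_cur
        if best_j is None:
            break
        off = off | {best_j}
        F_cur += best_dF
        touched.add(best_j)

    # near-prunable effects join the enumeration neighbourhood
    for j in range(d):
        if j not in off:
            dF, _, _ = score(off | {j})
            if dF - F_cur > -borderline_dF:
                touched.add(j)
    touched = sorted(touched)
    while 2 ** len(touched) > max_enum:
        touched = touched[:-1]

    models = []
    base = frozenset(off) - set(touched)
    for bits in itertools.product((0, 1), repeat=len(touched)):
        off_m = base | {j for j, b in zip(touched, bits) if b == 0}
        dF, rm, rc = score(frozenset(off_m))
        models.append((dF, frozenset(off_m), rm, rc))
    models.sort(key=lambda t: -t[0])
    models = models[:n_best]

    dFs = np.array([m[0] for m in models])
    w = np.exp(dFs - dFs.max())
    w /= w.sum()
    bma = np.zeros(d)
    pp = np.zeros(d)
    for wi, (dF, off_m, rm, _) in zip(w, models):
        bma += wi * rm
        on = np.ones(d)
        on[list(off_m)] = 0.0
        pp += wi * on
    out = PEBResult(**{**peb.__dict__})
    out.bma_mean = bma
    out.pp = pp
    out.searched_models = [(float(dF), tuple(sorted(off_m)), float(wi))
                           for wi, (dF, off_m, _, _) in zip(w, models)]
    return out
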