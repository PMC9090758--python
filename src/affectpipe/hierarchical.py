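"""Hierarchical Bayesian estimation of the LBA by DE-MCMC.

Subjects share a group-level population: each subject-level parameter
``k`` (on its sampling scale: drifts natural, positive parameters log)
is drawn from ``Normal(mu_k, sigma_k)``.  The joint posterior over
subject vectors and group parameters is sampled with a blocked
Gibbs-within-differential-evolution scheme:

* subject blocks are updated conditional on the chain's group
  parameters by DE crossover sweeps plus blockwise Laplace independence
  proposals;
* group parameters are updated conditional on the subject draws by DE
  crossover and exact conditional (Gibbs/slice) refreshes;
* affine chain-level moves — a sigma/deviation rescale, a mu/subject
  translation, and a hierarchical crossover that shifts a chain's whole
  block by a donor difference — traverse the hierarchical funnel and
  merge chains (see docs/methods.md for why these are needed).

The number of chains is three times the subject-parameter count of the
model variant (so 36 for the drift-varying variant).  During burn-in a
migration move (cyclic state exchange among a random subset of chains)
fires with 5% probability per level; after burn-in only the
non-migration moves run.  Kept draws are thinned by 10 by default.

Proposals for chain ``i`` take the form ``theta_i + gamma (theta_j -
theta_k) + eps`` with distinct donors ``j, k != i``.  Donors are drawn
from the complementary half of the population (a red-blue split), which
keeps the simultaneous vectorised update a valid Metropolis kernel.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import lba
from .diagnostics import ConvergenceReport, hpdi, psrf

log = logging.getLogger(__name__)

#: per-run acceptance counters {move: [accepted, proposed]}, for diagnostics
_move_stats: dict = {}


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------

def default_hyperpriors(variant: lba.ModelVariant):
    """Weakly-informative hyperpriors on the sampling scale.

    Group means: drifts ~ N(1, 2); log A and log B ~ N(log 0.5, 1);
    log t0 ~ N(log 0.3, 0.5); log sv ~ N(log 0.5, 1).  Group SDs
    sigma_k ~ Exponential(1).
    """
    loc, scale = [], []
    for name in variant.param_names:
        if name.startswith("v_"):
            loc.append(1.0), scale.append(2.0)
        elif name.startswith(("A", "B")):
            loc.append(np.log(0.5)), scale.append(1.0)
        elif name.startswith("t0"):
            loc.append(np.log(0.3)), scale.append(0.5)
        else:  # sv_true
            loc.append(np.log(0.5)), scale.append(1.0)
    return np.array(loc), np.array(scale)


@dataclass
class HierModel:
    """Variant descriptor plus hyperpriors for the group level."""

    variant: lba.ModelVariant
    mu_loc: np.ndarray
    mu_scale: np.ndarray
    sigma_rate: float = 1.0

    @classmethod
    def for_variant(cls, name_or_variant) -> "HierModel":
        variant = (name_or_variant if isinstance(name_or_variant, lba.ModelVariant)
                   else lba.model_variant(name_or_variant))
        loc, scale = default_hyperpriors(variant)
        return cls(variant=variant, mu_loc=loc, mu_scale=scale)

    @property
    def n_params(self) -> int:
        return self.variant.n_params


@dataclass
class SamplerConfig:
    burnin: int = 500
    samples: int = 500
    thin: int = 10
    migration_prob: float = 0.05
    gamma: float | None = None        # default 2.38 / sqrt(2 d)
    jitter: float = 1e-3
    chain_factor: int = 3
    group_sweeps: int = 3             # group-level crossover sweeps/iteration
    subject_sweeps: int = 2
    scale_moves: int | None = 3       # funnel scale moves/iteration
                                      # (None: one per subject parameter)
    hier_crossovers: int = 8          # joint (mu + subjects) DE moves/iteration
    laplace_reps: int = 2             # independence-proposal rounds/subject
    target_mpsrf: float | None = None  # extend sampling until below this
    extension_samples: int | None = None
    max_extensions: int = 4
    time_budget: float | None = None   # seconds, bounds the extensions
    retain_last: int | None = None     # sliding window of stored draws:
                                       # older chunks age out as warm-up
    migration_during_sampling: bool = False
    seed: int = 0


@dataclass
class PosteriorSamples:
    """Thinned draws of a hierarchical fit.

    Subject and group draws are stored on the sampling scale
    (drifts natural, positive parameters log).  ``group_draws`` has
    layout (chain, stored iteration, 2p) ordered mu then log sigma.
    """

    variant: lba.ModelVariant
    subject_ids: tuple
    subject_draws: np.ndarray          # (chains, stored, subjects, p)
    group_draws: np.ndarray            # (chains, stored, 2p)
    pointwise_loglik: np.ndarray       # (chains * stored, n_trials)
    burnin: int
    thin: int
    config: SamplerConfig = None
    label: str = ""

    @property
    def group_param_names(self) -> tuple:
        names = self.variant.param_names
        return tuple([f"mu.{n}" for n in names]
                     + [f"sigma.{n}" for n in names])

    @property
    def n_stored(self) -> int:
        return self.group_draws.shape[1]

    def group_mu(self, parameter: str, scale: str = "natural") -> np.ndarray:
        """Flattened draws of the group-level location of ``parameter``.

        For log-sampled parameters ``scale='natural'`` returns
        ``exp(mu)`` (the population median on the natural scale).
        """
        names = self.variant.param_names
        if parameter not in names:
            raise KeyError(f"parameter {parameter!r} not in {names}")
        k = names.index(parameter)
        draws = self.group_draws[:, :, k].ravel()
        if scale == "natural" and not parameter.startswith("v_"):
            draws = np.exp(draws)
        return draws

    def group_sigma(self, parameter: str) -> np.ndarray:
        names = self.variant.param_names
        k = names.index(parameter)
        return np.exp(self.group_draws[:, :, self.variant.n_params + k].ravel())

    def subject_means(self, scale: str = "natural") -> np.ndarray:
        """(n_subjects, p) posterior-mean subject parameters."""
        psi = self.subject_draws.reshape(-1, *self.subject_draws.shape[2:])
        if scale == "natural":
            psi = lba.from_sampling_scale(psi, self.variant)
        return psi.mean(axis=0)


# ---------------------------------------------------------------------------
# DE-MCMC moves
# ---------------------------------------------------------------------------

def de_proposal(theta_i, theta_j, theta_k, gamma, eps=0.0):
    """Differential-evolution proposal theta_i + gamma (theta_j - theta_k) + eps."""
    return theta_i + gamma * (np.asarray(theta_j) - np.asarray(theta_k)) + eps


def crossover_step(states, logpost, gamma=None, jitter_width=1e-3, rng=None,
                   current_lp=None):
    """One DE crossover sweep over a chain population.

    ``states``: (n_chains, d); ``logpost(candidates, chain_idx)`` returns
    the per-chain log target.  Chains are updated in a red-blue split:
    each half proposes with donors drawn from the other half, so the
    vectorised simultaneous update remains a valid Metropolis kernel.
    Returns (new_states, new_logpost).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = np.array(states, dtype=float)
    n, d = states.shape
    if n < 4:
        raise ValueError("DE crossover requires at least 4 chains")
    if gamma is None:
        # base DE rate with a uniform multiplier (common DMC practice):
        # smaller average steps give healthier acceptance when the
        # population is overdispersed relative to the conditional target
        gamma = rng.uniform(0.5, 1.0) * 2.38 / np.sqrt(2.0 * d)
    if current_lp is None:
        current_lp = logpost(states, np.arange(n))
    lp = np.array(current_lp, dtype=float)

    half = n // 2
    groups = (np.arange(half), np.arange(half, n))
    for g, other in ((groups[0], groups[1]), (groups[1], groups[0])):
        m = len(g)
        j = rng.integers(0, len(other), size=m)
        k = (j + 1 + rng.integers(0, len(other) - 1, size=m)) % len(other)
        eps = rng.uniform(-jitter_width, jitter_width, size=(m, d))
        # occasional full-difference proposals (gamma = 1) let chains
        # swap between modes of the population
        gam = np.where(rng.uniform(size=m) < 0.1, 1.0, gamma)[:, None]
        cand = de_proposal(states[g], states[other][j], states[other][k],
                           gam, eps)
        cand_lp = np.asarray(logpost(cand, g), dtype=float)
        accept = np.log(rng.uniform(size=m)) < (cand_lp - lp[g])
        states[g[accept]] = cand[accept]
        lp[g[accept]] = cand_lp[accept]
    return states, lp


def migration_step(states, logpost, migration_prob, rng, current_lp=None):
    """Cyclic migration move among a random subset of chains.

    With probability ``migration_prob`` a subset of chains of random
    size proposes its cycle-predecessor's state; each proposal is
    accepted by Metropolis.  Otherwise the states are returned unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = np.array(states, dtype=float)
    n = states.shape[0]
    if current_lp is None:
        current_lp = logpost(states, np.arange(n))
    lp = np.array(current_lp, dtype=float)
    if migration_prob <= 0 or rng.uniform() >= migration_prob:
        return states, lp
    size = int(rng.integers(1, n + 1))
    sel = rng.permutation(n)[:size]
    if size < 2:
        return states, lp
    donors = np.roll(sel, 1)          # chain sel[i] proposes state of sel[i-1]
    cand = states[donors]
    cand_lp = np.asarray(logpost(cand, sel), dtype=float)
    accept = np.log(rng.uniform(size=size)) < (cand_lp - lp[sel])
    states[sel[accept]] = cand[accept]
    lp[sel[accept]] = cand_lp[accept]
    return states, lp


# ---------------------------------------------------------------------------
# data preparation and initial values
# ---------------------------------------------------------------------------

def _subject_arrays(data: pd.DataFrame):
    """Split a trial table into per-subject (rt, cond_idx, correct) arrays."""
    subjects, arrays = [], []
    resp = data["response"].astype(str)
    d = data[resp != "omission"]
    for sid, grp in d.groupby("subject_id", sort=True):
        rt = grp["rt"].to_numpy(float)
        cond = np.array([lba.CONDITIONS.index(c) for c in grp["condition"]])
        correct = grp["correct"].to_numpy(bool)
        subjects.append(sid)
        arrays.append((rt, cond, correct))
    return subjects, arrays


_DEFAULT_START = {"A": 0.4, "B": 0.6, "t0": 0.25, "sv_true": 0.5,
                  "v_true": 2.0, "v_false": 1.0}


def _fd_hessian(f, x, h=1e-3):
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


def _start_vector(variant: lba.ModelVariant, rt: np.ndarray) -> np.ndarray:
    start = []
    t0 = max(0.05, 0.5 * float(np.min(rt)))
    for name in variant.param_names:
        base = name.split(".")[0]
        start.append(t0 if base == "t0" else _DEFAULT_START[base])
    return np.array(start)


def fixed_effects_init(data: pd.DataFrame, variant_name) -> np.ndarray:
    """Per-subject penalised-ML estimates used to seed the sampler.

    Optimises each subject's summed log-likelihood (plus the group-level
    hyperprior density as a mild penalty) on the sampling scale with
    Nelder-Mead.  Deterministic given the data.  Returns natural-scale
    (n_subjects, p) estimates; failed optimisations fall back to
    domain-midpoint defaults with a warning.
    """
    variant = (variant_name if isinstance(variant_name, lba.ModelVariant)
               else lba.model_variant(variant_name))
    model = HierModel.for_variant(variant)
    _, arrays = _subject_arrays(data)
    out = []
    for rt, cond, correct in arrays:
        psi0 = lba.to_sampling_scale(_start_vector(variant, rt), variant)

        def neglp(psi):
            theta = lba.from_sampling_scale(psi[None, :], variant)
            ll = lba.loglik_batch(theta, variant, rt, cond, correct)[0]
            pen = -0.5 * np.sum(((psi - model.mu_loc) / (2.0 * model.mu_scale)) ** 2)
            return -(ll + pen)

        res = minimize(neglp, psi0, method="Nelder-Mead",
                       options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-4})
        psi = res.x if np.isfinite(res.fun) else psi0
        if not np.isfinite(res.fun):
            log.warning("fixed-effects fit failed; using default start values")
        out.append(lba.from_sampling_scale(psi, variant))
    return np.array(out)


# ---------------------------------------------------------------------------
# hierarchical sampler
# ---------------------------------------------------------------------------

def _group_logpost(group, psi_subj, model):
    """Group-level conditional log target, vectorised over chains.

    ``group``: (m, 2p) [mu, log sigma]; ``psi_subj``: (m, n_subj, p).
    """
    p = model.n_params
    mu = group[:, :p]
    log_sig = group[:, p:]
    sig = np.exp(log_sig)
    z = (psi_subj - mu[:, None, :]) / sig[:, None, :]
    ll = -0.5 * np.sum(z * z, axis=(1, 2)) \
        - psi_subj.shape[1] * np.sum(log_sig, axis=1)
    hyper_mu = -0.5 * np.sum(((mu - model.mu_loc) / model.mu_scale) ** 2, axis=1)
    # sigma ~ Exponential(rate); sampled as log sigma (Jacobian = sigma)
    hyper_sig = np.sum(-model.sigma_rate * sig + log_sig, axis=1)
    return ll + hyper_mu + hyper_sig


def _subject_logprior(psi, mu, log_sig):
    sig = np.exp(log_sig)
    z = (psi - mu) / sig
    return -0.5 * np.sum(z * z, axis=1) - np.sum(log_sig, axis=1)


def run_hierarchical(data: pd.DataFrame, variant_name,
                     config: SamplerConfig | None = None,
                     label: str = "") -> tuple[PosteriorSamples, ConvergenceReport]:
    """Fit the hierarchical LBA to a trial table by blocked DE-MCMC.

    Returns the thinned posterior draws (with the per-trial pointwise
    log-likelihood matrix needed for ELPD) and a split-half PSRF report
    over the group-level parameters.  A convergence failure is reported,
    not raised.
    """
    config = config or SamplerConfig()
    variant = (variant_name if isinstance(variant_name, lba.ModelVariant)
               else lba.model_variant(variant_name))
    model = HierModel.for_variant(variant)
    p = variant.n_params
    n_chains = config.chain_factor * p
    rng = np.random.default_rng(config.seed)

    subjects, arrays = _subject_arrays(data)
    n_subj = len(subjects)
    theta0 = fixed_effects_init(data, variant)
    psi0 = lba.to_sampling_scale(theta0, variant)      # (n_subj, p)

    # per-subject Laplace approximation of the likelihood (mode and
    # curvature on the sampling scale), used for independence proposals
    lap_mean = psi0
    lap_prec = np.empty((n_subj, p, p))
    for s in range(n_subj):
        rt, cond, correct = arrays[s]

        def nll(psi_vec):
            theta = lba.from_sampling_scale(psi_vec[None, :], variant)
            return -lba.loglik_batch(theta, variant, rt, cond, correct)[0]

        lap_prec[s] = _fd_hessian(nll, psi0[s])
        w, V = np.linalg.eigh(0.5 * (lap_prec[s] + lap_prec[s].T))
        w = np.clip(w, 1e-2, 1e6)   # PD floor: flat directions fall back
        lap_prec[s] = (V * w) @ V.T  # to the group prior in the proposal

    mu0 = psi0.mean(axis=0)
    sig0 = np.maximum(psi0.std(axis=0), 0.05)

    # chain populations, jittered around the fixed-effects solution
    psi = psi0[None, :, :] + 0.1 * sig0 * rng.standard_normal((n_chains, n_subj, p))
    group = np.concatenate([
        mu0[None, :] + 0.2 * sig0 * rng.standard_normal((n_chains, p)),
        np.log(sig0)[None, :] + 0.2 * rng.standard_normal((n_chains, p)),
    ], axis=1)

    def raw_ll(psi_c, s):
        rt, cond, correct = arrays[s]
        theta = lba.from_sampling_scale(psi_c, variant)
        return lba.loglik_batch(theta, variant, rt, cond, correct)

    rt_all = np.concatenate([a[0] for a in arrays])
    cond_all = np.concatenate([a[1] for a in arrays])
    corr_all = np.concatenate([a[2] for a in arrays])
    offsets = np.concatenate([[0], np.cumsum([len(a[0]) for a in arrays])])

    def raw_ll_all(psi_block):
        """(m, n_subj, p) sampling-scale states -> (m, n_subj) loglik."""
        theta = lba.from_sampling_scale(psi_block, variant)
        return lba.loglik_batch_subjects(theta, variant, rt_all, cond_all,
                                         corr_all, offsets)

    def subject_lp(psi_c, chain_idx, s):
        mu = group[chain_idx, :p]
        log_sig = group[chain_idx, p:]
        return raw_ll(psi_c, s) + _subject_logprior(psi_c, mu, log_sig)

    # cached per-chain, per-subject log-likelihood of the current states;
    # every subject-level move reuses and maintains it
    ll_cur = np.empty((n_chains, n_subj))

    # subject parameters are updated in two conditional blocks (drifts,
    # then the structural parameters A/B/t0/sv) for better mixing
    drift_block = np.array([i for i, nm in enumerate(variant.param_names)
                            if nm.startswith("v_")])
    struct_block = np.array([i for i, nm in enumerate(variant.param_names)
                             if not nm.startswith("v_")])
    # finer blocks for the independence proposals: lower dimension keeps
    # the acceptance rate of an independence sampler workable
    laplace_blocks = [b for b in (
        np.array([i for i, nm in enumerate(variant.param_names)
                  if nm.startswith("v_true")]),
        np.array([i for i, nm in enumerate(variant.param_names)
                  if nm.startswith("v_false")]),
        struct_block) if len(b)]
    laplace_others = [np.setdiff1d(np.arange(p), b) for b in laplace_blocks]

    def subject_crossover(s, block):
        """Red-blue DE crossover on one subject block with cached loglik."""
        half = n_chains // 2
        halves = (np.arange(half), np.arange(half, n_chains))
        d = len(block)
        for g, other in ((halves[0], halves[1]), (halves[1], halves[0])):
            m = len(g)
            gamma = config.gamma
            if gamma is None:
                gamma = rng.uniform(0.5, 1.0) * 2.38 / np.sqrt(2.0 * d)
            j = rng.integers(0, len(other), size=m)
            k = (j + 1 + rng.integers(0, len(other) - 1, size=m)) % len(other)
            eps = rng.uniform(-config.jitter, config.jitter, size=(m, d))
            gam = np.where(rng.uniform(size=m) < 0.1, 1.0, gamma)[:, None]
            cand = psi[g, s, :].copy()
            cand[:, block] = de_proposal(psi[g, s, :][:, block],
                                         psi[other[j], s, :][:, block],
                                         psi[other[k], s, :][:, block],
                                         gam, eps)
            mu = group[g, :p]
            log_sig = group[g, p:]
            ll_cand = raw_ll(cand, s)
            lp_cand = ll_cand + _subject_logprior(cand, mu, log_sig)
            lp_cur = ll_cur[g, s] + _subject_logprior(psi[g, s, :], mu, log_sig)
            accept = np.log(rng.uniform(size=m)) < (lp_cand - lp_cur)
            st = _move_stats.setdefault(f"cross_d{d}", [0, 0])
            st[0] += int(accept.sum())
            st[1] += m
            psi[g[accept], s, :] = cand[accept]
            ll_cur[g[accept], s] = ll_cand[accept]

    # the LBA's near-degenerate evidence-scale direction: multiplying all
    # drifts, A, B and sv by a common factor changes the data distribution
    # only through the fixed sv_false = 1, so the posterior has a long
    # soft ridge along it.  On the sampling scale the map is: drifts *= c,
    # log A/B/sv += log c, t0 untouched.
    v_idx = drift_block
    shift_idx = np.array([i for i, nm in enumerate(variant.param_names)
                          if not nm.startswith(("v_", "t0"))])
    n_vdim = len(v_idx)

    def subject_ridge_move(s, step=0.12):
        """Evidence-scale ridge move for one subject (all chains)."""
        delta = rng.normal(0.0, step, size=n_chains)
        c = np.exp(delta)
        cand = psi[:, s, :].copy()
        cand[:, v_idx] *= c[:, None]
        cand[:, shift_idx] += delta[:, None]
        mu = group[:, :p]
        log_sig = group[:, p:]
        ll_cand = raw_ll(cand, s)
        lp_cand = ll_cand + _subject_logprior(cand, mu, log_sig)
        lp_cur = ll_cur[:, s] + _subject_logprior(psi[:, s, :], mu, log_sig)
        # Jacobian of the drift scaling
        ratio = lp_cand - lp_cur + n_vdim * delta
        accept = np.log(rng.uniform(size=n_chains)) < ratio
        st = _move_stats.setdefault("ridge_subj", [0, 0])
        st[0] += int(accept.sum())
        st[1] += n_chains
        psi[accept, s, :] = cand[accept]
        ll_cur[accept, s] = ll_cand[accept]

    def chain_ridge_move(step=0.12):
        """Evidence-scale ridge move for a chain's whole hierarchical block.

        Applies the scale map to every subject and to (mu, sigma): drift
        mus scale by c, drift sigmas scale by c, log-dim mus shift by
        log c.  Z-scores are preserved, so the group density change
        cancels against the subject-level Jacobian and the ratio only
        involves the likelihood, the hyperpriors and the mu Jacobian.
        """
        delta = rng.normal(0.0, step, size=n_chains)
        c = np.exp(delta)
        psi_new = psi.copy()
        psi_new[:, :, v_idx] *= c[:, None, None]
        psi_new[:, :, shift_idx] += delta[:, None, None]
        ll_new = raw_ll_all(psi_new)
        dll = (ll_new - ll_cur).sum(axis=1)
        mu_old = group[:, :p]
        mu_new = mu_old.copy()
        mu_new[:, v_idx] *= c[:, None]
        mu_new[:, shift_idx] += delta[:, None]
        dh_mu = -0.5 * ((((mu_new - model.mu_loc) / model.mu_scale) ** 2
                         - ((mu_old - model.mu_loc) / model.mu_scale) ** 2)
                        .sum(axis=1))
        ls_old_v = group[:, p + v_idx]
        sig_old_v = np.exp(ls_old_v)
        sig_new_v = sig_old_v * c[:, None]
        dh_sig = (-model.sigma_rate * (sig_new_v - sig_old_v)
                  + delta[:, None]).sum(axis=1)
        ratio = dll + dh_mu + dh_sig + n_vdim * delta   # mu Jacobian
        accept = np.log(rng.uniform(size=n_chains)) < ratio
        st = _move_stats.setdefault("ridge_chain", [0, 0])
        st[0] += int(accept.sum())
        st[1] += n_chains
        psi[accept] = psi_new[accept]
        ll_cur[accept] = ll_new[accept]
        group[accept, :p] = mu_new[accept]
        group[np.ix_(accept, p + v_idx)] = ls_old_v[accept] + delta[accept, None]

    def laplace_independence_moves(s, reps):
        """Blockwise independence MH from the Laplace-approximate conditional.

        The proposal for one parameter block is the conditional (given
        the current values of the other block) of the Gaussian formed by
        the subject's precomputed likelihood Laplace approximation and
        the chain's current group prior.  Lower-dimensional blocks keep
        the independence-sampler acceptance rate workable; the exact
        likelihood enters through the Metropolis correction.  The joint
        Gaussian is factored once per subject and iteration.
        """
        mu = group[:, :p]
        log_sig = group[:, p:]
        D = np.exp(-2.0 * log_sig)                     # (m, p) prior precisions
        P = lap_prec[s][None, :, :] + D[:, :, None] * np.eye(p)[None, :, :]
        rhs = (lap_prec[s] @ lap_mean[s])[None, :] + D * mu   # (m, p)
        m_full = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        pre = {}
        for bi, block in enumerate(laplace_blocks):
            other = laplace_others[bi]
            Pbb = P[:, block[:, None], block[None, :]]
            Pbo = P[:, block[:, None], other[None, :]]
            pre[bi] = (block, other, Pbb, Pbo, np.linalg.cholesky(Pbb))
        for _ in range(reps):
            for bi in pre:
                _laplace_block_update(s, m_full, *pre[bi])

    def _laplace_block_update(s, m_full, block, other, Pbb, Pbo, L):
        infl = 1.25   # proposal SD inflation: the conditional is wider
        mu = group[:, :p]   # than its curvature along soft ridges
        dx_o = (psi[:, s, other] - m_full[:, other])[:, :, None]
        mean_b = m_full[:, block] - np.linalg.solve(Pbb, Pbo @ dx_o)[:, :, 0]
        z = rng.standard_normal((n_chains, len(block)))
        cand_b = mean_b + infl * np.linalg.solve(np.swapaxes(L, 1, 2),
                                                 z[:, :, None])[:, :, 0]
        logdetL = np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1) \
            - len(block) * np.log(infl)

        def logq(xb):
            d = (xb - mean_b)[:, :, None]
            u = (np.swapaxes(L, 1, 2) @ d)[:, :, 0] / infl
            return -0.5 * np.sum(u * u, axis=1) + logdetL

        cur = psi[:, s, :]
        cand = cur.copy()
        cand[:, block] = cand_b
        prior_all = _subject_logprior
        ls = group[:, p:]
        ll_cand = raw_ll(cand, s)
        ratio = (ll_cand + prior_all(cand, mu, ls)
                 - ll_cur[:, s] - prior_all(cur, mu, ls)
                 + logq(cur[:, block]) - logq(cand_b))
        accept = np.log(rng.uniform(size=n_chains)) < ratio
        st = _move_stats.setdefault(f"laplace_d{len(block)}", [0, 0])
        st[0] += int(accept.sum())
        st[1] += n_chains
        psi[accept, s, :] = cand[accept]
        ll_cur[accept, s] = ll_cand[accept]

    def gibbs_group_refresh():
        """Exact conditional refresh of the group level.

        Given the subject draws, mu_k has a closed-form normal
        conditional (normal hyperprior); log sigma_k is drawn by slice
        sampling from its 1-D conditional (exponential hyperprior with
        the log-scale Jacobian).  Both are vectorised over chains and
        parameters and supplement the DE crossover sweeps.
        """
        sig = np.exp(group[:, p:])                      # (m, p)
        xbar = psi.mean(axis=1)                         # (m, p)
        prec = 1.0 / model.mu_scale ** 2 + n_subj / sig ** 2
        mean = (model.mu_loc / model.mu_scale ** 2
                + n_subj * xbar / sig ** 2) / prec
        group[:, :p] = mean + rng.standard_normal((n_chains, p)) / np.sqrt(prec)

        mu = group[:, :p]
        ss = np.sum((psi - mu[:, None, :]) ** 2, axis=1)  # (m, p)
        x0 = group[:, p:]

        def logf(x):
            s = np.exp(x)
            return (-n_subj * x - ss / (2.0 * s * s)
                    - model.sigma_rate * s + x)

        # stepping-out slice sampler, vectorised with masks
        y = logf(x0) + np.log(rng.uniform(size=x0.shape))
        w = 0.5
        lo = x0 - w * rng.uniform(size=x0.shape)
        hi = lo + w
        for _ in range(20):
            grow_lo = logf(lo) > y
            grow_hi = logf(hi) > y
            if not (grow_lo.any() or grow_hi.any()):
                break
            lo = np.where(grow_lo, lo - w, lo)
            hi = np.where(grow_hi, hi + w, hi)
        x = lo + rng.uniform(size=x0.shape) * (hi - lo)
        for _ in range(50):
            bad = logf(x) < y
            if not bad.any():
                break
            lo = np.where(bad & (x < x0), x, lo)
            hi = np.where(bad & (x >= x0), x, hi)
            x = np.where(bad, lo + rng.uniform(size=x0.shape) * (hi - lo), x)
        group[:, p:] = x

    def scale_move(k, scale_step=0.25):
        """Single-parameter (sigma, subject-deviation) rescaling move.

        Proposes log sigma_k += delta while rescaling every subject's
        deviation from mu_k by the same factor.  The group-density
        change cancels against the transformation Jacobian, so the
        Metropolis ratio reduces to the likelihood change plus the sigma
        hyperprior — and for weakly-informed parameters the move
        traverses the hierarchical funnel freely.
        """
        delta = rng.normal(0.0, scale_step, size=n_chains)
        mu_k = group[:, k]
        log_sig_k = group[:, p + k]
        psi_new = psi.copy()
        psi_new[:, :, k] = (mu_k[:, None]
                            + (psi[:, :, k] - mu_k[:, None])
                            * np.exp(delta)[:, None])
        ll_new = raw_ll_all(psi_new)
        dll = (ll_new - ll_cur).sum(axis=1)
        sig_old = np.exp(log_sig_k)
        sig_new = np.exp(log_sig_k + delta)
        dhyper = -model.sigma_rate * (sig_new - sig_old) + delta
        accept = np.log(rng.uniform(size=n_chains)) < dll + dhyper
        st = _move_stats.setdefault("scale", [0, 0])
        st[0] += int(accept.sum())
        st[1] += n_chains
        psi[accept] = psi_new[accept]
        ll_cur[accept] = ll_new[accept]
        group[accept, p + k] = log_sig_k[accept] + delta[accept]

    def translation_move(k, rel_step=0.6):
        """Joint (mu, subject-value) translation along one parameter.

        Shifts mu_k and every subject's psi_k by the same delta, leaving
        the group density invariant; the Metropolis ratio reduces to the
        likelihood change plus the mu hyperprior.  Together with the
        scale move this gives each chain affine mobility of its whole
        hierarchical block, breaking the slow self-anchoring loop
        between group and subject levels.
        """
        sig_k = np.exp(group[:, p + k])
        delta = rng.normal(0.0, rel_step, size=n_chains) * sig_k \
            / np.sqrt(n_subj)
        psi_new = psi.copy()
        psi_new[:, :, k] = psi[:, :, k] + delta[:, None]
        ll_new = raw_ll_all(psi_new)
        dll = (ll_new - ll_cur).sum(axis=1)
        mu_old = group[:, k]
        mu_new = mu_old + delta
        dhyper = (-0.5 * ((mu_new - model.mu_loc[k]) / model.mu_scale[k]) ** 2
                  + 0.5 * ((mu_old - model.mu_loc[k]) / model.mu_scale[k]) ** 2)
        accept = np.log(rng.uniform(size=n_chains)) < dll + dhyper
        st = _move_stats.setdefault("translate", [0, 0])
        st[0] += int(accept.sum())
        st[1] += n_chains
        psi[accept] = psi_new[accept]
        ll_cur[accept] = ll_new[accept]
        group[accept, k] = mu_new[accept]

    def hierarchical_crossover():
        """DE crossover on mu with the subjects translated alongside.

        The proposal shifts a chain's whole hierarchical block — group
        means and every subject vector — by a scaled difference of two
        donor chains' group means.  Donor differences point along the
        directions chains still disagree on, so this move contracts
        exactly the between-chain variance the convergence diagnostic
        measures, while the group density stays invariant under the
        joint translation.
        """
        half = n_chains // 2
        halves = (np.arange(half), np.arange(half, n_chains))
        for g, other in ((halves[0], halves[1]), (halves[1], halves[0])):
            m = len(g)
            gamma = rng.uniform(0.2, 0.7) * 2.38 / np.sqrt(2.0 * p)
            gam = np.where(rng.uniform(size=m) < 0.1, 1.0, gamma)[:, None]
            j = rng.integers(0, len(other), size=m)
            k = (j + 1 + rng.integers(0, len(other) - 1, size=m)) % len(other)
            delta = gam * (group[other[j], :p] - group[other[k], :p]) \
                + rng.uniform(-config.jitter, config.jitter, size=(m, p))
            # half the proposals move the location only; the other half
            # also carry the donors' scale difference
            dls = gam * (group[other[j], p:] - group[other[k], p:]) \
                * (rng.uniform(size=(m, 1)) < 0.5)
            mu_old = group[g, :p]
            mu_new = mu_old + delta
            ls_old = group[g, p:]
            ls_new = ls_old + dls
            # subjects follow the affine map; z-scores are preserved, so
            # the group density change cancels against the Jacobian
            psi_new = (mu_new[:, None, :]
                       + (psi[g] - mu_old[:, None, :]) * np.exp(dls)[:, None, :])
            ll_new = raw_ll_all(psi_new)
            dll = (ll_new - ll_cur[g]).sum(axis=1)
            dhyper_mu = -0.5 * (((mu_new - model.mu_loc) / model.mu_scale) ** 2
                                - ((mu_old - model.mu_loc)
                                   / model.mu_scale) ** 2).sum(axis=1)
            dhyper_sig = (-model.sigma_rate * (np.exp(ls_new) - np.exp(ls_old))
                          + dls).sum(axis=1)
            accept = np.log(rng.uniform(size=m)) < dll + dhyper_mu + dhyper_sig
            st = _move_stats.setdefault("hier_cross", [0, 0])
            st[0] += int(accept.sum())
            st[1] += m
            psi[g[accept]] = psi_new[accept]
            ll_cur[g[accept]] = ll_new[accept]
            group[g[accept], :p] = mu_new[accept]
            group[g[accept], p:] = ls_new[accept]

    n_trials_total = sum(len(a[0]) for a in arrays)

    def run_phase(burn_i, samp_i, first_phase, sub_store, grp_store,
                  ll_store):
        """Run ``burn_i + samp_i`` iterations, storing thinned draws."""
        stored = 0
        for it in range(burn_i + samp_i):
            in_burnin = it < burn_i
            # migration runs during the initial burn-in and during
            # extension phases (where it re-merges chains that locked
            # into remote configurations; the pre-merge draws age out of
            # the retention window)
            migrate = (in_burnin or not first_phase
                       or config.migration_during_sampling) \
                and config.migration_prob > 0

            # --- group level -----------------------------------------------
            # the group conditional factorises over parameters given the
            # subject draws, so each (mu_k, log sigma_k) pair is its own
            # 2-D DE block; migration acts on the full group vector
            if migrate:
                def grp_lp(cand, idx):
                    return _group_logpost(cand, psi[idx], model)
                group[:, :], _ = migration_step(group, grp_lp,
                                                config.migration_prob, rng)
            for _ in range(config.group_sweeps):
                for k in range(p):
                    def blk_lp(cand, idx, k=k):
                        mu, ls = cand[:, 0], cand[:, 1]
                        sig = np.exp(ls)
                        z = (psi[idx][:, :, k] - mu[:, None]) / sig[:, None]
                        return (-0.5 * np.sum(z * z, axis=1) - n_subj * ls
                                - 0.5 * ((mu - model.mu_loc[k])
                                         / model.mu_scale[k]) ** 2
                                - model.sigma_rate * sig + ls)
                    blk = group[:, [k, p + k]]
                    blk, _ = crossover_step(blk, blk_lp, gamma=config.gamma,
                                            jitter_width=config.jitter,
                                            rng=rng)
                    group[:, k] = blk[:, 0]
                    group[:, p + k] = blk[:, 1]

            # --- subject level ---------------------------------------------
            if first_phase and it == 0:
                ll_cur[:, :] = raw_ll_all(psi)
            for s in range(n_subj):
                if migrate:
                    lp_s = lambda cand, idx, s=s: subject_lp(cand, idx, s)
                    psi[:, s, :], _ = migration_step(psi[:, s, :], lp_s,
                                                     config.migration_prob,
                                                     rng)
                    ll_cur[:, s] = raw_ll(psi[:, s, :], s)
                for _ in range(config.subject_sweeps):
                    for block in (drift_block, struct_block):
                        subject_crossover(s, block)
                laplace_independence_moves(s, config.laplace_reps)
                subject_ridge_move(s)

            n_scale = (config.scale_moves if config.scale_moves is not None
                       else p)
            for k in rng.permutation(p)[:n_scale]:
                scale_move(int(k))
                translation_move(int(k))
            for _ in range(config.hier_crossovers):
                hierarchical_crossover()
            chain_ridge_move()
            chain_ridge_move()
            gibbs_group_refresh()

            if not in_burnin and (it - burn_i) % config.thin == config.thin - 1:
                sub_store[:, stored] = psi
                grp_store[:, stored] = group
                offset = 0
                for s in range(n_subj):
                    rt, cond, correct = arrays[s]
                    theta = lba.from_sampling_scale(psi[:, s, :], variant)
                    pw = lba.loglik_batch(theta, variant, rt, cond, correct,
                                          pointwise=True)
                    ll_store[:, stored, offset:offset + len(rt)] = pw
                    offset += len(rt)
                stored += 1
        return stored

    # sampling proceeds in phases: the configured (burnin, samples) run,
    # then optional extensions until the split-half multivariate PSRF
    # drops below ``target_mpsrf`` or the wall-clock budget runs out --
    # mirroring the practice of sampling until the convergence criterion
    # is met.  The diagnostic always covers *all* stored draws.
    t_start = time.monotonic()
    phases = [(config.burnin, config.samples)]
    if config.target_mpsrf is not None:
        ext = config.extension_samples or max(
            config.thin * (config.samples // (4 * config.thin)), config.thin)
        phases += [(0, ext)] * config.max_extensions

    sub_chunks, grp_chunks, ll_chunks = [], [], []
    first_phase = True
    interim = None
    for burn_i, samp_i in phases:
        if not first_phase:
            if interim is not None and interim.mpsrf < config.target_mpsrf:
                break
            if (config.time_budget is not None
                    and time.monotonic() - t_start > config.time_budget):
                break
        n_store = samp_i // config.thin
        sub_store = np.empty((n_chains, n_store, n_subj, p))
        grp_store = np.empty((n_chains, n_store, 2 * p))
        ll_store = np.empty((n_chains, n_store, n_trials_total))
        stored = run_phase(burn_i, samp_i, first_phase,
                           sub_store, grp_store, ll_store)
        sub_chunks.append(sub_store[:, :stored])
        grp_chunks.append(grp_store[:, :stored])
        ll_chunks.append(ll_store[:, :stored])
        if config.retain_last is not None:
            # fixed retention rule: keep only the most recent draws, so
            # the earliest (least equilibrated) chunks age out as
            # additional warm-up while sampling is extended
            while (sum(c.shape[1] for c in grp_chunks)
                   - grp_chunks[0].shape[1] >= config.retain_last
                   and len(grp_chunks) > 1):
                sub_chunks.pop(0)
                grp_chunks.pop(0)
                ll_chunks.pop(0)
        if config.target_mpsrf is not None:
            grp_all = np.concatenate(grp_chunks, axis=1)
            if grp_all.shape[1] >= 4:
                interim = psrf(grp_all)
        first_phase = False

    sub_all = np.concatenate(sub_chunks, axis=1)
    grp_all = np.concatenate(grp_chunks, axis=1)
    ll_flat = np.concatenate(ll_chunks, axis=1).reshape(-1, n_trials_total)

    post = PosteriorSamples(variant=variant, subject_ids=tuple(subjects),
                            subject_draws=sub_all, group_draws=grp_all,
                            pointwise_loglik=ll_flat, burnin=config.burnin,
                            thin=config.thin, config=config, label=label)
    if grp_all.shape[1] >= 4:
        report = psrf(grp_all, param_names=post.group_param_names)
    else:
        # too few stored draws for split-half diagnostics
        report = ConvergenceReport(psrf=np.full(2 * p, np.inf),
                                   mpsrf=np.inf, passed=False,
                                   param_names=post.group_param_names)
    if not report.passed:
        log.warning("hierarchical fit did not converge: mpsrf=%.3f",
                    report.mpsrf)
    return post, report


# ---------------------------------------------------------------------------
# group comparison and posterior prediction
# ---------------------------------------------------------------------------

@dataclass
class GroupDifference:
    parameter: str
    delta_draws: np.ndarray      # control minus patient, paired draws
    mean: float
    interval: tuple
    significant: bool
    mass: float = 0.95


def compare_groups(post_controls: PosteriorSamples,
                   post_patients: PosteriorSamples,
                   parameter: str, mass: float = 0.95,
                   scale: str = "natural") -> GroupDifference:
    """Posterior of the group difference in a group-level location.

    Draws are paired in stored order after truncating to the shorter
    sample; positive differences mean controls larger.  The difference
    is flagged significant when the ``mass`` HPD interval excludes zero.
    """
    dc = post_controls.group_mu(parameter, scale=scale)
    dp = post_patients.group_mu(parameter, scale=scale)
    n = min(len(dc), len(dp))
    delta = dc[:n] - dp[:n]
    lo, hi = hpdi(delta, mass)
    return GroupDifference(parameter=parameter, delta_draws=delta,
                           mean=float(delta.mean()), interval=(lo, hi),
                           significant=bool(lo > 0 or hi < 0), mass=mass)


def posterior_predictive_cohort(group_fits: dict, n_per_group: int = 1000,
                                trials_per_condition: int = 20,
                                seed: int = 0) -> pd.DataFrame:
    """Simulate a synthetic cohort from fitted group-level posteriors.

    For each synthetic subject a stored group-level draw is selected,
    subject parameters are drawn from the population distribution, and
    ``trials_per_condition`` trials are simulated per condition.  With
    the defaults and two groups this yields 2000 subjects.
    """
    rng = np.random.default_rng(seed)
    frames = []
    sid = 0
    for group, post in group_fits.items():
        variant = post.variant
        p = variant.n_params
        flat = post.group_draws.reshape(-1, 2 * p)
        for _ in range(n_per_group):
            draw = flat[rng.integers(0, flat.shape[0])]
            mu, sig = draw[:p], np.exp(draw[p:])
            psi = rng.normal(mu, sig)
            theta = lba.from_sampling_scale(psi, variant)
            params = lba.params_from_vector(theta, variant)
            design = pd.DataFrame({
                "condition": np.repeat(lba.CONDITIONS, trials_per_condition),
                "onset": np.arange(4 * trials_per_condition, dtype=float),
            })
            trials = lba.simulate_trials(params, design,
                                         rng_seed=int(rng.integers(2 ** 31)))
            trials.insert(0, "group", group)
            trials.insert(0, "subject_id", f"ppc{sid:05d}")
            frames.append(trials)
            sid += 1
    return pd.concat(frames, ignore_index=True)


def subsample_cohort(trials: pd.DataFrame, n_controls: int = 33,
                     n_patients: int = 30, seed: int = 0,
                     groups: tuple = ("control", "MDD")) -> pd.DataFrame:
    """Randomly select a study-sized subsample of a simulated cohort."""
    rng = np.random.default_rng(seed)
    keep = []
    for group, n in zip(groups, (n_controls, n_patients)):
        ids = trials.loc[trials["group"] == group, "subject_id"].unique()
        keep.extend(rng.choice(ids, size=n, replace=False))
    return trials[trials["subject_id"].isin(keep)].copy()
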