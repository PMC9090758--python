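"""Leave-one-out cross-validated diagnosis classification from connectivity.

For each subject, the PEB model is fitted to all remaining subjects and
the roles of predictor and data are swapped for the held-out one: the
posterior predictive density of their connectivity is evaluated under
each possible group code (with their nuisance covariates fixed), giving
a posterior probability of diagnostic status.  The probability list
yields the ROC curve and the area under it (the Mann-Whitney pairwise
concordance); confidence bounds come from a stratified bootstrap of the
probability list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .peb import peb_fit

log = logging.getLogger(__name__)


@dataclass
class LoocvResult:
    probabilities: np.ndarray    # P(group == positive label) per subject
    labels: np.ndarray           # binary group membership (1 = patient)
    auc: float
    auc_ci: tuple
    roc: tuple                   # (fpr, tpr) arrays
    skipped: tuple = ()


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the pairwise concordance probability (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (pos.size * neg.size))


def _roc_curve(scores, labels):
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def _bootstrap_ci(scores, labels, n_boot=2000, seed=0, mass=0.95):
    rng = np.random.default_rng(seed)
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, float)
    ip, iq = np.where(y)[0], np.where(~y)[0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(ip, size=ip.size, replace=True)
        bn = rng.choice(iq, size=iq.size, replace=True)
        sel = np.concatenate([bp, bn])
        stats[b] = auc_mann_whitney(s[sel], y[sel])
    a = (1 - mass) / 2
    return float(np.quantile(stats, a)), float(np.quantile(stats, 1 - a))


def loocv_classify(posteriors, X, covariate_names, param_subset="A",
                   group_col: str = "group", seed: int = 0,
                   n_boot: int = 2000, **peb_kwargs) -> LoocvResult:
    """LOOCV group classification from DCM parameters via PEB.

    ``X`` is the full second-level design (intercept first, mean-centered
    covariates) and must contain a group column; each fold refits the
    PEB on the remaining subjects (with the fold's columns re-centered)
    and scores the held-out subject's implied connectivity under both
    group codes.  Folds whose PEB fit fails are skipped with a warning.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    gi = list(covariate_names).index(group_col)
    group_raw = X[:, gi] - X[:, gi].min()          # 0 for controls
    group_raw = group_raw / group_raw.max()         # exactly 0/1
    labels = group_raw.astype(int)
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    probs = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        keep = np.arange(n) != i
        Xt = X[keep].copy()
        raw_cols = {}
        for j in range(1, X.shape[1]):
            raw_cols[j] = Xt[:, j].mean()
            Xt[:, j] -= raw_cols[j]
        try:
            peb = peb_fit([posteriors[k] for k in np.where(keep)[0]], Xt,
                          param_subset=param_subset,
                          covariate_names=covariate_names, **peb_kwargs)
        except Exception as exc:  # noqa: BLE001 - fold failure is reported
            log.warning("LOOCV fold %d failed: %s", i, exc)
            skipped.append(i)
            continue
        # candidate design rows for the held-out subject under both groups
        lp = np.empty(2)
        for g, code in enumerate(sorted(np.unique(X[:, gi]))):
            xi = X[i].copy()
            xi[gi] = code
            for j in range(1, X.shape[1]):
                xi[j] -= raw_cols[j]
            lp[g] = _predictive_logdensity(peb, xi, i, posteriors,
                                           param_subset)
        lp -= lp.max()
        post = np.exp(lp) / np.exp(lp).sum()
        probs[i] = post[1]          # probability of the higher group code
    ok = ~np.isnan(probs)
    scores, y = probs[ok], labels[ok]
    auc = auc_mann_whitney(scores, y)
    ci = _bootstrap_ci(scores, y, n_boot=n_boot, seed=seed)
    return LoocvResult(probabilities=probs, labels=labels, auc=auc,
                       auc_ci=ci, roc=_roc_curve(scores, y),
                       skipped=tuple(skipped))


def _predictive_logdensity(peb, x_row, i, posteriors, param_subset):
    """Log posterior-predictive density of subject i's connectivity."""
    from .peb import implied_observation
    p = peb.n_params
    idx = posteriors[i].subset(param_subset) if isinstance(param_subset, str) \
        else np.asarray(param_subset, int)
    h, Q = implied_observation(posteriors[i], idx)
    A = np.kron(x_row, np.eye(p))
    mu = A @ peb.beta_mean
    S = A @ peb.beta_cov @ A.T + Q + peb.re_cov
    S = 0.5 * (S + S.T)
    sign, logdet = np.linalg.slogdet(S)
    d = h - mu
    return -0.5 * (logdet + d @ np.linalg.solve(S, d) + p * np.log(2 * np.pi))
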