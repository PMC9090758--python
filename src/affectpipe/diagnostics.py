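"""Posterior diagnostics: HPD intervals, convergence, predictive accuracy.

Convergence follows the split-half potential scale reduction factor
(PSRF): each chain is cut in half, doubling the chain count, and the
Gelman-Rubin statistic is computed per parameter together with the
Brooks-Gelman multivariate version.  A fit passes when the multivariate
R-hat is below 1.1.

Model comparison uses the expected log pointwise predictive density
(ELPD) estimated by WAIC from the stored pointwise log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# highest posterior density interval
# ---------------------------------------------------------------------------

def hpdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Implements the sorted-window search: with ``n`` sorted draws the
    interval covers ``ceil(mass * n)`` consecutive order statistics and
    the window with minimal width is returned.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 1:
        raise ValueError("hpdi requires at least one draw")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


# ---------------------------------------------------------------------------
# potential scale reduction factor
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Univariate and multivariate split-half PSRF."""

    psrf: np.ndarray            # per-parameter univariate R-hat
    mpsrf: float                # Brooks-Gelman multivariate R-hat
    passed: bool
    param_names: tuple = ()

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"ConvergenceReport(mpsrf={self.mpsrf:.4f}, "
                f"max_psrf={np.max(self.psrf):.4f}, passed={self.passed})")


def _split_chains(x: np.ndarray) -> np.ndarray:
    """(m, n, p) -> (2m, n//2, p), dropping an odd trailing draw."""
    m, n, p = x.shape
    h = n // 2
    return np.concatenate([x[:, :h], x[:, h: 2 * h]], axis=0)


def psrf(samples: np.ndarray, param_names=(), threshold: float = 1.1
         ) -> ConvergenceReport:
    """Split-half PSRF of an (n_chains, n_iter, n_params) array.

    Univariate R-hat per Gelman-Rubin; multivariate per Brooks-Gelman,
    ``R = (n-1)/n + (m+1)/m * lambda_1`` with ``lambda_1`` the largest
    eigenvalue of ``W^{-1} B / n``.  Degenerate (zero-variance) chains
    report R-hat 1 by convention.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("psrf needs >= 2 chains and >= 4 stored iterations")
    x = _split_chains(x)
    m, n, p = x.shape

    chain_means = x.mean(axis=1)                      # (m, p)
    grand_mean = chain_means.mean(axis=0)             # (p,)
    B_over_n = ((chain_means - grand_mean).T @ (chain_means - grand_mean)
                ) / (m - 1)                           # B/n, (p, p)
    dev = x - chain_means[:, None, :]
    W = np.einsum("cip,ciq->pq", dev, dev) / (m * (n - 1))

    var_w = np.diag(W)
    var_b = np.diag(B_over_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = (n - 1) / n * var_w + var_b
        rhat = np.sqrt((m + 1) / m * sigma2 / var_w - (n - 1) / (m * n))
    rhat = np.where(var_w <= 0, 1.0, rhat)
    rhat = np.where(np.isfinite(rhat), rhat, 1.0)

    # multivariate: largest eigenvalue of W^{-1} (B/n)
    if np.all(var_w > 0):
        jitter = 1e-12 * np.trace(W) / p
        try:
            lam = np.linalg.eigvals(
                np.linalg.solve(W + jitter * np.eye(p), B_over_n))
            lam1 = float(np.max(lam.real))
        except np.linalg.LinAlgError:  # pragma: no cover
            lam1 = float(np.max(var_b / np.maximum(var_w, 1e-300)))
        # variance-scale statistic, matching the convention of the R
        # `coda` implementation (no square root on the multivariate form)
        mpsrf = float((n - 1) / n + (m + 1) / m * lam1)
    else:
        mpsrf = 1.0
    return ConvergenceReport(psrf=rhat, mpsrf=mpsrf,
                             passed=bool(mpsrf < threshold),
                             param_names=tuple(param_names))


# ---------------------------------------------------------------------------
# WAIC / ELPD
# ---------------------------------------------------------------------------

@dataclass
class ElpdResult:
    elpd: float
    se: float
    p_eff: float
    pointwise: np.ndarray


def waic(pointwise_loglik: np.ndarray) -> ElpdResult:
    """WAIC estimate of the ELPD from a (draws, observations) matrix.

    ``lppd_i = log mean_s exp(ll_si)``, penalty ``p_i = var_s(ll_si)``,
    ``elpd_i = lppd_i - p_i``; the SE is ``sqrt(n * var_i(elpd_i))``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    s, n = ll.shape
    mx = ll.max(axis=0)
    lppd = mx + np.log(np.mean(np.exp(ll - mx), axis=0))
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd - p_i
    return ElpdResult(elpd=float(elpd_i.sum()),
                      se=float(np.sqrt(n * elpd_i.var(ddof=1))),
                      p_eff=float(p_i.sum()),
                      pointwise=elpd_i)


@dataclass
class ModelComparison:
    """ELPD ranking across model variants."""

    names: tuple
    elpd: np.ndarray
    se: np.ndarray
    winner: str

    @property
    def ranking(self) -> tuple:
        order = np.argsort(-self.elpd)
        return tuple(self.names[i] for i in order)


def elpd_compare(fits: dict) -> ModelComparison:
    """Compare variants by WAIC-estimated ELPD.

    ``fits`` maps variant name to a (draws, trials) pointwise
    log-likelihood matrix (or an object exposing ``pointwise_loglik``).
    All matrices must cover the same trials.
    """
    mats = {}
    for name, f in fits.items():
        mats[name] = np.asarray(getattr(f, "pointwise_loglik", f), float)
    n_trials = {m.shape[1] for m in mats.values()}
    if len(n_trials) != 1:
        raise ValueError("pointwise log-likelihoods cover different trial sets")
    names = tuple(mats)
    res = [waic(mats[n]) for n in names]
    elpd = np.array([r.elpd for r in res])
    se = np.array([r.se for r in res])
    return ModelComparison(names=names, elpd=elpd, se=se,
                           winner=names[int(np.argmax(elpd))])
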