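"""Numba-compiled batch likelihood for the two-accumulator LBA.

Mirrors the closed forms in :mod:`affectpipe.lba` (positive-drift
truncation) for the hot path of the hierarchical sampler: evaluating one
subject's trials under many parameter vectors at once, or a whole
cohort of (chain, subject) rows in one call.
"""

import math

import numpy as np
from numba import njit

SQRT2PI = math.sqrt(2.0 * math.pi)
LOGLIK_FLOOR = -1e10


@njit(cache=True, fastmath=True, inline="always")
def _ndtr(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True, fastmath=True, inline="always")
def _npdf(x):
    return math.exp(-0.5 * x * x) / SQRT2PI


@njit(cache=True, fastmath=True, inline="always")
def _acc_pdf_n(t, A, b, v, sv, znorm):
    """First-passage density given the precomputed normaliser Phi(v/sv)."""
    if znorm < 1e-300:
        # drift almost surely at the truncation boundary: no finite-time
        # crossing mass worth representing
        return 0.0
    z1 = (b - A - t * v) / (t * sv)
    z2 = (b - t * v) / (t * sv)
    f = (-v * _ndtr(z1) + sv * _npdf(z1) + v * _ndtr(z2) - sv * _npdf(z2)) / A
    f = f / znorm
    return f if f > 0.0 else 0.0


@njit(cache=True, fastmath=True, inline="always")
def _acc_cdf_n(t, A, b, v, sv, znorm):
    if znorm < 1e-300:
        return 0.0
    z1 = (b - A - t * v) / (t * sv)
    z2 = (b - t * v) / (t * sv)
    F = (1.0 + (b - A - t * v) / A * _ndtr(z1)
         - (b - t * v) / A * _ndtr(z2)
         + t * sv / A * (_npdf(z1) - _npdf(z2)))
    F = F / znorm
    if F < 0.0:
        return 0.0
    if F > 1.0:
        return 1.0
    return F


@njit(cache=True, fastmath=True, inline="always")
def _acc_pdf(t, A, b, v, sv):
    return _acc_pdf_n(t, A, b, v, sv, _ndtr(v / sv))


@njit(cache=True, fastmath=True, inline="always")
def _acc_cdf(t, A, b, v, sv):
    return _acc_cdf_n(t, A, b, v, sv, _ndtr(v / sv))


@njit(cache=True, fastmath=True, inline="always")
def _row_loglik(Ai, Brow, t0i, svi, vt_row, vf_row, rt, cond, correct,
                j0, j1, pointwise, out_pw, row, zn_t, zn_f):
    """One parameter vector against trials ``j0:j1``; returns the sum."""
    valid = (Ai >= 0.0) and (t0i > 0.0) and (svi > 0.0)
    if valid:
        for c in range(4):
            if Brow[c] <= 0.0:
                valid = False
    if valid:
        for c in range(4):
            zn_t[c] = _ndtr(vt_row[c] / svi)
            zn_f[c] = _ndtr(vf_row[c])
    total = 0.0
    for j in range(j0, j1):
        ll = LOGLIK_FLOOR
        if valid:
            dt = rt[j] - t0i
            if dt > 0.0:
                c = cond[j]
                b = Ai + Brow[c]
                if correct[j]:
                    vw, sw, znw = vt_row[c], svi, zn_t[c]
                    vl, sl, znl = vf_row[c], 1.0, zn_f[c]
                else:
                    vw, sw, znw = vf_row[c], 1.0, zn_f[c]
                    vl, sl, znl = vt_row[c], svi, zn_t[c]
                Ai_s = Ai if Ai > 1e-9 else 1e-9
                f = _acc_pdf_n(dt, Ai_s, b, vw, sw, znw)
                S = 1.0 - _acc_cdf_n(dt, Ai_s, b, vl, sl, znl)
                dens = f * S
                if dens > 0.0:
                    ll = math.log(dens)
                    if ll < LOGLIK_FLOOR:
                        ll = LOGLIK_FLOOR
                    elif not math.isfinite(ll):
                        ll = LOGLIK_FLOOR
        if pointwise:
            out_pw[row, j - j0] = ll
        total += ll
    return total


@njit(cache=True, fastmath=True)
def batch_loglik(A, Bmat, t0, sv_t, vt_mat, vf_mat, rt, cond, correct,
                 pointwise, out_pw):
    """Summed (or pointwise) log-likelihood for m parameter vectors.

    A, t0, sv_t: (m,); Bmat, vt_mat, vf_mat: (m, 4); rt: (n,); cond:
    (n,) int; correct: (n,) bool.  Returns (m,) sums; fills ``out_pw``
    (m, n) when ``pointwise``.
    """
    m = A.shape[0]
    n = rt.shape[0]
    out = np.empty(m)
    zn_t = np.empty(4)
    zn_f = np.empty(4)
    for i in range(m):
        out[i] = _row_loglik(A[i], Bmat[i], t0[i], sv_t[i], vt_mat[i],
                             vf_mat[i], rt, cond, correct, 0, n,
                             pointwise, out_pw, i, zn_t, zn_f)
    return out


@njit(cache=True, fastmath=True)
def batch_loglik_stacked(A, Bmat, t0, sv_t, vt_mat, vf_mat, rt, cond,
                         correct, offsets, n_subj):
    """Summed log-likelihood for stacked (chain, subject) rows.

    Row ``r`` is chain ``r // n_subj``, subject ``r % n_subj``; subject
    ``s`` owns trials ``offsets[s]:offsets[s+1]`` of the concatenated
    arrays.  Returns (n_rows,).
    """
    n_rows = A.shape[0]
    out = np.empty(n_rows)
    zn_t = np.empty(4)
    zn_f = np.empty(4)
    dummy = np.empty((1, 1))
    for r in range(n_rows):
        s = r % n_subj
        out[r] = _row_loglik(A[r], Bmat[r], t0[r], sv_t[r], vt_mat[r],
                             vf_mat[r], rt, cond, correct,
                             offsets[s], offsets[s + 1], False, dummy, 0,
                             zn_t, zn_f)
    return out
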