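"""Numba-compiled fixed-step integrators for the DCM forward model.

The neural + hemodynamic system is integrated with classical RK4 at a
micro-time step (default TR/16).  The three strictly-positive
hemodynamic states (flow f, volume nu, deoxyhemoglobin q) are
propagated in log space so trajectories remain in the admissible domain
for any step size.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _full_drift(state, u, Aeff, Bp, Bn, C, kappa, gamma_h, tau, alpha, E0):
    """Derivative of the packed state (n_regions x 5: z, s, lf, lnu, lq)."""
    n = Aeff.shape[0]
    out = np.empty((n, 5))
    J = Aeff + u[1] * Bp + u[2] * Bn
    z = state[:, 0]
    for i in range(n):
        dz = 0.0
        for j in range(n):
            dz += J[i, j] * z[j]
        for k in range(C.shape[1]):
            dz += C[i, k] * u[k]
        s = state[i, 1]
        # smooth tanh saturation of the log states when evaluating
        # derivatives: keeps the exponentials bounded (no underflow, no
        # blow-up) while leaving the physiological regime |x| < ~4
        # essentially untouched and the objective differentiable
        lf = 8.0 * np.tanh(state[i, 2] / 8.0)
        lnu = 8.0 * np.tanh(state[i, 3] / 8.0)
        lq = 8.0 * np.tanh(state[i, 4] / 8.0)
        f = np.exp(lf)
        nu = np.exp(lnu)
        q = np.exp(lq)
        fv = nu ** (1.0 / alpha)
        ff = (1.0 - (1.0 - E0) ** (1.0 / f)) / E0
        out[i, 0] = dz
        out[i, 1] = z[i] - kappa * s - gamma_h * (f - 1.0)
        out[i, 2] = s / f
        out[i, 3] = (f - fv) / (tau[i] * nu)
        out[i, 4] = (f * ff - fv * q / nu) / (tau[i] * q)
    return out


@njit(cache=True)
def integrate_session(Aeff, Bp, Bn, C, U, dt, oversample, n_vol,
                      kappa, gamma_h, tau, alpha, E0, V0, k1, k2, k3):
    """Integrate the full model and sample BOLD once per volume.

    ``U`` is (n_vol * oversample, n_inputs) at micro-time.  BOLD is read
    out at the end of each block of ``oversample`` micro-steps.  Returns
    (n_vol, n_regions); raises no exceptions but returns NaN-free output
    only while states stay below 1e6 (caller checks).
    """
    n = Aeff.shape[0]
    state = np.zeros((n, 5))
    y = np.empty((n_vol, n))
    step = 0
    for vol in range(n_vol):
        for _ in range(oversample):
            u = U[step]
            k_1 = _full_drift(state, u, Aeff, Bp, Bn, C, kappa, gamma_h,
                              tau, alpha, E0)
            k_2 = _full_drift(state + 0.5 * dt * k_1, u, Aeff, Bp, Bn, C,
                              kappa, gamma_h, tau, alpha, E0)
            k_3 = _full_drift(state + 0.5 * dt * k_2, u, Aeff, Bp, Bn, C,
                              kappa, gamma_h, tau, alpha, E0)
            k_4 = _full_drift(state + dt * k_3, u, Aeff, Bp, Bn, C,
                              kappa, gamma_h, tau, alpha, E0)
            state = state + dt / 6.0 * (k_1 + 2.0 * k_2 + 2.0 * k_3 + k_4)
            # wide hard bounds on the stored states; the effective values
            # entering the dynamics saturate smoothly well before these
            for i in range(n):
                if state[i, 1] > 50.0:
                    state[i, 1] = 50.0
                elif state[i, 1] < -50.0:
                    state[i, 1] = -50.0
                for j in range(2, 5):
                    if state[i, j] > 16.0:
                        state[i, j] = 16.0
                    elif state[i, j] < -16.0:
                        state[i, j] = -16.0
            step += 1
        for i in range(n):
            nu = np.exp(state[i, 3])
            q = np.exp(state[i, 4])
            y[vol, i] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / nu)
                              + k3 * (1.0 - nu))
        # instability guard: report via huge values, caller raises
        for i in range(n):
            if np.abs(state[i, 0]) > 1e6:
                y[vol, i] = np.inf
    return y


@njit(cache=True)
def integrate_neural(Aeff, Bp, Bn, C, U, dt):
    """Neural states only, returned at every micro-step (nt, n_regions)."""
    n = Aeff.shape[0]
    nt = U.shape[0]
    z = np.zeros(n)
    out = np.empty((nt, n))
    for t in range(nt):
        u = U[t]
        J = Aeff + u[1] * Bp + u[2] * Bn
        k1v = J @ z + C @ u
        k2v = J @ (z + 0.5 * dt * k1v) + C @ u
        k3v = J @ (z + 0.5 * dt * k2v) + C @ u
        k4v = J @ (z + dt * k3v) + C @ u
        z = z + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        out[t] = z
    return out
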