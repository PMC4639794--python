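"""Numba Gibbs sampler for the stochastic Gompertz state-space model.

Process:      x_{t+1} = x_t + r - b*x_t + c*z_t + eps_t,  eps ~ N(0, tau^2)
Observation:  y_t     = x_t + eta_t,                      eta ~ N(0, sigma^2)

Sampler sweeps:
  1. latent states by forward-filter backward-sample (Kalman/FFBS; the
     model is conditionally linear-Gaussian given the parameters);
  2. (r, b, c) jointly from their conjugate Gaussian conditional — the
     state increments form a linear regression on [1, -x_t, z_t];
  3. tau and sigma from truncated inverse-gamma conditionals implied by
     the flat Uniform(0, sd_max) priors on the standard deviations.

Standard deviations are floored at 1e-4 so the filter stays defined on
noise-free (degenerate) inputs.
"""

import numpy as np
from numba import njit

SD_FLOOR = 1.0e-4


@njit(cache=True)
def _trunc_invgamma_sd(shape, rate, sd_max):
    """Draw sd with sd^2 ~ InvGamma(shape, rate) truncated to sd < sd_max."""
    for _ in range(200):
        prec = np.random.gamma(shape, 1.0 / rate)
        var = 1.0 / prec
        if var < sd_max * sd_max:
            sd = np.sqrt(var)
            return sd if sd > SD_FLOOR else SD_FLOOR
    # overwhelming posterior mass beyond the bound: park just inside it
    return sd_max * (1.0 - 1.0e-6 * np.random.random())


@njit(cache=True)
def gompertz_gibbs(y, z, n_iter, burn, seed,
                   prior_r_mean, prior_r_sd, prior_bc_sd, sd_max,
                   x1_prior_var):
    """One chain; returns draws array (n_iter, 5 + T): r, b, c, tau, sigma, x."""
    np.random.seed(seed)
    T = y.shape[0]
    x = y.copy()
    r = prior_r_mean
    b = 0.0
    c = 0.0
    tau = 0.1
    sigma = 0.1
    out = np.empty((n_iter, 5 + T))

    m = np.empty(T)
    P = np.empty(T)
    a_pred = np.empty(T)
    R_pred = np.empty(T)

    prior_r_prec = 1.0 / (prior_r_sd * prior_r_sd)
    prior_bc_prec = 1.0 / (prior_bc_sd * prior_bc_sd)

    for it in range(n_iter + burn):
        tau2 = tau * tau
        sig2 = sigma * sigma
        phi = 1.0 - b

        # --- forward filter ---
        # prior x1 ~ N(y1, x1_prior_var), updated with the observation y1
        R_pred[0] = x1_prior_var
        a_pred[0] = y[0]
        K = R_pred[0] / (R_pred[0] + sig2)
        m[0] = a_pred[0] + K * (y[0] - a_pred[0])
        P[0] = (1.0 - K) * R_pred[0]
        for t in range(1, T):
            a_pred[t] = r + c * z[t - 1] + phi * m[t - 1]
            R_pred[t] = phi * phi * P[t - 1] + tau2
            F = R_pred[t] + sig2
            K = R_pred[t] / F
            m[t] = a_pred[t] + K * (y[t] - a_pred[t])
            P[t] = (1.0 - K) * R_pred[t]

        # --- backward sample ---
        x[T - 1] = m[T - 1] + np.sqrt(max(P[T - 1], 1e-14)) * np.random.normal()
        for t in range(T - 2, -1, -1):
            G = phi * P[t] / max(R_pred[t + 1], 1e-14)
            mean = m[t] + G * (x[t + 1] - a_pred[t + 1])
            var = P[t] - G * phi * P[t]
            x[t] = mean + np.sqrt(max(var, 1e-14)) * np.random.normal()

        # --- (r, b, c) regression update ---
        # d_t = x_{t+1} - x_t = r - b*x_t + c*z_t + eps_t
        A = np.zeros((3, 3))
        v = np.zeros(3)
        for t in range(T - 1):
            w0 = 1.0
            w1 = -x[t]
            w2 = z[t]
            d = x[t + 1] - x[t]
            A[0, 0] += w0 * w0
            A[0, 1] += w0 * w1
            A[0, 2] += w0 * w2
            A[1, 1] += w1 * w1
            A[1, 2] += w1 * w2
            A[2, 2] += w2 * w2
            v[0] += w0 * d
            v[1] += w1 * d
            v[2] += w2 * d
        A[1, 0] = A[0, 1]
        A[2, 0] = A[0, 2]
        A[2, 1] = A[1, 2]
        A /= tau2
        v /= tau2
        A[0, 0] += prior_r_prec
        A[1, 1] += prior_bc_prec
        A[2, 2] += prior_bc_prec
        v[0] += prior_r_prec * prior_r_mean
        mean_theta = np.linalg.solve(A, v)
        # sample theta ~ N(mean, A^{-1}) via Cholesky of the precision
        L = np.linalg.cholesky(A)
        eps = np.random.normal(0.0, 1.0, 3)
        # solve L^T u = eps  =>  u ~ N(0, A^{-1})
        u = np.empty(3)
        for i in range(2, -1, -1):
            s = eps[i]
            for j in range(i + 1, 3):
                s -= L[j, i] * u[j]
            u[i] = s / L[i, i]
        r = mean_theta[0] + u[0]
        b = mean_theta[1] + u[1]
        c = mean_theta[2] + u[2]

        # --- tau ---
        ss = 0.0
        for t in range(T - 1):
            e = x[t + 1] - x[t] - (r - b * x[t] + c * z[t])
            ss += e * e
        tau = _trunc_invgamma_sd(0.5 * (T - 2), 0.5 * ss + 1e-12, sd_max)

        # --- sigma ---
        ss = 0.0
        for t in range(T):
            e = y[t] - x[t]
            ss += e * e
        sigma = _trunc_invgamma_sd(0.5 * (T - 1), 0.5 * ss + 1e-12, sd_max)

        if it >= burn:
            j = it - burn
            out[j, 0] = r
            out[j, 1] = b
            out[j, 2] = c
            out[j, 3] = tau
            out[j, 4] = sigma
            out[j, 5:] = x
    return out
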