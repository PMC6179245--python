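"""Numba kernel for the hierarchical site-use sampler.

One compiled function runs a single chain of the Metropolis-within-Gibbs
sampler.  The detection model depends only on the station's trail type,
so the detection likelihood collapses to per-trail sufficient statistics
(detections and observed occasions summed over currently-used sites);
each scan is O(n_sites).

Update scheme per scan:

* latent use Z: exact Gibbs (forced to 1 at detected sites);
* area intercepts: random-walk Metropolis with Normal(mu, tau^2) prior;
* mu: conjugate Gibbs given the area intercepts (or Metropolis on the
  occupancy likelihood when the random intercept is disabled, tau = 0);
* tau: random-walk Metropolis, Uniform(0, tau_max) prior on the SD scale;
* inclusion indicators w: exact Gibbs (Kuo-Mallick - the effective
  coefficient is w*alpha, and alpha is refreshed from its uniform prior
  whenever its indicator is off);
* slopes and detection coefficients: random-walk Metropolis inside their
  uniform prior bounds.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in only
and are frozen afterwards, preserving detailed balance for the retained
draws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain", "param_layout"]


def param_layout(n_areas: int, n_cov: int, n_contrast: int):
    """Column layout of the kernel's output draw matrix."""
    names = [f"alpha_area[{a}]" for a in range(n_areas)]
    names += ["mu", "tau"]
    names += [f"alpha[{c}]" for c in range(n_cov)]
    names += [f"w[{c}]" for c in range(n_cov)]
    names += ["beta0"]
    names += [f"beta[{t}]" for t in range(n_contrast)]
    names += [f"w_beta[{t}]" for t in range(n_contrast)]
    names += ["n_sites_used"]
    return names


@njit(cache=True)
def _log1pexp(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def _occ_loglik(eta, Z):
    ll = 0.0
    for i in range(eta.shape[0]):
        if Z[i] == 1:
            ll -= _log1pexp(-eta[i])
        else:
            ll -= _log1pexp(eta[i])
    return ll


@njit(cache=True)
def _det_loglik(beta0, beta_t, w_t, sd_t, sm_t):
    # sd_t[t]: detections, sm_t[t]: non-detection occasions, over used sites
    ll = 0.0
    for t in range(sd_t.shape[0]):
        lp = beta0
        if t > 0:
            lp += w_t[t - 1] * beta_t[t - 1]
        ll += -sd_t[t] * _log1pexp(-lp) - sm_t[t] * _log1pexp(lp)
    return ll


@njit(cache=True)
def run_chain(seed, n_iter, burn_in, thin,
              x, area_idx, trail_idx, n_areas, n_trail,
              m, d, det,
              coef_low, coef_high, mu_loc, mu_scale, tau_max,
              incl_prior, incl_prior_det, select_occ, select_det,
              mu_fixed_flag, mu_fixed_val, tau_fixed_flag, tau_fixed_val):
    np.random.seed(seed)
    n = x.shape[0]
    C = x.shape[1]
    Tm1 = n_trail - 1

    # --- init ------------------------------------------------------------
    if mu_fixed_flag:
        mu = mu_fixed_val
    else:
        mu = mu_loc + np.random.normal()
    if tau_fixed_flag:
        tau = tau_fixed_val
    else:
        tau = 0.5 + np.random.random()
    alpha_area = np.empty(n_areas)
    for a in range(n_areas):
        if tau > 0.0:
            alpha_area[a] = mu + np.random.normal() * max(tau, 0.1)
        else:
            alpha_area[a] = mu
    alpha = np.empty(C)
    w = np.ones(C, dtype=np.int64)
    for c in range(C):
        alpha[c] = 0.5 * np.random.normal()
    beta0 = 0.5 * np.random.normal()
    beta_t = np.empty(max(Tm1, 1))
    w_t = np.ones(max(Tm1, 1), dtype=np.int64)
    for t in range(Tm1):
        beta_t[t] = 0.5 * np.random.normal()
    Z = np.empty(n, dtype=np.int64)
    for i in range(n):
        Z[i] = 1 if (det[i] == 1 or np.random.random() < 0.5) else 0

    # effective occupancy linear predictor
    eta = np.empty(n)
    for i in range(n):
        e = alpha_area[area_idx[i]]
        for c in range(C):
            e += w[c] * alpha[c] * x[i, c]
        eta[i] = e

    # adaptive proposal scales
    s_area = np.full(n_areas, 0.5)
    s_mu = 0.5
    s_tau = 0.5
    s_alpha = np.full(C, 0.5)
    s_beta0 = 0.2
    s_beta = np.full(max(Tm1, 1), 0.3)
    a_area = np.zeros(n_areas)
    a_mu = 0.0
    a_tau = 0.0
    a_alpha = np.zeros(C)
    a_beta0 = 0.0
    a_beta = np.zeros(max(Tm1, 1))
    ADAPT_EVERY = 50
    TARGET = 0.44
    SC_LO, SC_HI = 1e-3, 50.0

    n_kept = (n_iter - burn_in + thin - 1) // thin
    P = n_areas + 2 + 2 * C + 1 + 2 * Tm1 + 1
    out = np.empty((n_kept, P))
    psi_sum = np.zeros(n)
    z_sum = np.zeros(n)
    kept = 0

    sd_t = np.zeros(n_trail)
    sm_t = np.zeros(n_trail)

    for it in range(n_iter):
        # --- detection probs per trail, for the Z update ----------------
        logq = np.empty(n_trail)   # log(1 - p) per trail
        for t in range(n_trail):
            lp = beta0
            if t > 0:
                lp += w_t[t - 1] * beta_t[t - 1]
            logq[t] = -_log1pexp(lp)

        # --- latent Z (Gibbs) -------------------------------------------
        for i in range(n):
            if det[i] == 1:
                Z[i] = 1
            else:
                psi = 1.0 / (1.0 + np.exp(-eta[i]))
                q = np.exp(m[i] * logq[trail_idx[i]])
                num = psi * q
                pz = num / (num + 1.0 - psi)
                Z[i] = 1 if np.random.random() < pz else 0

        # detection sufficient statistics over used sites
        for t in range(n_trail):
            sd_t[t] = 0.0
            sm_t[t] = 0.0
        for i in range(n):
            if Z[i] == 1:
                sd_t[trail_idx[i]] += d[i]
                sm_t[trail_idx[i]] += m[i] - d[i]

        # --- area intercepts --------------------------------------------
        if not (tau_fixed_flag and tau_fixed_val == 0.0):
            for a in range(n_areas):
                prop = alpha_area[a] + s_area[a] * np.random.normal()
                dl = 0.0
                for i in range(n):
                    if area_idx[i] == a:
                        e_new = eta[i] + (prop - alpha_area[a])
                        if Z[i] == 1:
                            dl += _log1pexp(-eta[i]) - _log1pexp(-e_new)
                        else:
                            dl += _log1pexp(eta[i]) - _log1pexp(e_new)
                if tau > 0.0:
                    dl += -0.5 * ((prop - mu) ** 2 - (alpha_area[a] - mu) ** 2) / (tau * tau)
                if np.log(np.random.random()) < dl:
                    delta = prop - alpha_area[a]
                    alpha_area[a] = prop
                    for i in range(n):
                        if area_idx[i] == a:
                            eta[i] += delta
                    a_area[a] += 1.0

        # --- mu ----------------------------------------------------------
        if not mu_fixed_flag:
            if tau_fixed_flag and tau_fixed_val == 0.0:
                # no random intercept: mu is the shared occupancy intercept
                prop = mu + s_mu * np.random.normal()
                dl = -0.5 * ((prop - mu_loc) ** 2 - (mu - mu_loc) ** 2) / (mu_scale**2)
                for i in range(n):
                    e_new = eta[i] + (prop - mu)
                    if Z[i] == 1:
                        dl += _log1pexp(-eta[i]) - _log1pexp(-e_new)
                    else:
                        dl += _log1pexp(eta[i]) - _log1pexp(e_new)
                if np.log(np.random.random()) < dl:
                    delta = prop - mu
                    mu = prop
                    for i in range(n):
                        eta[i] += delta
                    for a in range(n_areas):
                        alpha_area[a] = mu
                    a_mu += 1.0
            else:
                # conjugate Gibbs given area intercepts
                prec = n_areas / (tau * tau) + 1.0 / (mu_scale**2)
                s = 0.0
                for a in range(n_areas):
                    s += alpha_area[a]
                mean = (s / (tau * tau) + mu_loc / (mu_scale**2)) / prec
                mu = mean + np.random.normal() / np.sqrt(prec)

        # --- tau ---------------------------------------------------------
        if not tau_fixed_flag:
            prop = tau + s_tau * np.random.normal()
            if 0.0 < prop <= tau_max:
                dl = 0.0
                for a in range(n_areas):
                    r = alpha_area[a] - mu
                    dl += (np.log(tau) - np.log(prop)
                           + 0.5 * r * r * (1.0 / (tau * tau) - 1.0 / (prop * prop)))
                if np.log(np.random.random()) < dl:
                    tau = prop
                    a_tau += 1.0

        # --- inclusion indicators and slopes -----------------------------
        for c in range(C):
            if select_occ:
                # Gibbs for w_c given alpha_c: compare eta with/without term
                ll_cur = _occ_loglik(eta, Z)
                eta_alt = eta.copy()
                if w[c] == 1:
                    for i in range(n):
                        eta_alt[i] -= alpha[c] * x[i, c]
                    ll0, ll1 = _occ_loglik(eta_alt, Z), ll_cur
                else:
                    for i in range(n):
                        eta_alt[i] += alpha[c] * x[i, c]
                    ll0, ll1 = ll_cur, _occ_loglik(eta_alt, Z)
                logit_p1 = np.log(incl_prior) - np.log(1.0 - incl_prior) + ll1 - ll0
                new_w = 1 if np.random.random() < 1.0 / (1.0 + np.exp(-logit_p1)) else 0
                if new_w != w[c]:
                    sgn = 1.0 if new_w == 1 else -1.0
                    for i in range(n):
                        eta[i] += sgn * alpha[c] * x[i, c]
                    w[c] = new_w
            if w[c] == 1:
                # mixture kernel: mostly random-walk, sometimes an
                # independence proposal from the prior (helps mixing when
                # the slope is weakly identified)
                indep = np.random.random() < 0.2
                if indep:
                    prop = coef_low + np.random.random() * (coef_high - coef_low)
                else:
                    prop = alpha[c] + s_alpha[c] * np.random.normal()
                if coef_low <= prop <= coef_high:
                    dl = 0.0
                    for i in range(n):
                        e_new = eta[i] + (prop - alpha[c]) * x[i, c]
                        if Z[i] == 1:
                            dl += _log1pexp(-eta[i]) - _log1pexp(-e_new)
                        else:
                            dl += _log1pexp(eta[i]) - _log1pexp(e_new)
                    if np.log(np.random.random()) < dl:
                        for i in range(n):
                            eta[i] += (prop - alpha[c]) * x[i, c]
                        alpha[c] = prop
                        if not indep:
                            a_alpha[c] += 1.0
            else:
                # indicator off: coefficient refreshes from its prior
                alpha[c] = coef_low + np.random.random() * (coef_high - coef_low)

        # --- detection intercept -----------------------------------------
        prop = beta0 + s_beta0 * np.random.normal()
        if coef_low <= prop <= coef_high:
            dl = (_det_loglik(prop, beta_t, w_t, sd_t, sm_t)
                  - _det_loglik(beta0, beta_t, w_t, sd_t, sm_t))
            if np.log(np.random.random()) < dl:
                beta0 = prop
                a_beta0 += 1.0

        # --- trail contrasts ---------------------------------------------
        for t in range(Tm1):
            if select_det:
                w_t[t] = 1
                ll1 = _det_loglik(beta0, beta_t, w_t, sd_t, sm_t)
                w_t[t] = 0
                ll0 = _det_loglik(beta0, beta_t, w_t, sd_t, sm_t)
                logit_p1 = (np.log(incl_prior_det) - np.log(1.0 - incl_prior_det)
                            + ll1 - ll0)
                w_t[t] = 1 if np.random.random() < 1.0 / (1.0 + np.exp(-logit_p1)) else 0
            if w_t[t] == 1:
                indep = np.random.random() < 0.2
                if indep:
                    prop = coef_low + np.random.random() * (coef_high - coef_low)
                else:
                    prop = beta_t[t] + s_beta[t] * np.random.normal()
                if coef_low <= prop <= coef_high:
                    old = beta_t[t]
                    ll_old = _det_loglik(beta0, beta_t, w_t, sd_t, sm_t)
                    beta_t[t] = prop
                    ll_new = _det_loglik(beta0, beta_t, w_t, sd_t, sm_t)
                    if np.log(np.random.random()) < ll_new - ll_old:
                        if not indep:
                            a_beta[t] += 1.0
                    else:
                        beta_t[t] = old
            else:
                beta_t[t] = coef_low + np.random.random() * (coef_high - coef_low)

        # --- adaptation (burn-in only) -----------------------------------
        if it < burn_in and (it + 1) % ADAPT_EVERY == 0:
            for a in range(n_areas):
                s_area[a] = min(max(s_area[a] * np.exp(a_area[a] / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
                a_area[a] = 0.0
            s_mu = min(max(s_mu * np.exp(a_mu / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
            a_mu = 0.0
            s_tau = min(max(s_tau * np.exp(a_tau / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
            a_tau = 0.0
            for c in range(C):
                s_alpha[c] = min(max(s_alpha[c] * np.exp(a_alpha[c] / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
                a_alpha[c] = 0.0
            s_beta0 = min(max(s_beta0 * np.exp(a_beta0 / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
            a_beta0 = 0.0
            for t in range(Tm1):
                s_beta[t] = min(max(s_beta[t] * np.exp(a_beta[t] / ADAPT_EVERY - TARGET), SC_LO), SC_HI)
                a_beta[t] = 0.0

        # --- periodic eta refresh against float drift --------------------
        if (it + 1) % 1000 == 0:
            for i in range(n):
                e = alpha_area[area_idx[i]]
                for c in range(C):
                    e += w[c] * alpha[c] * x[i, c]
                eta[i] = e

        # --- record -------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            col = 0
            for a in range(n_areas):
                out[kept, col] = alpha_area[a]
                col += 1
            out[kept, col] = mu
            col += 1
            out[kept, col] = tau
            col += 1
            for c in range(C):
                out[kept, col] = alpha[c]
                col += 1
            for c in range(C):
                out[kept, col] = w[c]
                col += 1
            out[kept, col] = beta0
            col += 1
            for t in range(Tm1):
                out[kept, col] = beta_t[t]
                col += 1
            for t in range(Tm1):
                out[kept, col] = w_t[t]
                col += 1
            nz = 0
            for i in range(n):
                psi_sum[i] += 1.0 / (1.0 + np.exp(-eta[i]))
                z_sum[i] += Z[i]
                nz += Z[i]
            out[kept, col] = nz
            kept += 1

    return out, psi_sum / max(kept, 1), z_sum / max(kept, 1)
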