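"""Compiled numerical kernels (numba).

The population-estimation, bootstrap and VPC loops need on the order of 1e5-1e6
solutions of the 3-state QSS TMDD system, where the per-call overhead of a
generic solver dominates.  This module provides a jitted Dormand-Prince 5(4)
adaptive integrator specialized to the model, plus the per-subject Laplace
machinery (residuals, Gauss-Newton mode search over the two random effects).

Parameter vectors are packed float64 arrays in the order defined by
``model_core.STRUCTURAL_ORDER``:

    0 CL, 1 V1, 2 V2, 3 Q, 4 Kss, 5 kint, 6 Rtot, 7 Rtotp,
    8 kout, 9 Smax, 10 S50, 11 gamma

Accuracy is cross-checked in the test suite against scipy's LSODA and against
the closed-form biexponential infusion solution in the linear limit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector
iCL, iV1, iV2, iQ, iKSS, iKINT, iRTOT, iRTOTP, iKOUT, iSMAX, iS50, iGAMMA = range(12)

MAX_STEPS = 200_000
_LOG_FLOOR = -60.0  # floor on log-concentration (~1e-26 mg/L) to avoid -inf


@njit(cache=True, fastmath=False)
def _rhs(y, th, rate, dy):
    A1 = y[0]
    A2 = y[1]
    A3 = y[2]
    V1 = th[iV1]
    V2 = th[iV2]
    Q = th[iQ]
    Kss = th[iKSS]
    C1 = A1 / V1
    if C1 < 0.0:
        C1 = 0.0
    C2 = A2 / V2
    if C2 < 0.0:
        C2 = 0.0
    d1 = 1.0 + th[iRTOT] * Kss / ((Kss + C1) * (Kss + C1))
    d2 = 1.0 + th[iRTOTP] * Kss / ((Kss + C2) * (Kss + C2))
    dy[0] = (rate - (th[iCL] * A3 / V1 + Q / V1) * A1 + (Q / V2) * A2
             - th[iKINT] * th[iRTOT] * A1 / (Kss + C1)) / d1
    dy[1] = ((Q / V1) * A1 - (Q / V2) * A2) / d2
    if th[iSMAX] == 0.0 or C1 == 0.0:
        stim = 0.0
    else:
        g = th[iGAMMA]
        cg = C1 ** g
        stim = th[iSMAX] * cg / (th[iS50] ** g + cg)
    dy[2] = th[iKOUT] * (1.0 + stim) - th[iKOUT] * A3


@njit(cache=True)
def _integrate_segment(th, rate, t0, t1, y, t_out, y_out, iout, rtol, atol):
    """Advance y from t0 to t1 (constant infusion rate), filling y_out for all
    t_out in (t0, t1].  Returns (next output index, ok flag)."""
    n_out = t_out.shape[0]
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    k5 = np.empty(3)
    k6 = np.empty(3)
    k7 = np.empty(3)
    ytmp = np.empty(3)
    ynew = np.empty(3)

    t = t0
    span = t1 - t0
    if span <= 0.0:
        while iout < n_out and t_out[iout] <= t1 + 1e-12:
            for j in range(3):
                y_out[iout, j] = y[j]
            iout += 1
        return iout, True

    _rhs(y, th, rate, k1)  # FSAL seed
    h = span * 1e-3
    if h > 1.0:
        h = 1.0
    nsteps = 0
    while t < t1 - 1e-12:
        nsteps += 1
        if nsteps > MAX_STEPS:
            return iout, False
        if t + h > t1:
            h = t1 - t
        # clamp to next requested output time
        if iout < n_out and t_out[iout] > t + 1e-14 and t_out[iout] < t + h:
            h = t_out[iout] - t

        # Dormand-Prince 5(4) stages
        for j in range(3):
            ytmp[j] = y[j] + h * (0.2 * k1[j])
        _rhs(ytmp, th, rate, k2)
        for j in range(3):
            ytmp[j] = y[j] + h * (3.0 / 40.0 * k1[j] + 9.0 / 40.0 * k2[j])
        _rhs(ytmp, th, rate, k3)
        for j in range(3):
            ytmp[j] = y[j] + h * (44.0 / 45.0 * k1[j] - 56.0 / 15.0 * k2[j]
                                  + 32.0 / 9.0 * k3[j])
        _rhs(ytmp, th, rate, k4)
        for j in range(3):
            ytmp[j] = y[j] + h * (19372.0 / 6561.0 * k1[j] - 25360.0 / 2187.0 * k2[j]
                                  + 64448.0 / 6561.0 * k3[j] - 212.0 / 729.0 * k4[j])
        _rhs(ytmp, th, rate, k5)
        for j in range(3):
            ytmp[j] = y[j] + h * (9017.0 / 3168.0 * k1[j] - 355.0 / 33.0 * k2[j]
                                  + 46732.0 / 5247.0 * k3[j] + 49.0 / 176.0 * k4[j]
                                  - 5103.0 / 18656.0 * k5[j])
        _rhs(ytmp, th, rate, k6)
        for j in range(3):
            ynew[j] = y[j] + h * (35.0 / 384.0 * k1[j] + 500.0 / 1113.0 * k3[j]
                                  + 125.0 / 192.0 * k4[j] - 2187.0 / 6784.0 * k5[j]
                                  + 11.0 / 84.0 * k6[j])
        _rhs(ynew, th, rate, k7)

        # embedded error estimate
        err = 0.0
        for j in range(3):
            e = h * (71.0 / 57600.0 * k1[j] - 71.0 / 16695.0 * k3[j]
                     + 71.0 / 1920.0 * k4[j] - 17253.0 / 339200.0 * k5[j]
                     + 22.0 / 525.0 * k6[j] - 1.0 / 40.0 * k7[j])
            ay = abs(y[j])
            ayn = abs(ynew[j])
            sc = atol + rtol * (ay if ay > ayn else ayn)
            err += (e / sc) * (e / sc)
        err = np.sqrt(err / 3.0)

        if err <= 1.0 or h <= 1e-12:
            t_new = t + h
            # record any requested outputs at the step end
            while iout < n_out and t_out[iout] <= t_new + 1e-12 and t_out[iout] <= t1 + 1e-12:
                for j in range(3):
                    y_out[iout, j] = ynew[j]
                iout += 1
            t = t_new
            for j in range(3):
                y[j] = ynew[j]
                k1[j] = k7[j]  # FSAL
            if err == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h *= fac
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            h *= fac
            _rhs(y, th, rate, k1)  # k1 unchanged in principle; recompute for safety
    return iout, True


@njit(cache=True)
def solve_piecewise(th, seg_bounds, seg_rates, t_out, rtol, atol):
    """Integrate from rest over piecewise-constant infusion segments.

    seg_bounds: (m+1,) increasing times, seg_bounds[0] == 0.
    seg_rates: (m,) infusion rate on each segment, mg/h.
    t_out: sorted requested output times within [0, seg_bounds[-1]].

    Returns (y_out (n,3), ok).
    """
    n_out = t_out.shape[0]
    y_out = np.empty((n_out, 3))
    y = np.empty(3)
    y[0] = 0.0
    y[1] = 0.0
    y[2] = 1.0
    iout = 0
    while iout < n_out and t_out[iout] <= 0.0:
        y_out[iout, 0] = 0.0
        y_out[iout, 1] = 0.0
        y_out[iout, 2] = 1.0
        iout += 1
    ok = True
    for s in range(seg_rates.shape[0]):
        iout, ok = _integrate_segment(th, seg_rates[s], seg_bounds[s],
                                      seg_bounds[s + 1], y, t_out, y_out, iout,
                                      rtol, atol)
        if not ok:
            break
    return y_out, ok


@njit(cache=True)
def total_conc_from_a1(a1, th):
    """Total central concentration (free + complex) from free amounts."""
    n = a1.shape[0]
    out = np.empty(n)
    for i in range(n):
        c = a1[i] / th[iV1]
        if c < 0.0:
            c = 0.0
        out[i] = c + th[iRTOT] * c / (th[iKSS] + c)
    return out


@njit(cache=True)
def predict_log_total(th, seg_bounds, seg_rates, t_obs, rtol, atol):
    """log total central concentration at observation times (floored)."""
    y_out, ok = solve_piecewise(th, seg_bounds, seg_rates, t_obs, rtol, atol)
    n = t_obs.shape[0]
    out = np.empty(n)
    for i in range(n):
        c = y_out[i, 0] / th[iV1]
        if c < 0.0:
            c = 0.0
        ctot = c + th[iRTOT] * c / (th[iKSS] + c)
        if ctot <= 0.0:
            out[i] = _LOG_FLOOR
        else:
            lc = np.log(ctot)
            out[i] = lc if lc > _LOG_FLOOR else _LOG_FLOOR
    return out, ok


@njit(cache=True)
def _eta_log_pred(th_subj, eta1, eta2, seg_bounds, seg_rates, t_obs, rtol, atol):
    th = th_subj.copy()
    th[iRTOTP] = th_subj[iRTOTP] * np.exp(eta1)
    th[iKOUT] = th_subj[iKOUT] * np.exp(eta2)
    return predict_log_total(th, seg_bounds, seg_rates, t_obs, rtol, atol)


@njit(cache=True)
def laplace_subject(th_subj, seg_bounds, seg_rates, t_obs, log_y, sigma,
                    om1, om2, eta_init, rtol, atol, max_iter, gtol):
    """-2 log marginal likelihood contribution of one subject (Laplace).

    Random effects: eta1 on Rtotp, eta2 on kout (log-normal).  The mode is
    located by damped Gauss-Newton with forward-difference Jacobians of the
    log-prediction; the Laplace curvature uses the same Gauss-Newton Hessian
    J'J/sigma^2 + Omega^-1.

    Returns (neg2ll, eta1, eta2, ok).
    """
    n = t_obs.shape[0]
    s2 = sigma * sigma
    w1 = 1.0 / (om1 * om1)
    w2 = 1.0 / (om2 * om2)
    e1 = eta_init[0]
    e2 = eta_init[1]
    d = 1e-3  # FD step on eta; keeps Jacobian noise well below the gradient tol

    f, ok = _eta_log_pred(th_subj, e1, e2, seg_bounds, seg_rates, t_obs, rtol, atol)
    if not ok:
        return np.inf, e1, e2, False
    obj = 0.0
    for i in range(n):
        r = log_y[i] - f[i]
        obj += r * r
    obj = obj / s2 + e1 * e1 * w1 + e2 * e2 * w2

    lam = 1e-3   # Levenberg-Marquardt damping, carried across iterations
    h11 = 0.0
    h12 = 0.0
    h22 = 0.0
    for it in range(max_iter):
        f1, ok1 = _eta_log_pred(th_subj, e1 + d, e2, seg_bounds, seg_rates,
                                t_obs, rtol, atol)
        f2, ok2 = _eta_log_pred(th_subj, e1, e2 + d, seg_bounds, seg_rates,
                                t_obs, rtol, atol)
        if not (ok1 and ok2):
            return np.inf, e1, e2, False
        g1 = e1 * w1
        g2 = e2 * w2
        h11 = w1
        h12 = 0.0
        h22 = w2
        for i in range(n):
            j1 = (f1[i] - f[i]) / d
            j2 = (f2[i] - f[i]) / d
            r = log_y[i] - f[i]
            g1 -= j1 * r / s2
            g2 -= j2 * r / s2
            h11 += j1 * j1 / s2
            h12 += j1 * j2 / s2
            h22 += j2 * j2 / s2
        gnorm = np.sqrt(g1 * g1 + g2 * g2)
        if gnorm < gtol:
            break
        # Levenberg-Marquardt step with persistent damping
        accepted = False
        de1 = 0.0
        de2 = 0.0
        for _trial in range(10):
            # Marquardt scaling: damp each coordinate relative to its own
            # curvature so wildly different eta scales stay balanced
            a11 = h11 * (1.0 + lam)
            a22 = h22 * (1.0 + lam)
            det = a11 * a22 - h12 * h12
            if det <= 0.0:
                lam = 4.0 * lam
                continue
            de1 = -(a22 * g1 - h12 * g2) / det
            de2 = -(-h12 * g1 + a11 * g2) / det
            ne1 = e1 + de1
            ne2 = e2 + de2
            fn, okn = _eta_log_pred(th_subj, ne1, ne2, seg_bounds, seg_rates,
                                    t_obs, rtol, atol)
            if okn:
                nobj = 0.0
                for i in range(n):
                    r = log_y[i] - fn[i]
                    nobj += r * r
                nobj = nobj / s2 + ne1 * ne1 * w1 + ne2 * ne2 * w2
                if nobj <= obj + 1e-9 * (1.0 + abs(obj)):
                    e1 = ne1
                    e2 = ne2
                    obj = nobj
                    for i in range(n):
                        f[i] = fn[i]
                    accepted = True
                    lam = lam / 3.0
                    if lam < 1e-8:
                        lam = 1e-8
                    break
            lam = 4.0 * lam
        if not accepted:
            break
        if np.sqrt(de1 * de1 + de2 * de2) < 1e-5:
            # refresh curvature at the final point before exiting
            f1, ok1 = _eta_log_pred(th_subj, e1 + d, e2, seg_bounds, seg_rates,
                                    t_obs, rtol, atol)
            f2, ok2 = _eta_log_pred(th_subj, e1, e2 + d, seg_bounds, seg_rates,
                                    t_obs, rtol, atol)
            if ok1 and ok2:
                h11 = w1
                h12 = 0.0
                h22 = w2
                for i in range(n):
                    j1 = (f1[i] - f[i]) / d
                    j2 = (f2[i] - f[i]) / d
                    h11 += j1 * j1 / s2
                    h12 += j1 * j2 / s2
                    h22 += j2 * j2 / s2
            break

    det_h = h11 * h22 - h12 * h12
    if det_h <= 0.0:
        det_h = 1e-300
    # -2 log L = n log(2 pi s2) + SSR/s2 + eta' Om^-1 eta + log|Om| + log|H|
    ssr_term = 0.0
    for i in range(n):
        r = log_y[i] - f[i]
        ssr_term += r * r
    neg2ll = (n * np.log(2.0 * np.pi * s2) + ssr_term / s2
              + e1 * e1 * w1 + e2 * e2 * w2
              + np.log(om1 * om1) + np.log(om2 * om2) + np.log(det_h))
    return neg2ll, e1, e2, True


@njit(cache=True)
def individual_neg2ll_kernel(th_ind, seg_bounds, seg_rates, t_obs, log_y,
                             sigma, rtol, atol):
    """-2 log likelihood at fixed individual parameters (no random effects)."""
    f, ok = predict_log_total(th_ind, seg_bounds, seg_rates, t_obs, rtol, atol)
    if not ok:
        return np.inf, False
    s2 = sigma * sigma
    n = t_obs.shape[0]
    total = 0.0
    for i in range(n):
        r = log_y[i] - f[i]
        total += np.log(2.0 * np.pi * s2) + r * r / s2
    return total, True
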