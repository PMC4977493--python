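"""Compiled fixed-step RK4 kernel for the delayed three-oscillator network.

Delayed phases are obtained by cubic Hermite interpolation of the stored
trajectory (values + derivatives at the grid nodes).  For query times at or
before t = 0 the initial history is used: ``theta_i(t) = theta_i(0) +
hr_i * t`` with history rates ``hr`` (all zero for the standard constant
history; equal to the collective frequency when seeding a phase-locked
configuration).

The step-size precondition ``h <= tau / 10`` guarantees every delayed stage
time lies at least nine steps in the past, so the interpolation never reads
nodes that have not been computed yet.
"""

import numpy as np
from numba import njit

__all__ = ["integrate_core"]


@njit(cache=True, fastmath=False)
def _interp1(theta, f, h, tq, col, theta0, hr):
    """Cubic Hermite interpolation of phase component `col` at time `tq`."""
    if tq <= 0.0:
        return theta0[col] + hr[col] * tq
    j = int(tq / h)
    s = (tq - j * h) / h
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    return (
        h00 * theta[j, col]
        + h10 * h * f[j, col]
        + h01 * theta[j + 1, col]
        + h11 * h * f[j + 1, col]
    )


@njit(cache=True, fastmath=False)
def integrate_core(w1, w2, w3, k1, k2, tau, visual_leads, theta0, hr, h, n):
    """Integrate n fixed RK4 steps of size h; returns (theta, f), each (n+1, 3)."""
    theta = np.empty((n + 1, 3))
    f = np.empty((n + 1, 3))
    theta[0, 0] = theta0[0]
    theta[0, 1] = theta0[1]
    theta[0, 2] = theta0[2]
    delayed = tau > 0.0
    # delayed components: visual_leads -> (theta2, theta3) = cols (1, 2)
    #                     auditory_leads -> (theta1, theta3) = cols (0, 2)
    ca = 1 if visual_leads else 0  # non-AV node whose delayed phase AV sees
    for i in range(n + 1):
        t = i * h
        if i > 0:
            # RK4 step from node i-1 to node i
            tp = (i - 1) * h
            y1 = theta[i - 1, 0]
            y2 = theta[i - 1, 1]
            y3 = theta[i - 1, 2]
            a1, a2, a3 = _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca,
                              delayed, theta, f, h, theta0, hr, tp, y1, y2, y3)
            b1, b2, b3 = _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca,
                              delayed, theta, f, h, theta0, hr, tp + 0.5 * h,
                              y1 + 0.5 * h * a1, y2 + 0.5 * h * a2, y3 + 0.5 * h * a3)
            c1, c2, c3 = _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca,
                              delayed, theta, f, h, theta0, hr, tp + 0.5 * h,
                              y1 + 0.5 * h * b1, y2 + 0.5 * h * b2, y3 + 0.5 * h * b3)
            d1, d2, d3 = _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca,
                              delayed, theta, f, h, theta0, hr, tp + h,
                              y1 + h * c1, y2 + h * c2, y3 + h * c3)
            theta[i, 0] = y1 + h / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
            theta[i, 1] = y2 + h / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
            theta[i, 2] = y3 + h / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3 + d3)
        e1, e2, e3 = _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca,
                          delayed, theta, f, h, theta0, hr, t,
                          theta[i, 0], theta[i, 1], theta[i, 2])
        f[i, 0] = e1
        f[i, 1] = e2
        f[i, 2] = e3
    return theta, f


@njit(cache=True, fastmath=False)
def _rhs(w1, w2, w3, k1, k2, tau, visual_leads, ca, delayed,
         theta, f, h, theta0, hr, t, y1, y2, y3):
    """Right-hand side at state (y1, y2, y3), time t, using stored history."""
    if delayed:
        tq = t - tau
        d_other = _interp1(theta, f, h, tq, ca, theta0, hr)
        d_av = _interp1(theta, f, h, tq, 2, theta0, hr)
    else:
        d_other = y1 if ca == 0 else y2
        d_av = y3
    if visual_leads:
        r1 = w1 + k1 * np.sin(y3 - y1)
        r2 = w2 + k2 * np.sin(d_av - y2)
        r3 = w3 + k1 * np.sin(y1 - y3) + k2 * np.sin(d_other - y3)
    else:
        r1 = w1 + k1 * np.sin(d_av - y1)
        r2 = w2 + k2 * np.sin(y3 - y2)
        r3 = w3 + k1 * np.sin(d_other - y3) + k2 * np.sin(y2 - y3)
    return r1, r2, r3
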