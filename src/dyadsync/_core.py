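"""Numba kernels for the delay-coupled phase oscillator system.

Fixed-step explicit Euler on the phase equations with a linearly
interpolated delay buffer.  Phases are in radians, time in ms.  The
kernels are deliberately minimal: all bookkeeping (event readout,
noise generation, unit conversion) lives in the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def integrate_pair(
    omega1: float,
    omega2: float,
    k1: float,
    k2: float,
    tau1: float,
    tau2: float,
    cscale: float,
    th10: float,
    th20: float,
    dt: float,
    n_steps: int,
    period: float,
    eps1: np.ndarray,
    eps2: np.ndarray,
    delay_on_partner: bool,
):
    """Integrate two mutually delay-coupled oscillators.

    dθi/dt = 2π/ωi + ki * cscale * sin(θj_heard(t) − θi(t − τi))

    ``eps1``/``eps2`` hold per-tone onset jitter (ms) of each oscillator's
    emitted tones; the *partner* perceives a phase shifted by the jitter of
    the most recently sounded tone.  Pass zero arrays for the noise-free
    skeleton.  If ``delay_on_partner`` the delay is applied to the partner's
    phase instead of the oscillator's own past state.
    """
    th1 = np.empty(n_steps + 1)
    th2 = np.empty(n_steps + 1)
    th1[0] = th10
    th2[0] = th20
    v1 = TWO_PI / omega1
    v2 = TWO_PI / omega2
    om_ev = TWO_PI / period
    n_ev = eps1.shape[0]

    for i in range(n_steps):
        t = i * dt

        # own (or partner) state at t - tau, constant-velocity history for t<0
        td = t - tau1
        if td <= 0.0:
            d1 = th10 + td * v1
            d2p = th20 + td * v2
        else:
            j = td / dt
            j0 = int(j)
            f = j - j0
            if j0 + 1 > i:
                d1 = th1[i]
                d2p = th2[i]
            else:
                d1 = th1[j0] * (1.0 - f) + th1[j0 + 1] * f
                d2p = th2[j0] * (1.0 - f) + th2[j0 + 1] * f
        td = t - tau2
        if td <= 0.0:
            d2 = th20 + td * v2
            d1p = th10 + td * v1
        else:
            j = td / dt
            j0 = int(j)
            f = j - j0
            if j0 + 1 > i:
                d2 = th2[i]
                d1p = th1[i]
            else:
                d2 = th2[j0] * (1.0 - f) + th2[j0 + 1] * f
                d1p = th1[j0] * (1.0 - f) + th1[j0 + 1] * f

        # phase of the partner as heard: shifted by jitter of the latest tone
        m = int(t / period)
        if m >= n_ev:
            m = n_ev - 1
        heard2 = th2[i] - eps2[m] * om_ev
        heard1 = th1[i] - eps1[m] * om_ev

        if delay_on_partner:
            dth1 = v1 + k1 * cscale * np.sin((d2p - eps2[m] * om_ev) - th1[i])
            dth2 = v2 + k2 * cscale * np.sin((d1p - eps1[m] * om_ev) - th2[i])
        else:
            dth1 = v1 + k1 * cscale * np.sin(heard2 - d1)
            dth2 = v2 + k2 * cscale * np.sin(heard1 - d2)

        th1[i + 1] = th1[i] + dt * dth1
        th2[i + 1] = th2[i] + dt * dth2

    return th1, th2


@njit(cache=True, fastmath=True)
def integrate_driven(
    omega: float,
    k: float,
    tau: float,
    cscale: float,
    th0: float,
    dt: float,
    n_steps: int,
    theta_stim: np.ndarray,
):
    """Integrate one oscillator driven by a non-adapting stimulus phase.

    ``theta_stim[i]`` is the stimulus phase at step i (precomputed from the
    tone schedule).  The coupling law mirrors :func:`integrate_pair` with the
    delay on the responder's own past state.
    """
    th = np.empty(n_steps + 1)
    th[0] = th0
    v = TWO_PI / omega
    for i in range(n_steps):
        t = i * dt
        td = t - tau
        if td <= 0.0:
            d = th0 + td * v
        else:
            j = td / dt
            j0 = int(j)
            f = j - j0
            if j0 + 1 > i:
                d = th[i]
            else:
                d = th[j0] * (1.0 - f) + th[j0 + 1] * f
        th[i + 1] = th[i] + dt * (v + k * cscale * np.sin(theta_stim[i] - d))
    return th
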