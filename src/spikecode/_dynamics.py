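"""Compiled per-layer membrane dynamics.

The feedforward architecture has no synaptic delays, so for a given layer the
entire input-current time series is known before the layer is integrated.  The
inter-layer matrix products are therefore done as single BLAS calls elsewhere;
only the strictly sequential within-layer recursions live here, as numba
kernels that loop over time.

Alpha (spike-response) neuron, per step::

    E[t] = a * (1 - S[t-1]) * E[t-1] + C[t]     excitatory current trace
    I[t] = b * (1 - S[t-1]) * I[t-1] - C[t]     inhibitory current trace
    U[t] = tau * (E[t] + I[t])                  membrane potential
    S[t] = H(U[t] - theta)                      spike

Because the membrane potential of the alpha model is slaved to the two
current traces, clearing the traces on a spike is what actually realizes
"U is reset to U_reset = 0 on the step after threshold is crossed": with
E and I cleared, the next step gives E = C, I = -C and hence U = 0 exactly,
after which the membrane re-charges through the alpha kernel (an effective
recovery period).

LIF neuron, per step::

    V[t] = b * U[t-1] + C[t]
    U[t] = (1 - S[t-1]) * V[t]
    S[t] = H(U[t] - theta)

Here U is a genuine state variable, so the one-step multiplicative gate is
the standard differentiable reset-to-zero.  In
``smooth`` mode the Heaviside H is replaced by the fast-sigmoid relaxation
``0.5 * (1 + k*x / (1 + k*|x|))`` whose exact derivative is used in the
backward pass; this mode exists so the hand-derived gradients can be checked
against finite differences.  In hard mode spikes are binary and the backward
pass uses the fast-sigmoid surrogate derivative ``1 / (1 + k*|x|)**2``.
"""

import numpy as np
from numba import njit

__all__ = [
    "alpha_forward",
    "alpha_backward",
    "lif_forward",
    "lif_backward",
]


@njit(cache=True)
def _spike(x, slope, smooth):
    if smooth:
        return 0.5 * (1.0 + slope * x / (1.0 + slope * abs(x)))
    return 1.0 if x > 0.0 else 0.0


@njit(cache=True)
def _dspike(x, slope, smooth):
    d = 1.0 / (1.0 + slope * abs(x)) ** 2
    if smooth:
        return 0.5 * slope * d
    return d


@njit(cache=True)
def alpha_forward(C, a, b, tau, theta, slope, smooth):
    """Integrate one alpha-neuron layer.

    C : (T, n) input currents.  a, b, tau, theta : (n,) per-neuron parameters.
    Returns S, E, I, U, each (T, n).
    """
    T, n = C.shape
    S = np.zeros((T, n))
    E = np.zeros((T, n))
    I = np.zeros((T, n))
    U = np.zeros((T, n))
    for t in range(T):
        for j in range(n):
            if t == 0:
                e = C[t, j]
                i = -C[t, j]
            else:
                keep = 1.0 - S[t - 1, j]
                e = a[j] * keep * E[t - 1, j] + C[t, j]
                i = b[j] * keep * I[t - 1, j] - C[t, j]
            u = tau[j] * (e + i)
            E[t, j] = e
            I[t, j] = i
            U[t, j] = u
            S[t, j] = _spike(u - theta[j], slope, smooth)
    return S, E, I, U


@njit(cache=True)
def alpha_backward(gS_ext, S, E, I, U, a, b, tau, theta, slope, smooth):
    """Backward pass matching :func:`alpha_forward`.

    gS_ext : (T, n) direct loss gradient w.r.t. the spikes (from downstream
    layers and/or the readout).  Returns (gC, ga, gb, gtau).
    """
    T, n = gS_ext.shape
    gC = np.zeros((T, n))
    ga = np.zeros(n)
    gb = np.zeros(n)
    gtau = np.zeros(n)
    for j in range(n):
        gE_next = 0.0
        gI_next = 0.0
        for t in range(T - 1, -1, -1):
            # S[t] feeds downstream/readout and gates the trace decay at t+1
            gS = gS_ext[t, j]
            if t < T - 1:
                gS -= a[j] * E[t, j] * gE_next + b[j] * I[t, j] * gI_next
            gU = gS * _dspike(U[t, j] - theta[j], slope, smooth)
            gtau[j] += gU * (E[t, j] + I[t, j])
            keep = 1.0 - S[t, j]
            gE = tau[j] * gU + a[j] * keep * gE_next
            gI = tau[j] * gU + b[j] * keep * gI_next
            if t > 0:
                keep_prev = 1.0 - S[t - 1, j]
                ga[j] += keep_prev * E[t - 1, j] * gE
                gb[j] += keep_prev * I[t - 1, j] * gI
            gC[t, j] = gE - gI
            gE_next = gE
            gI_next = gI
    return gC, ga, gb, gtau


@njit(cache=True)
def lif_forward(C, b, theta, slope, smooth):
    """Integrate one LIF layer.  Returns S, U, each (T, n)."""
    T, n = C.shape
    S = np.zeros((T, n))
    U = np.zeros((T, n))
    for t in range(T):
        for j in range(n):
            uprev = 0.0 if t == 0 else U[t - 1, j]
            sprev = 0.0 if t == 0 else S[t - 1, j]
            v = b[j] * uprev + C[t, j]
            u = (1.0 - sprev) * v
            U[t, j] = u
            S[t, j] = _spike(u - theta[j], slope, smooth)
    return S, U


@njit(cache=True)
def lif_backward(gS_ext, S, U, C, b, theta, slope, smooth):
    """Backward pass matching :func:`lif_forward`.  Returns (gC, gb)."""
    T, n = gS_ext.shape
    gC = np.zeros((T, n))
    gb = np.zeros(n)
    for j in range(n):
        gU_next = 0.0
        v_next = 0.0
        for t in range(T - 1, -1, -1):
            sprev = 0.0 if t == 0 else S[t - 1, j]
            uprev = 0.0 if t == 0 else U[t - 1, j]
            # gate: U[t+1] = (1 - S[t]) * V[t+1]  =>  dU[t+1]/dS[t] = -V[t+1]
            gS = gS_ext[t, j] - v_next * gU_next
            # U[t] feeds S[t] directly and V[t+1] = b*U[t] + C[t+1] via the leak
            snow = S[t, j]
            gU = gS * _dspike(U[t, j] - theta[j], slope, smooth) + b[j] * (1.0 - snow) * gU_next
            v = b[j] * uprev + C[t, j]
            gV = (1.0 - sprev) * gU
            gb[j] += gV * uprev
            gC[t, j] = gV
            v_next = v
            gU_next = gU
    return gC, gb
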