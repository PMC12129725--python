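"""Numba-compiled likelihood kernels for the bandit trial recursion.

These are drop-in accelerations of the numpy reference implementation in
:mod:`painlearn.models`; the two paths are required to agree to 1e-10 and
are cross-checked in the test suite.  Decay and lapse are applied
unconditionally with neutral values (d=0, xi=0) standing in for inactive
parameters, which the callers guarantee.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def loglik_total(choice0, win, loss, R, P, lr_r, lr_p, d, xi):
    B, S = R.shape
    T = choice0.shape[1]
    out = np.zeros((B, S))
    qr = np.zeros(4)
    qp = np.zeros(4)
    p = np.zeros(4)
    for b in range(B):
        for s in range(S):
            for i in range(4):
                qr[i] = 0.0
                qp[i] = 0.0
            keep = 1.0 - d[b, s]
            x = xi[b, s]
            rr, pp = R[b, s], P[b, s]
            ar, ap = lr_r[b, s], lr_p[b, s]
            ll = 0.0
            for t in range(T):
                m = -1e300
                for i in range(4):
                    qr[i] *= keep
                    qp[i] *= keep
                    tot = qr[i] + qp[i]
                    if tot > m:
                        m = tot
                ssum = 0.0
                for i in range(4):
                    p[i] = math.exp(qr[i] + qp[i] - m)
                    ssum += p[i]
                c = choice0[s, t]
                pc = p[c] / ssum * (1.0 - x) + 0.25 * x
                if pc < 1e-12:
                    pc = 1e-12
                ll += math.log(pc)
                dr = rr * (win[s, t] - qr[c])
                dp = pp * (loss[s, t] - qp[c])
                qr[c] += ar * dr
                qp[c] += ap * dp
            out[b, s] = ll
    return out


@njit(cache=True)
def loglik_pointwise(choice0, win, loss, R, P, lr_r, lr_p, d, xi):
    B, S = R.shape
    T = choice0.shape[1]
    out = np.zeros((B, S, T))
    qr = np.zeros(4)
    qp = np.zeros(4)
    p = np.zeros(4)
    for b in range(B):
        for s in range(S):
            for i in range(4):
                qr[i] = 0.0
                qp[i] = 0.0
            keep = 1.0 - d[b, s]
            x = xi[b, s]
            rr, pp = R[b, s], P[b, s]
            ar, ap = lr_r[b, s], lr_p[b, s]
            for t in range(T):
                m = -1e300
                for i in range(4):
                    qr[i] *= keep
                    qp[i] *= keep
                    tot = qr[i] + qp[i]
                    if tot > m:
                        m = tot
                ssum = 0.0
                for i in range(4):
                    p[i] = math.exp(qr[i] + qp[i] - m)
                    ssum += p[i]
                c = choice0[s, t]
                pc = p[c] / ssum * (1.0 - x) + 0.25 * x
                if pc < 1e-12:
                    pc = 1e-12
                out[b, s, t] = math.log(pc)
                dr = rr * (win[s, t] - qr[c])
                dp = pp * (loss[s, t] - qp[c])
                qr[c] += ar * dr
                qp[c] += ap * dp
    return out
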