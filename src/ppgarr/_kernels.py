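"""Numba-jitted GRU recurrence kernels (single precision).

The gate layout everywhere is ``[r | z | n]`` blocks of width H, with two
bias vectors per gate (input-side and recurrent-side), i.e.

    r_t = sigmoid(x_t Wi_r + bi_r + h_{t-1} Wh_r + bh_r)
    z_t = sigmoid(x_t Wi_z + bi_z + h_{t-1} Wh_z + bh_z)
    n_t = tanh   (x_t Wi_n + bi_n + r_t * (h_{t-1} Wh_n + bh_n))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

The input projection ``P = X Wi + bi`` is one large GEMM done by the
caller; the kernels only run the sequential recurrence.  The inner loops
are written branch-free over flat contiguous blocks so LLVM can
vectorize them; ``exp`` is a 6th-order polynomial with an exponent-bit
reconstruction (max relative error ~2e-6, ample for training).
"""
from __future__ import annotations

import numpy as np
from llvmlite import ir
from numba import njit, types
from numba.extending import intrinsic

F = np.float32
_LOG2E = F(1.4426950408889634)
_A1 = F(0.6931471805599453)
_A2 = F(0.2402265069591007)
_A3 = F(0.05550410866482158)
_A4 = F(0.009618129107628477)
_A5 = F(0.0013333558146428443)
_A6 = F(0.00015401735211)
_ONE = F(1.0)
_TWO = F(2.0)
_BIAS = F(12288.5)
_CLAMP = F(-87.0)


@intrinsic
def _i32_as_f32(typingctx, x):
    """Reinterpret an int32 bit pattern as float32 (LLVM bitcast)."""
    sig = types.float32(types.int32)

    def codegen(context, builder, signature, args):
        return builder.bitcast(args[0], ir.FloatType())

    return sig, codegen


@njit(cache=True, fastmath=True, inline="always")
def _sexp(x):
    # float32 exp via 2^k * 2^f, f in [-0.5, 0.5]; branch-free and SIMD-friendly
    y = max(x, _CLAMP) * _LOG2E
    ki = np.int32(y + _BIAS) - np.int32(12288)
    f = y - np.float32(ki)
    p = _ONE + f * (_A1 + f * (_A2 + f * (_A3 + f * (_A4 + f * (_A5 + f * _A6)))))
    return p * _i32_as_f32((ki + np.int32(127)) << np.int32(23))


@njit(cache=True, fastmath=True, inline="always")
def _sigmoid(x):
    return _ONE / (_ONE + _sexp(-x))


@njit(cache=True, fastmath=True)
def gru_forward(P, Wh, bh, R, Z, N, HN, Hs):
    """Run the recurrence over P (T, B, 3H); fill gate/state caches.

    ``R, Z, N, HN, Hs`` are preallocated (T, B, H) float32 outputs: reset
    gate, update gate, candidate, recurrent n-preactivation, and hidden
    state.  Returns nothing; the final state is ``Hs[-1]``.
    """
    T, B, G = P.shape
    H = G // 3
    h = np.zeros((B, H), dtype=np.float32)
    for t in range(T):
        Q = np.dot(h, Wh)
        q = Q.ravel()
        pt = P[t].ravel()
        rt = R[t].ravel()
        zt = Z[t].ravel()
        nt = N[t].ravel()
        hnt = HN[t].ravel()
        ht = Hs[t].ravel()
        hf = h.ravel()
        for b in range(B):
            o = b * 3 * H
            oh = b * H
            for j in range(H):
                rt[oh + j] = _sigmoid(pt[o + j] + q[o + j] + bh[j])
            for j in range(H):
                zt[oh + j] = _sigmoid(pt[o + H + j] + q[o + H + j] + bh[H + j])
            for j in range(H):
                hn = q[o + 2 * H + j] + bh[2 * H + j]
                hnt[oh + j] = hn
                e = _sexp(-_TWO * (pt[o + 2 * H + j] + rt[oh + j] * hn))
                nt[oh + j] = (_ONE - e) / (_ONE + e)
            for j in range(H):
                hv = (_ONE - zt[oh + j]) * nt[oh + j] + zt[oh + j] * hf[oh + j]
                ht[oh + j] = hv
                hf[oh + j] = hv


@njit(cache=True, fastmath=True)
def gru_forward_infer(P, Wh, bh, Hs):
    """Forward recurrence storing only hidden states (inference path)."""
    T, B, G = P.shape
    H = G // 3
    h = np.zeros((B, H), dtype=np.float32)
    for t in range(T):
        Q = np.dot(h, Wh)
        q = Q.ravel()
        pt = P[t].ravel()
        ht = Hs[t].ravel()
        hf = h.ravel()
        for b in range(B):
            o = b * 3 * H
            oh = b * H
            for j in range(H):
                r = _sigmoid(pt[o + j] + q[o + j] + bh[j])
                z = _sigmoid(pt[o + H + j] + q[o + H + j] + bh[H + j])
                hn = q[o + 2 * H + j] + bh[2 * H + j]
                e = _sexp(-_TWO * (pt[o + 2 * H + j] + r * hn))
                n = (_ONE - e) / (_ONE + e)
                hv = (_ONE - z) * n + z * hf[oh + j]
                ht[oh + j] = hv
                hf[oh + j] = hv


@njit(cache=True, fastmath=True)
def gru_backward(dH, WhT, R, Z, N, HN, Hs, dQ, dN):
    """Backpropagate through the recurrence.

    ``dH`` (T, B, H) holds upstream gradients on each hidden state.
    Fills ``dQ`` (T, B, 3H) with gradients w.r.t. the recurrent
    pre-activations ``h_{t-1} Wh + bh`` (gate layout [dr | dz | r*dn])
    and ``dN`` (T, B, H) with the candidate gradients (needed for the
    input-projection gradient, whose n-block is ``dn`` not ``r*dn``).
    ``WhT`` is the contiguous transpose of Wh.
    """
    T, B, H = dH.shape
    dh = np.zeros((B, H), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        dqt = dQ[t].ravel()
        dnt = dN[t].ravel()
        dht_up = dH[t].ravel()
        rt = R[t].ravel()
        zt = Z[t].ravel()
        nt = N[t].ravel()
        hnt = HN[t].ravel()
        dhf = dh.ravel()
        if t > 0:
            hprev = Hs[t - 1]
        else:
            hprev = np.zeros((B, H), dtype=np.float32)
        hp = hprev.ravel()
        for b in range(B):
            o = b * 3 * H
            oh = b * H
            for j in range(H):
                dtot = dht_up[oh + j] + dhf[oh + j]
                z = zt[oh + j]
                n = nt[oh + j]
                r = rt[oh + j]
                dz = dtot * (hp[oh + j] - n) * z * (_ONE - z)
                dn = dtot * (_ONE - z) * (_ONE - n * n)
                dr = dn * hnt[oh + j] * r * (_ONE - r)
                dqt[o + j] = dr
                dqt[o + H + j] = dz
                dqt[o + 2 * H + j] = dn * r
                dnt[oh + j] = dn
                dhf[oh + j] = dtot * z
        dh += np.dot(dQ[t], WhT)
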