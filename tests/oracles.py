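"""Loop-based brute-force evaluators used as independent oracles.

Deliberately naive: per-node, per-edge scalar arithmetic with no shared code
with the package's vectorized implementation.
"""

import math

import numpy as np


def leaky(x: float, slope: float) -> float:
    return x if x > 0 else slope * x


def gat_attention_oracle(H, A, W, a, slope):
    """Neighbourhood softmax of a.[Wh_i || Wh_j] after LeakyReLU."""
    n = H.shape[0]
    HW = np.array([W.T @ H[i] for i in range(n)])
    alpha = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        logits = [leaky(float(np.concatenate([HW[i], HW[j]]) @ a), slope)
                  for j in nbrs]
        m = max(logits)
        exps = [math.exp(v - m) for v in logits]
        z = sum(exps)
        for j, e in zip(nbrs, exps):
            alpha[i, j] = e / z
    return alpha


def gat_layer_oracle(H, A, Ws, a_s, slope):
    """Per-head ReLU(sum_j alpha_ij W h_j), heads concatenated."""
    n = H.shape[0]
    head_outs = []
    for W, a in zip(Ws, a_s):
        alpha = gat_attention_oracle(H, A, W, a, slope)
        HW = H @ W
        out = np.zeros((n, W.shape[1]))
        for i in range(n):
            s = np.zeros(W.shape[1])
            for j in range(n):
                if A[i, j]:
                    s += alpha[i, j] * HW[j]
            out[i] = np.maximum(s, 0.0)
        head_outs.append(out)
    return np.concatenate(head_outs, axis=1)


def gat_stack_oracle(H, A, layers, slope):
    """Sequential layers; concatenation of every layer's output."""
    outs = []
    cur = H
    for Ws, a_s in layers:
        cur = gat_layer_oracle(cur, A, Ws, a_s, slope)
        outs.append(cur)
    return np.concatenate(outs, axis=1)


def mhsa_head_oracle(X, WQ, WK, WV):
    """Literal per-position scaled dot-product attention."""
    n = X.shape[0]
    d_k = WK.shape[1]
    Q = np.array([WQ.T @ X[i] for i in range(n)])
    K = np.array([WK.T @ X[i] for i in range(n)])
    V = np.array([WV.T @ X[i] for i in range(n)])
    out = np.zeros((n, WV.shape[1]))
    for i in range(n):
        scores = [float(Q[i] @ K[j]) / math.sqrt(d_k) for j in range(n)]
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        z = sum(exps)
        for j in range(n):
            out[i] += (exps[j] / z) * V[j]
    return out


def auc_oracle(scores, labels):
    """O(m^2) rank AUC: fraction of positive-negative pairs correctly ordered,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
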