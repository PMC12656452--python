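"""Naive, loop-based reference implementations used as independent oracles.

Everything here is deliberately written as plain double/triple loops over
scalars so that it shares no code path with the vectorised package
implementations it checks.
"""

import math

import numpy as np


# ----------------------------------------------------------------- ssrm
def mask_oracle(f):
    c, h, w = f.shape
    m = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for ch in range(c):
                s += f[ch, i, j]
            m[i, j] = max(s / c, 0.0)
    lo = min(m[i, j] for i in range(h) for j in range(w))
    hi = max(m[i, j] for i in range(h) for j in range(w))
    if hi - lo < 1e-12:
        return np.full((h, w), 1.0 / (h * w))
    return (m - lo) / (hi - lo)


def argmax_oracle(mask):
    best = (0, 0)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] > mask[best]:
                best = (i, j)
    return best


def polar_targets_oracle(ref, n):
    x, y = ref
    r = np.zeros((n, n))
    th = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            r[i, j] = math.sqrt((x - i) ** 2 + (y - j) ** 2) / (n * math.sqrt(2))
            th[i, j] = ((math.atan2(y - j, x - i) + math.pi)
                        / (2 * math.pi)) % 1.0
    th[x, y] = 0.0
    return r, th


def polar_head_oracle(h, ref, weight, bias):
    """Per-cell affine + logistic sigmoid; weight (2, 2C), bias (2,)."""
    c, n, m = h.shape
    x, y = ref
    r = np.zeros((n, m))
    th = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            vec = np.concatenate([h[:, i, j], h[:, x, y]])
            out = weight @ vec + bias
            r[i, j] = 1.0 / (1.0 + math.exp(-out[0]))
            th[i, j] = 1.0 / (1.0 + math.exp(-out[1]))
    return r, th


def distance_loss_oracle(r_pred, r_t, mask):
    num = 0.0
    den = 0.0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            num += mask[i, j] * (r_pred[i, j] - r_t[i, j]) ** 2
            den += mask[i, j]
    return num / den


def angle_loss_oracle(th_pred, th_t, mask):
    n, m = mask.shape
    delta = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            d = th_pred[i, j] - th_t[i, j]
            delta[i, j] = d if d >= 0 else 1.0 + d
    den = sum(mask[i, j] for i in range(n) for j in range(m))
    mean = sum(mask[i, j] * delta[i, j] for i in range(n)
               for j in range(m)) / den
    return sum(mask[i, j] * (delta[i, j] - mean) ** 2 for i in range(n)
               for j in range(m)) / den


# ----------------------------------------------------------------- mcpm
def similarity_oracle(x1, x2):
    c, p1 = x1.shape
    _, p2 = x2.shape
    m = np.zeros((p1, p2))
    for i in range(p1):
        for j in range(p2):
            m[i, j] = sum(x1[ch, i] * x2[ch, j] for ch in range(c))
    return m


def colsoftmax_oracle(a):
    out = np.zeros_like(a)
    for j in range(a.shape[1]):
        col = a[:, j]
        e = np.exp(col - col.max())
        out[:, j] = e / e.sum()
    return out


def complementary_oracle(x_source, att):
    c, p_src = x_source.shape
    _, p_out = att.shape
    y = np.zeros((c, p_out))
    for i in range(p_out):
        for j in range(p_src):
            for ch in range(c):
                y[ch, i] += att[j, i] * x_source[ch, j]
    return y


def mcpm_oracle(scales, gamma):
    """Full pipeline via loops: returns one fused matrix per scale."""
    n = len(scales)
    ys = [np.zeros_like(x) for x in scales]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = similarity_oracle(scales[i], scales[j])
            a_ij = colsoftmax_oracle(-m.T)
            ys[i] = ys[i] + complementary_oracle(scales[j], a_ij)
    return [x + gamma * y for x, y in zip(scales, ys)]


# --------------------------------------------------------------- cdloss
def class_score_oracle(group, mask, xi):
    k, p = group.shape
    total = 0.0
    for loc in range(p):
        best = -math.inf
        for ch in range(xi):
            best = max(best, mask[ch, loc] * group[ch, loc])
        total += best
    return total / p


def cd_loss_oracle(fmap, label, c, k, xi, masks):
    """masks: list of c arrays, one per class group, in order."""
    flat = fmap.reshape(fmap.shape[0], -1)
    scores = []
    for i in range(c):
        group = flat[i * k:(i + 1) * k]
        scores.append(class_score_oracle(group, masks[i], xi))
    scores = np.asarray(scores)
    e = np.exp(scores - scores.max())
    p = e / e.sum()
    return -math.log(p[label])
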