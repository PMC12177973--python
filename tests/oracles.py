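"""Independent brute-force oracles used to validate the metric suite.

Everything here is written as plain loops over pixels/elements, sharing no
code with slideprep.metrics, so agreement is meaningful.
"""

import math

import numpy as np


def iou_oracle(P, G):
    inter = union = 0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            p, g = P[i, j] > 0, G[i, j] > 0
            inter += p and g
            union += p or g
    return inter / union if union else 1.0


def boundary_oracle(M):
    pts = []
    h, w = M.shape
    for i in range(h):
        for j in range(w):
            if M[i, j] <= 0:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or M[ni, nj] <= 0:
                    pts.append((i, j))
                    break
    return pts


def hausdorff_oracle(P, G):
    bp, bg = boundary_oracle(P), boundary_oracle(G)
    if not bp or not bg:
        return math.nan

    def directed(a, b):
        return max(min(math.dist(p, q) for q in b) for p in a)

    return max(directed(bp, bg), directed(bg, bp))


def perimeter_ratio_oracle(P, G):
    nb_g = len(boundary_oracle(G))
    return len(boundary_oracle(P)) / nb_g if nb_g else math.nan


def flood_fill_count(M, connectivity=8):
    """Component count by explicit stack-based flood fill."""
    h, w = M.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                if (a, b) != (0, 0)]
    else:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    count = 0
    for i in range(h):
        for j in range(w):
            if M[i, j] <= 0 or seen[i, j]:
                continue
            count += 1
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                ci, cj = stack.pop()
                for di, dj in nbrs:
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < h and 0 <= nj < w and M[ni, nj] > 0 \
                            and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
    return count


def comp_diff_oracle(P, G, connectivity=8):
    return abs(flood_fill_count(P, connectivity)
               - flood_fill_count(G, connectivity))


def multiclass_dice_oracle(A, B, classes):
    scores = []
    for c in classes:
        na = nb = inter = 0
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                a, b = A[i, j] == c, B[i, j] == c
                na += a
                nb += b
                inter += a and b
        if na == 0 and nb == 0:
            continue
        scores.append(2 * inter / (na + nb))
    return sum(scores) / len(scores) if scores else math.nan


def ari_oracle(a, b):
    from collections import Counter

    pairs = Counter(zip(a, b))
    ca, cb = Counter(a), Counter(b)

    def c2(x):
        return x * (x - 1) / 2

    sum_ij = sum(c2(v) for v in pairs.values())
    sum_a = sum(c2(v) for v in ca.values())
    sum_b = sum(c2(v) for v in cb.values())
    n = len(a)
    exp = sum_a * sum_b / c2(n)
    mx = (sum_a + sum_b) / 2
    if mx == exp:
        return 1.0
    return (sum_ij - exp) / (mx - exp)
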