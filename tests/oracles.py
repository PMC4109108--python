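"""Brute-force double-sum oracles.

Written as explicit Python loops so they share no code path with the
scipy-based separable-convolution implementation they check.
"""

import numpy as np


def brute_window_sum(field, weights, support, boundary):
    """sum_y K(x-y) field(y) by explicit loops.

    boundary="nearest" clamps out-of-grid indices (replicate extension);
    boundary="zero" skips out-of-grid terms (integration over the domain).
    """
    field = np.asarray(field, dtype=np.float64)
    h, w = field.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-support, support + 1):
                for dj in range(-support, support + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += weights[di + support, dj + support] * field[ii, jj]
                    elif boundary == "nearest":
                        ii = min(max(ii, 0), h - 1)
                        jj = min(max(jj, 0), w - 1)
                        acc += weights[di + support, dj + support] * field[ii, jj]
            out[i, j] = acc
    return out


def brute_fitting_means(I, M1, M2, kernel):
    """Windowed-mean ratio K*(M_i I) / K*M_i evaluated by explicit loops."""
    f = []
    for M in (M1, M2):
        num = brute_window_sum(I * M, kernel.weights, kernel.support, "nearest")
        den = brute_window_sum(np.asarray(M, float), kernel.weights,
                               kernel.support, "nearest")
        f.append(num / den)
    return f[0], f[1]


def brute_means_counts(I, M1, M2, kernel):
    """Window-mass-weighted means/counts via explicit double sums over the
    domain (the double-integral form, inner integral over the grid only)."""
    mass = brute_window_sum(np.ones_like(I), kernel.weights, kernel.support, "zero")
    out = []
    for M in (M1, M2):
        N = float(np.sum(mass * M))
        C = float(np.sum(mass * I * M)) / N
        out.append((C, N))
    return out[0][0], out[1][0], out[0][1], out[1][1]  # C1, C2, N1, N2


def brute_fitting_energy(I, M1, M2, f1, f2, kernel, lambda1=1.0, lambda2=1.0):
    """Double-sum fitting energy sum_x sum_y K(x-y)(I(y)-f_i(x))^2 M_i(y),
    with the y-extension replicated beyond the grid."""
    h, w = I.shape
    s = kernel.support
    total = 0.0
    for lam, fi, M in ((lambda1, f1, M1), (lambda2, f2, M2)):
        for i in range(h):
            for j in range(w):
                for di in range(-s, s + 1):
                    for dj in range(-s, s + 1):
                        ii = min(max(i + di, 0), h - 1)
                        jj = min(max(j + dj, 0), w - 1)
                        total += lam * kernel.weights[di + s, dj + s] * (
                            (I[ii, jj] - fi[i, j]) ** 2 * M[ii, jj]
                        )
    return total


def brute_discriminant(I, M1, M2, C1, C2, N1, N2):
    """Direct evaluation of the inverse-Fisher ratio."""
    V1 = np.sum((I - C1) ** 2 * M1) / (N1 - 1.0)
    V2 = np.sum((I - C2) ** 2 * M2) / (N2 - 1.0)
    return (V1 + V2) / (C1 - C2) ** 2
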