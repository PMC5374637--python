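"""Brute-force reference implementations used as oracles.

Everything here is written as literal double/triple sums over the defining
formulas, independent of the vectorized FFT paths in the package, so the
two can be compared within tight absolute tolerances on small inputs.
"""

from __future__ import annotations

import numpy as np


def brute_instantaneous(x: str, y: str, lookup, L: int, convention: str = "asymmetric"):
    """r[n, tau] by direct evaluation; ``lookup(a, b)`` scores a symbol pair."""
    N = len(x)
    vals = np.zeros((N, 2 * L + 1))
    for n in range(N):
        for j, tau in enumerate(range(-L, L + 1)):
            if convention == "asymmetric":
                a, b = n, n + tau
            else:
                a, b = n - tau, n + tau
            if 0 <= a < N and 0 <= b < len(y):
                vals[n, j] = lookup(x[a], y[b])
    return vals


def brute_correlation(vals: np.ndarray):
    """R[tau] = sum_n r[n, tau]."""
    return np.array([sum(vals[n, j] for n in range(vals.shape[0]))
                     for j in range(vals.shape[1])])


def brute_circular_correlation(x: str, y: str, lookup):
    N = len(x)
    return np.array([sum(lookup(x[n], y[(n + t) % N]) for n in range(N))
                     for t in range(N)])


def brute_symmetry(x: str, lookup, M: int):
    """s[n] = sum_{m=-M..M} S(x[n-m], x[n+m]), signed lags both counted."""
    N = len(x)
    out = np.zeros(N)
    for n in range(N):
        for m in range(-M, M + 1):
            if 0 <= n - m < N and 0 <= n + m < N:
                out[n] += lookup(x[n - m], x[n + m])
    return out


def brute_dft_lags(series: np.ndarray, lags: np.ndarray, K: int):
    """X[k] = sum_tau series[tau] exp(-2 pi i k tau / K), k = 0..K-1."""
    k = np.arange(K)
    return np.array([np.sum(series * np.exp(-2j * np.pi * kk * lags / K)) for kk in k])


def brute_wigner_ville(vals: np.ndarray, lags: np.ndarray, K: int):
    """Row-wise signed-lag DFT; returns the full complex (N, K) plane."""
    return np.stack([brute_dft_lags(vals[n], lags, K) for n in range(vals.shape[0])])


def brute_ambiguity(vals: np.ndarray, n_fft: int):
    """Column-wise position DFT: AF[i, j] = sum_n r[n, tau_j] e^{-2 pi i i n / N};
    rows unshifted (eta_i = i / n_fft)."""
    N = vals.shape[0]
    n = np.arange(N)
    out = np.zeros((n_fft, vals.shape[1]), dtype=complex)
    for i in range(n_fft):
        w = np.exp(-2j * np.pi * i * n / n_fft)
        for j in range(vals.shape[1]):
            out[i, j] = np.sum(vals[:, j] * w)
    return out


def brute_indicator_spectrum(x: str):
    """S[k] = sum_i |U_i[k]|^2 over the four DNA indicator tracks, full k."""
    N = len(x)
    S = np.zeros(N)
    for sym in "ACGT":
        u = np.array([1.0 if c == sym else 0.0 for c in x])
        U = brute_dft_lags(u, np.arange(N), N)
        S += np.abs(U) ** 2
    return S
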