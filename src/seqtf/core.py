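"""Bilinear time-frequency transforms driven by a similarity matrix.

Everything derives from the instantaneous correlation

    r[n, tau] = S(x[n], y[n + tau])          (asymmetric lag convention)
    r[n, m]   = S(x[n - m], y[n + m])        (symmetric / half-lag convention)

where S is a pairwise symbol-similarity matrix, or the ordinary product
``conj(x[n]) * y[n + tau]`` when the inputs are numeric (the validation
mode in which every transform reduces to its textbook form).  Out-of-range
positions contribute exactly zero.

From r[n, tau] follow, by summation and discrete Fourier transforms:

* the correlation function  R[tau] = sum_n r[n, tau]  (linear or circular),
* the symmetry function     s[n]   = sum_m r[n, m]    (symmetric convention),
* the spectrum              |DFT_tau R|,
* the Wigner-Ville plane    row-wise DFT of r over tau,
* the ambiguity plane       column-wise DFT of r over n (lag x Doppler),
* Cohen-class distributions: the ambiguity plane multiplied by a kernel
  and transformed to the time-frequency plane, equivalently the
  Wigner-Ville plane circularly convolved with the kernel's TF-domain form.

Frequencies are normalized (cycles per position): a period-P repeat puts a
line at 1/P.  Forward DFTs are unnormalized; the FFT length is zero-padded
to a power of two by default and recorded in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .similarity import SimilarityMatrix, identity_similarity
from .sequence_io import GenomicSequence, encode_sequence

__all__ = [
    "InstantaneousCorrelation",
    "CorrelationSeries",
    "SymmetrySeries",
    "Spectrum1D",
    "TFPlane",
    "AmbiguityPlane",
    "TFKernel",
    "instantaneous_correlation",
    "correlation_function",
    "symmetry_function",
    "spectrum",
    "series_spectrum",
    "tf_marginal_spectrum",
    "wigner_ville",
    "ambiguity",
    "cohen_distribution",
    "default_max_lag",
    "default_fft_length",
]


def default_max_lag(n: int) -> int:
    """Full lag range for short sequences, capped for long ones (the lag
    plane is quadratic in sequence length)."""
    return n - 1 if n <= 2048 else 1024


def default_fft_length(n_lags: int) -> int:
    """Next power of two >= 2 * n_lags, for a smooth frequency grid."""
    k = 1
    while k < 2 * n_lags:
        k *= 2
    return k


# ---------------------------------------------------------------------------
# containers


@dataclass
class InstantaneousCorrelation:
    """Position x lag grid of pointwise similarities, the root object of
    every bilinear transform.

    ``values[n, j]`` holds the similarity at position n and lag
    ``lags[j]``; entries whose accessed positions fall outside the
    sequence are exactly zero.
    """

    values: np.ndarray          # (N, 2L+1), real (similarity) or complex (numeric)
    lags: np.ndarray            # signed integers -L..L (half-lags m if symmetric)
    convention: str             # "asymmetric" | "symmetric"
    is_auto: bool
    metadata: dict = field(default_factory=dict)
    # retained inputs, used by circular-mode recomputation
    _x_codes: Optional[np.ndarray] = None
    _y_codes: Optional[np.ndarray] = None
    _sim_padded: Optional[np.ndarray] = None
    _x_num: Optional[np.ndarray] = None
    _y_num: Optional[np.ndarray] = None

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def max_lag(self) -> int:
        return int(self.lags[-1])


@dataclass
class CorrelationSeries:
    """Average similarity of the two sequences at each lag."""

    lags: np.ndarray
    values: np.ndarray
    mode: str                   # "linear" (signed lags -L..L) | "circular" (0..N-1)
    normalization: str          # "sum" | "per-overlap-mean"
    metadata: dict = field(default_factory=dict)


@dataclass
class SymmetrySeries:
    """Lag-summed similarity of symbols mirrored about each position."""

    positions: np.ndarray
    values: np.ndarray
    max_half_lag: int
    metadata: dict = field(default_factory=dict)


@dataclass
class Spectrum1D:
    """Magnitude spectrum on normalized frequencies in [0, 0.5]."""

    freqs: np.ndarray
    values: np.ndarray
    fft_length: int
    complex_values: Optional[np.ndarray] = None   # full-length complex DFT
    metadata: dict = field(default_factory=dict)


@dataclass
class TFPlane:
    """Position x frequency plane (Wigner-Ville or Cohen-class).

    ``values`` is the magnitude view on frequencies in [0, 0.5];
    ``complex_values`` keeps the full-FFT-length complex plane for
    marginal and pathway identities.
    """

    positions: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    kind: str                   # "wigner-ville" | "cohen"
    fft_length: int
    complex_values: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)


@dataclass
class AmbiguityPlane:
    """Lag x lag-frequency (Doppler) plane, complex with magnitude view.

    Rows are Doppler frequencies eta (centered, eta = 0 in the middle);
    columns are signed lags.
    """

    lags: np.ndarray
    etas: np.ndarray
    values: np.ndarray          # complex, (n_eta, n_lags)
    metadata: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def at_origin(self) -> complex:
        i = int(np.argmin(np.abs(self.etas)))
        j = int(np.argmin(np.abs(self.lags)))
        return complex(self.values[i, j])


@dataclass
class TFKernel:
    """Cohen-class smoothing kernel, specified in the ambiguity domain.

    ``evaluate`` returns Phi(tau, eta) on a grid; Phi(0, 0) = 1 for every
    kind, which makes the kernel's time-frequency-domain form sum to 1 on
    its grid (total plane mass is preserved).

    kinds: ``none`` (multiplicative identity), ``gaussian`` (separable,
    widths sigma_lag in samples and sigma_doppler in normalized
    frequency), ``choi-williams`` (exp(-(2 pi tau eta)^2 / sigma)).
    """

    kind: str = "none"
    sigma_lag: Optional[float] = None      # default L/8, resolved at use
    sigma_doppler: float = 1.0 / 16.0
    sigma_cw: float = 1.0

    def evaluate(self, lags: np.ndarray, etas: np.ndarray) -> np.ndarray:
        """Phi on the (eta, lag) grid: shape (len(etas), len(lags))."""
        lags = np.asarray(lags, dtype=float)
        etas = np.asarray(etas, dtype=float)
        if self.kind == "none":
            return np.ones((etas.size, lags.size))
        if self.kind == "gaussian":
            s_tau = self.sigma_lag if self.sigma_lag is not None else max(lags.max(), 1.0) / 8.0
            g_tau = np.exp(-(lags ** 2) / (2.0 * s_tau ** 2))
            g_eta = np.exp(-(etas ** 2) / (2.0 * self.sigma_doppler ** 2))
            return np.outer(g_eta, g_tau)
        if self.kind == "choi-williams":
            te = np.outer(etas, lags)
            return np.exp(-((2.0 * np.pi * te) ** 2) / self.sigma_cw)
        raise ValueError(f"unknown kernel kind {self.kind!r}")


# ---------------------------------------------------------------------------
# instantaneous correlation


def _as_codes(seq, sim: SimilarityMatrix, mode: str) -> np.ndarray:
    if isinstance(seq, GenomicSequence):
        if seq.alphabet.symbols != sim.alphabet.symbols:
            raise ValueError(
                f"sequence alphabet {seq.alphabet.symbols} does not match "
                f"similarity alphabet {sim.alphabet.symbols}"
            )
        return encode_sequence(seq, sim.alphabet, mode)
    return encode_sequence(str(seq), sim.alphabet, mode)


def instantaneous_correlation(
    x,
    y=None,
    sim: Union[SimilarityMatrix, str, None] = None,
    max_lag: Optional[int] = None,
    convention: str = "asymmetric",
    mode: str = "lenient",
) -> InstantaneousCorrelation:
    """Compute r[n, tau] for symbol sequences (via a similarity matrix) or
    numeric arrays (``sim="product"``: r[n, tau] = conj(x[n]) y[n+tau]).

    ``y=None`` gives the auto case.  Lags run over -max_lag..max_lag; with
    the symmetric convention the lag axis holds half-lags m and r[n, m] =
    S(x[n-m], y[n+m]).
    """
    is_auto = y is None
    numeric = sim == "product" or (
        sim is None and not isinstance(x, (GenomicSequence, str))
    )
    if numeric:
        xv = np.asarray(x)
        yv = xv if is_auto else np.asarray(y)
        if not np.issubdtype(xv.dtype, np.number):
            raise TypeError("numeric mode requires numeric arrays")
        N, Ny = len(xv), len(yv)
    else:
        if sim is None:
            alph = x.alphabet if isinstance(x, GenomicSequence) else None
            sim = identity_similarity(alph) if alph is not None else identity_similarity()
        if not isinstance(sim, SimilarityMatrix):
            raise TypeError(f"sim must be a SimilarityMatrix or 'product', got {sim!r}")
        xc = _as_codes(x, sim, mode)
        yc = xc if is_auto else _as_codes(y, sim, mode)
        N, Ny = len(xc), len(yc)
    L = default_max_lag(N) if max_lag is None else int(max_lag)
    if not 1 <= L <= N - 1:
        raise ValueError(f"max_lag must satisfy 1 <= L <= N-1 = {N - 1}, got {L}")
    lags = np.arange(-L, L + 1)
    if convention not in ("asymmetric", "symmetric"):
        raise ValueError(f"unknown convention {convention!r}")

    if numeric:
        vals = np.zeros((N, 2 * L + 1), dtype=complex)
        n = np.arange(N)
        for j, tau in enumerate(lags):
            if convention == "asymmetric":
                a, b = n, n + tau
            else:
                a, b = n - tau, n + tau
            ok = (a >= 0) & (a < N) & (b >= 0) & (b < Ny)
            vals[ok, j] = np.conj(xv[a[ok]]) * yv[b[ok]]
        if np.allclose(vals.imag, 0.0):
            vals = vals.real
        rc = InstantaneousCorrelation(
            vals, lags, convention, is_auto,
            metadata={"mode": "numeric", "similarity": "product"},
            _x_num=xv, _y_num=yv,
        )
        return rc

    P = sim.padded()            # sentinel index -1 -> all-zero row/column
    vals = np.zeros((N, 2 * L + 1))
    n = np.arange(N)
    for j, tau in enumerate(lags):
        if convention == "asymmetric":
            a, b = n, n + tau
        else:
            a, b = n - tau, n + tau
        ok = (a >= 0) & (a < N) & (b >= 0) & (b < Ny)
        vals[ok, j] = P[xc[a[ok]], yc[b[ok]]]
    ident = []
    for s in (x, y):
        if isinstance(s, GenomicSequence):
            ident.append(s.identifier)
    rc = InstantaneousCorrelation(
        vals, lags, convention, is_auto,
        metadata={"mode": "similarity", "similarity": sim.name,
                  "sequences": ",".join(ident)},
        _x_codes=xc, _y_codes=yc, _sim_padded=P,
    )
    return rc


# ---------------------------------------------------------------------------
# 1-D summaries


def correlation_function(
    rc: InstantaneousCorrelation,
    mode: str = "linear",
    normalization: str = "sum",
) -> CorrelationSeries:
    """R[tau] = sum_n r[n, tau].

    ``linear`` sums over the zero-padded grid (signed lags -L..L);
    ``circular`` wraps positions modulo N and spans one full period of
    lags 0..N-1, the mode under which the spectrum coincides exactly with
    the indicator-sequence DNA spectrum for identity similarity.
    ``per-overlap-mean`` divides each lag by its overlap count.
    """
    if rc.convention != "asymmetric":
        raise ValueError("correlation_function requires the asymmetric lag convention")
    if normalization not in ("sum", "per-overlap-mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    meta = dict(rc.metadata)
    meta.update({"transform": "correlation", "mode": mode, "normalization": normalization})
    if mode == "linear":
        vals = rc.values.sum(axis=0)
        if np.iscomplexobj(vals):
            pass
        if normalization == "per-overlap-mean":
            N = rc.n_positions
            if rc._y_codes is not None:
                Ny = len(rc._y_codes)
            elif rc._y_num is not None:
                Ny = len(rc._y_num)
            else:
                Ny = N
            counts = np.array(
                [max(0, min(N, Ny - t) - max(0, -t)) for t in rc.lags], dtype=float
            )
            vals = np.divide(vals, counts, out=np.zeros_like(vals, dtype=float), where=counts > 0)
        return CorrelationSeries(rc.lags.copy(), vals, "linear", normalization, meta)
    if mode == "circular":
        if rc._x_codes is not None:
            xc, yc, P = rc._x_codes, rc._y_codes, rc._sim_padded
            if len(xc) != len(yc):
                raise ValueError("circular mode requires equal-length sequences")
            N = len(xc)
            if N <= 4096:
                # direct sums: exact (integer) arithmetic for 0/1 matrices
                vals = np.empty(N)
                for t in range(N):
                    vals[t] = P[xc, np.roll(yc, -t)].sum()
            else:
                # cross-correlation theorem on the one-hot tracks
                k = P.shape[0] - 1
                Ux = np.stack([np.fft.fft(xc == a) for a in range(k)])
                Uy = Ux if rc.is_auto else np.stack([np.fft.fft(yc == a) for a in range(k)])
                C = np.zeros(N, dtype=complex)
                for a in range(k):
                    for b in range(k):
                        if P[a, b] != 0.0:
                            C += P[a, b] * np.conj(Ux[a]) * Uy[b]
                vals = np.fft.ifft(C).real
        else:
            xv, yv = rc._x_num, rc._y_num
            if len(xv) != len(yv):
                raise ValueError("circular mode requires equal-length sequences")
            N = len(xv)
            vals = np.array([np.sum(np.conj(xv) * np.roll(yv, -t)) for t in range(N)])
            if np.allclose(np.imag(vals), 0.0):
                vals = vals.real
        if normalization == "per-overlap-mean":
            vals = vals / N
        return CorrelationSeries(np.arange(N), vals, "circular", normalization, meta)
    raise ValueError(f"unknown mode {mode!r}")


def symmetry_function(
    x,
    sim: Optional[SimilarityMatrix] = None,
    max_half_lag: Optional[int] = None,
    mode: str = "lenient",
) -> SymmetrySeries:
    """s[n] = sum_{m=-M..M} S(x[n-m], x[n+m]): local mirror symmetry.

    Signed half-lags m and -m are both counted (for symmetric S each
    mirror pair therefore contributes twice, plus the m = 0 self term).
    Out-of-range terms are zero.
    """
    if sim is None:
        sim = identity_similarity(x.alphabet) if isinstance(x, GenomicSequence) else identity_similarity()
    xc = _as_codes(x, sim, mode)
    N = len(xc)
    M = default_max_lag(N) if max_half_lag is None else int(max_half_lag)
    if not 1 <= M <= N - 1:
        raise ValueError(f"max_half_lag must satisfy 1 <= M <= N-1 = {N - 1}, got {M}")
    P = sim.padded()
    n = np.arange(N)
    vals = np.zeros(N)
    for m in range(-M, M + 1):
        a, b = n - m, n + m
        ok = (a >= 0) & (a < N) & (b >= 0) & (b < N)
        vals[ok] += P[xc[a[ok]], xc[b[ok]]]
    meta = {"transform": "symmetry", "max_half_lag": M, "similarity": sim.name,
            "lag_counting": "signed"}
    return SymmetrySeries(n, vals, M, meta)


def _embed_lags(values: np.ndarray, lags: np.ndarray, K: int) -> np.ndarray:
    """Place signed-lag columns at index (lag mod K) of a length-K axis."""
    if K < len(lags):
        raise ValueError(f"fft_length {K} < number of lags {len(lags)}")
    dtype = complex if np.iscomplexobj(values) else float
    if values.ndim == 1:
        out = np.zeros(K, dtype=dtype)
        out[lags % K] = values
    else:
        out = np.zeros((values.shape[0], K), dtype=dtype)
        out[:, lags % K] = values
    return out


def spectrum(R: CorrelationSeries, fft_length: Optional[int] = None) -> Spectrum1D:
    """Magnitude DFT of the correlation function over lag.

    Linear series are zero-padded (default length: next power of two >=
    twice the lag count); circular series default to an exact length-N
    transform, under which (identity similarity, auto case) the result is
    real, non-negative, and equal bin-by-bin to the indicator DNA
    spectrum.
    """
    if R.mode == "circular":
        K = len(R.values) if fft_length is None else int(fft_length)
        F = np.fft.fft(R.values, n=K)
    else:
        K = default_fft_length(len(R.lags)) if fft_length is None else int(fft_length)
        F = np.fft.fft(_embed_lags(R.values, R.lags, K))
    half = K // 2 + 1
    freqs = np.arange(half) / K
    meta = dict(R.metadata)
    meta.update({"transform": "spectrum", "fft_length": K,
                 "lag_support": len(R.values) if R.mode == "circular" else len(R.lags),
                 "dft_normalization": "unnormalized-forward"})
    return Spectrum1D(freqs, np.abs(F[:half]), K, complex_values=F, metadata=meta)


def series_spectrum(series, fft_length: Optional[int] = None) -> Spectrum1D:
    """Magnitude DFT of a position-indexed series (e.g. the symmetry
    function), default length N so bin k sits at frequency k/N."""
    vals = series.values if hasattr(series, "values") else np.asarray(series, dtype=float)
    K = len(vals) if fft_length is None else int(fft_length)
    F = np.fft.fft(vals, n=K)
    half = K // 2 + 1
    freqs = np.arange(half) / K
    meta = dict(getattr(series, "metadata", {}))
    meta.update({"transform": "series-spectrum", "fft_length": K})
    return Spectrum1D(freqs, np.abs(F[:half]), K, complex_values=F, metadata=meta)


# ---------------------------------------------------------------------------
# planes


def wigner_ville(rc: InstantaneousCorrelation, fft_length: Optional[int] = None) -> TFPlane:
    """Row-wise DFT of r[n, tau] over the signed lag axis.

    Under the asymmetric convention a period-P repeat yields a horizontal
    line at 1/P; under the symmetric (half-lag) convention the frequency
    axis is halved (effective lag step 2, Nyquist at 0.25) and relabeled
    accordingly.
    """
    K = default_fft_length(len(rc.lags)) if fft_length is None else int(fft_length)
    buf = _embed_lags(rc.values, rc.lags, K)
    F = np.fft.fft(buf, axis=1)
    half = K // 2 + 1
    freqs = np.arange(half) / K
    scale = 1.0
    if rc.convention == "symmetric":
        freqs = freqs / 2.0
        scale = 0.5
    meta = dict(rc.metadata)
    meta.update({"transform": "wigner-ville", "fft_length": K,
                 "convention": rc.convention, "frequency_scale": scale,
                 "lag_support": len(rc.lags),
                 "dft_normalization": "unnormalized-forward"})
    return TFPlane(np.arange(rc.n_positions), freqs, np.abs(F[:, :half]),
                   "wigner-ville", K, complex_values=F, metadata=meta)


def tf_marginal_spectrum(tf: TFPlane) -> Spectrum1D:
    """Global spectrum as the position-summed complex rows of a TF plane.

    For a plane built from an asymmetric-convention correlation this is
    identical to ``spectrum(correlation_function(rc, "linear"))`` at the
    same FFT length (summation and the DFT commute); for the symmetric
    (half-lag) convention it provides the global spectrum on the relabeled
    frequency axis, where correlation_function itself is undefined.
    """
    if tf.complex_values is None:
        raise ValueError("TF plane does not retain its complex view")
    F = tf.complex_values.sum(axis=0)
    half = tf.fft_length // 2 + 1
    meta = dict(tf.metadata)
    meta["transform"] = "tf-marginal-spectrum"
    return Spectrum1D(tf.freqs.copy(), np.abs(F[:half]), tf.fft_length,
                      complex_values=F, metadata=meta)


def ambiguity(rc: InstantaneousCorrelation, fft_length: Optional[int] = None) -> AmbiguityPlane:
    """Column-wise DFT of r[n, tau] over position, fftshifted so the
    Doppler axis eta is centered at 0.

    For the auto case with identity similarity AF(0, 0) = N, and the
    magnitude attains its maximum at the origin whenever S is
    non-negative with a dominant diagonal.
    """
    Np = rc.n_positions if fft_length is None else int(fft_length)
    A = np.fft.fft(rc.values, n=Np, axis=0)
    A = np.fft.fftshift(A, axes=0)
    etas = np.fft.fftshift(np.fft.fftfreq(Np))
    meta = dict(rc.metadata)
    meta.update({"transform": "ambiguity", "fft_length": Np,
                 "dft_normalization": "unnormalized-forward"})
    return AmbiguityPlane(rc.lags.copy(), etas, A, meta)


def cohen_distribution(
    rc: InstantaneousCorrelation,
    kernel: TFKernel,
    fft_length: Optional[int] = None,
    path: str = "ambiguity",
) -> TFPlane:
    """Kernel-smoothed time-frequency distribution.

    ``path="ambiguity"`` multiplies the (unshifted) ambiguity plane by
    Phi(tau, eta) and transforms to the TF plane; ``path="tf-convolution"``
    circularly convolves the complex Wigner-Ville plane with the kernel's
    TF-domain form by direct summation.  The two are mathematically
    identical; the direct-convolution path is quadratic in the plane size
    and intended as a cross-check on small inputs.
    """
    if kernel.kind not in ("none", "gaussian", "choi-williams"):
        raise ValueError(f"unknown kernel kind {kernel.kind!r}")
    K = default_fft_length(len(rc.lags)) if fft_length is None else int(fft_length)
    N = rc.n_positions
    etas = np.fft.fftfreq(N)                 # unshifted, signed
    phi_at = kernel.evaluate(rc.lags, etas)  # (N, 2L+1)

    if path == "ambiguity":
        A = np.fft.fft(rc.values, axis=0)    # (N, 2L+1), eta unshifted
        r_f = np.fft.ifft(A * phi_at, axis=0)
        buf = _embed_lags(r_f, rc.lags, K)
        F = np.fft.fft(buf, axis=1)
    elif path == "tf-convolution":
        wv = np.fft.fft(_embed_lags(rc.values, rc.lags, K), axis=1)
        phi_emb = _embed_lags(phi_at.astype(complex), rc.lags, K)
        phi_tf = np.fft.fft(np.fft.ifft(phi_emb, axis=0), axis=1) / K
        F = np.zeros((N, K), dtype=complex)
        for dn in range(N):
            for dk in range(K):
                w = wv[dn, dk]
                if w != 0.0:
                    F += w * np.roll(np.roll(phi_tf, dn, axis=0), dk, axis=1)
    else:
        raise ValueError(f"unknown path {path!r}")

    half = K // 2 + 1
    freqs = np.arange(half) / K
    scale = 1.0
    if rc.convention == "symmetric":
        freqs = freqs / 2.0
        scale = 0.5
    meta = dict(rc.metadata)
    meta.update({"transform": "cohen", "fft_length": K, "path": path,
                 "lag_support": len(rc.lags),
                 "kernel": kernel.kind,
                 "kernel_params": {"sigma_lag": kernel.sigma_lag,
                                   "sigma_doppler": kernel.sigma_doppler,
                                   "sigma_cw": kernel.sigma_cw},
                 "convention": rc.convention, "frequency_scale": scale})
    return TFPlane(np.arange(N), freqs, np.abs(F[:, :half]), "cohen", K,
                   complex_values=F, metadata=meta)
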