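"""Peak and spectral-line detection.

A tandem repeat of period P shows up in the Wigner-Ville plane as a
horizontal line at normalized frequency 1/P spanning the positions of the
repeat.  ``detect_spectral_lines`` operationalizes the by-eye reading of
such planes: per-position spectral peaks above a median-relative threshold
are linked across adjacent positions into lines, and short runs are
discarded.  All thresholds are relative, so detections are invariant to
scaling the plane by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.signal import find_peaks

from .core import Spectrum1D, TFPlane

__all__ = ["Peak", "SpectralLine", "dominant_frequency", "detect_spectral_lines",
           "lines_to_table", "lines_to_bed"]


class Peak(NamedTuple):
    freq: float
    magnitude: float


@dataclass
class SpectralLine:
    """A persistent spectral peak: frequency, 1-based inclusive position
    span, mean strength, and the implied repeat period 1/freq."""

    freq: float
    start: int
    end: int
    strength: float

    @property
    def period(self) -> float:
        return 1.0 / self.freq

    @property
    def extent(self) -> int:
        return self.end - self.start + 1


def dominant_frequency(
    spec: Spectrum1D,
    exclude_dc: bool = True,
    dc_guard: Optional[int] = None,
) -> Optional[Peak]:
    """Frequency of the largest spectral magnitude.

    ``dc_guard`` leading bins are skipped when ``exclude_dc`` (the DC bin
    and its immediate leakage).  The default guard is 2 bins, widened to
    two DC main-lobe widths (2 * fft_length / lag_support) for spectra
    computed from a zero-padded finite lag window, whose DC energy leaks
    over ~fft_length / support bins.  Ties break toward the smallest
    frequency.  Returns None when nothing is above zero.
    """
    if dc_guard is None:
        dc_guard = 2
        support = int(spec.metadata.get("lag_support", 0))
        if support:
            dc_guard = max(2, int(np.ceil(2.0 * spec.fft_length / support)))
    start = dc_guard if exclude_dc else 0
    vals = spec.values[start:]
    if vals.size == 0 or np.all(vals <= 0.0):
        return None
    i = int(np.argmax(vals))            # argmax takes the first (lowest-freq) tie
    return Peak(float(spec.freqs[start + i]), float(vals[i]))


def _row_peaks(row: np.ndarray, guard: int, height: float, distance: int) -> list[int]:
    """Indices of local maxima above ``height``, ignoring the first
    ``guard`` bins; edge bins (e.g. the Nyquist bin at 0.5) count.
    Peaks closer than ``distance`` bins are thinned to the tallest, which
    suppresses the sidelobe skirt around a strong spectral peak."""
    seg = row[guard:]
    padded = np.concatenate(([-np.inf], seg, [-np.inf]))
    idx, _ = find_peaks(padded, height=height, distance=distance)
    return [int(i) - 1 + guard for i in idx]


def detect_spectral_lines(
    tf: TFPlane,
    strength_threshold: float = 5.0,
    min_extent: int = 20,
    min_freq: float = 0.005,
    min_separation: float = 0.01,
) -> list[SpectralLine]:
    """Link per-position spectral peaks into horizontal lines.

    Per position, local spectral maxima exceeding ``strength_threshold``
    times the plane median are kept; peaks in adjacent rows within one
    frequency bin of each other are linked into a line.  Two guards keep
    the finite-support artifacts of the lag grid out of the line list:
    frequencies below ``min_freq`` are not searched (the zero-padded
    support of each row leaks DC energy into the lowest bins, which would
    otherwise register as spurious ultra-long-period lines), and peaks
    closer than ``min_separation`` (normalized frequency) are thinned to
    the tallest (the sidelobe skirt of a strong line would otherwise spawn
    parallel ghost lines one skirt-ripple apart).  Periodicities closer in
    frequency than ``min_separation`` are reported as one line.  Lines
    shorter than ``min_extent`` positions are dropped; output is sorted by
    mean strength descending, ties by frequency ascending.
    """
    if strength_threshold <= 1.0:
        raise ValueError("strength_threshold must exceed 1")
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    plane = tf.values
    if plane.size == 0:
        return []
    med = float(np.median(plane))
    height = strength_threshold * med
    guard = int(np.searchsorted(tf.freqs, min_freq))
    # each row's finite lag support leaks DC energy over a main lobe of
    # ~ fft_length / support bins; stay two lobes clear of DC
    support = int(tf.metadata.get("lag_support", 0))
    if support:
        guard = max(guard, int(np.ceil(2.0 * tf.fft_length / support)))
    dnu = float(tf.freqs[1] - tf.freqs[0]) if len(tf.freqs) > 1 else 1.0
    distance = max(1, int(round(min_separation / dnu)))

    # greedy row-by-row tracking
    active: list[dict] = []
    finished: list[dict] = []
    for n in range(plane.shape[0]):
        peaks = _row_peaks(plane[n], guard, height, distance)
        unmatched = set(peaks)
        still = []
        for line in active:
            best = None
            for b in unmatched:
                if abs(b - line["bin"]) <= 1 and (best is None or abs(b - line["bin"]) < abs(best - line["bin"])):
                    best = b
            if best is not None:
                unmatched.discard(best)
                line["bin"] = best
                line["rows"].append(n)
                line["bins"].append(best)
                line["strengths"].append(plane[n, best])
                still.append(line)
            else:
                finished.append(line)
        active = still
        for b in unmatched:
            active.append({"bin": b, "rows": [n], "bins": [b],
                           "strengths": [plane[n, b]]})
    finished.extend(active)

    lines: list[SpectralLine] = []
    for tr in finished:
        strengths = np.asarray(tr["strengths"])
        rows = tr["rows"]
        bins = tr["bins"]
        if len(rows) < min_extent:
            continue
        nu = float(tf.freqs[int(np.median(bins))])
        if nu <= 0.0:
            continue
        lines.append(SpectralLine(
            freq=nu,
            start=rows[0] + 1,
            end=rows[-1] + 1,
            strength=float(strengths.mean()),
        ))
    lines.sort(key=lambda l: (-l.strength, l.freq))
    return lines


def lines_to_table(lines: list[SpectralLine], sequence_id: str = "") -> str:
    """Delimited text: id, start, end (1-based inclusive), freq, period,
    strength."""
    out = ["# columns: sequence\tstart\tend\tfreq\tperiod\tstrength",
           "# positions are 1-based inclusive"]
    for l in lines:
        out.append(f"{sequence_id}\t{l.start}\t{l.end}\t{l.freq:.6g}\t{l.period:.6g}\t{l.strength:.6g}")
    return "\n".join(out) + "\n"


def lines_to_bed(lines: list[SpectralLine], sequence_id: str) -> str:
    """BED-style export: 0-based half-open intervals, name = period."""
    out = ["# BED: 0-based half-open"]
    for l in lines:
        out.append(f"{sequence_id}\t{l.start - 1}\t{l.end}\tperiod_{l.period:.4g}\t{l.strength:.6g}")
    return "\n".join(out) + "\n"
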