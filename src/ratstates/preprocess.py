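"""Preprocessing: average reference, zero-phase FIR band-pass, and
behavioural-inactivity segmentation.

The default pipeline mirrors common rodent resting-state practice:
re-reference to the channel average, band-pass 1-40 Hz with a 2000-tap
zero-phase (forward-backward) FIR filter, keep only behavioural-inactivity
intervals of at least 2 s, and concatenate the survivors into one
continuous series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin

from .io import Recording

__all__ = [
    "SegmentSet",
    "EmptySegmentsError",
    "average_reference",
    "bandpass",
    "segment_inactivity",
    "concatenate",
]


class EmptySegmentsError(RuntimeError):
    """No interval satisfied the segmentation rule."""


@dataclass
class SegmentSet:
    """Ordered recording slices plus the source interval of each."""

    segments: list[Recording]
    provenance: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.provenance):
            raise ValueError("provenance must align with segments")
        if self.segments:
            fs0 = self.segments[0].fs
            names0 = self.segments[0].montage.channel_names
            for seg in self.segments:
                if seg.fs != fs0 or seg.montage.channel_names != names0:
                    raise ValueError("segments must share fs and montage")

    @property
    def total_duration_s(self) -> float:
        return sum(seg.duration_s for seg in self.segments)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous channel mean from every sample."""
    return rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 40.0,
             n_taps: int = 2000) -> Recording:
    """Zero-phase FIR band-pass (windowed-sinc design, forward-backward).

    ``n_taps`` is the number of filter coefficients; applying the filter in
    both directions squares its magnitude response and cancels its phase.
    An even tap count is bumped by one so the band-pass has a symmetric
    type-I impulse response.
    """
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist={rec.fs / 2})")
    if n_taps < 3:
        raise ValueError("n_taps must be >= 3")
    numtaps = n_taps if n_taps % 2 == 1 else n_taps + 1
    taps = firwin(numtaps, [lo, hi], pass_zero=False, window="hamming",
                  fs=rec.fs)
    if rec.n_samples <= 3 * numtaps:
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for a "
            f"{numtaps}-tap forward-backward filter"
        )
    return rec.copy(data=filtfilt(taps, [1.0], rec.data, axis=1))


def segment_inactivity(rec: Recording, min_len_s: float = 2.0,
                       inactive_label: str = "inactive") -> SegmentSet:
    """Extract behavioural-inactivity intervals of at least ``min_len_s``.

    Raises
    ------
    EmptySegmentsError
        If no annotated inactivity interval is long enough.
    """
    kept: list[Recording] = []
    prov: list[tuple[float, float]] = []
    for start, end, label in rec.annotations:
        if label != inactive_label or end - start < min_len_s:
            continue
        i0 = int(round(start * rec.fs))
        i1 = min(int(round(end * rec.fs)), rec.n_samples)
        if i1 <= i0:
            continue
        seg = Recording(rec.data[:, i0:i1].copy(), rec.fs, rec.montage)
        kept.append(seg)
        prov.append((start, end))
    if not kept:
        raise EmptySegmentsError(
            f"no '{inactive_label}' interval of >= {min_len_s} s found"
        )
    return SegmentSet(kept, prov)


def concatenate(segs: SegmentSet) -> Recording:
    """Join segments, in order, into one continuous recording.

    No tapering is applied at the seams; downstream clustering operates on
    GFP peaks, not on segment boundaries.
    """
    if not segs.segments:
        raise EmptySegmentsError("cannot concatenate an empty segment set")
    first = segs.segments[0]
    data = np.concatenate([seg.data for seg in segs.segments], axis=1)
    return Recording(data, first.fs, first.montage)
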