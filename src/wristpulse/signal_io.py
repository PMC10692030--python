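"""Pulse-signal container, CSV I/O, band-pass preprocessing, cycle segmentation.

A recording is a single-channel radial-artery pressure waveform sampled
uniformly (the acquisition convention here is a 60 s strip). Segmentation
locates the onset ("foot") of every cardiac cycle; consecutive onsets bound
one cycle, and cycles touching the recording edges are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "PulseSignal", "CycleSegment", "read_signal", "write_signal",
    "detrend_filter", "segment_cycles",
]

MIN_DURATION_S = 2.0  # shortest usable recording
MIN_CYCLE_SAMPLES = 10


@dataclass
class PulseSignal:
    """Uniformly sampled pressure waveform with subject metadata.

    Parameters
    ----------
    samples : ndarray of float
        Pressure values in arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier carried through to feature tables.
    meta : dict
        Optional covariates (group, bnp_level, age, sex, bmi).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("pulse signal must be one-dimensional")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(f"non-finite sample at row {bad[0]}")
        if self.samples.size < MIN_DURATION_S * self.fs:
            raise ValueError(
                f"recording too short: {self.samples.size} samples "
                f"< {MIN_DURATION_S} s at {self.fs} Hz"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class CycleSegment:
    """Half-open sample-index window [start, end) of one cardiac cycle."""

    start: int
    end: int
    samples: np.ndarray  # view of the cycle's samples
    baseline: float      # amplitude at the onset sample

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_CYCLE_SAMPLES:
            raise ValueError(
                f"cycle [{self.start}, {self.end}) shorter than "
                f"{MIN_CYCLE_SAMPLES} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def write_signal(sig: PulseSignal, path: str | Path) -> None:
    """Write a two-column CSV (time_s, amplitude) with a metadata header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={sig.fs} subject={sig.subject_id}\n")
        fh.write("time_s,amplitude\n")
        for t, x in zip(sig.times, sig.samples):
            fh.write(f"{t:.6f},{x:.9g}\n")


def read_signal(path: str | Path, fs: float | None = None) -> PulseSignal:
    """Read a signal CSV written by :func:`write_signal`.

    The sampling rate is taken from the ``# fs=...`` header comment unless
    supplied explicitly; a file with neither is rejected.
    """
    path = Path(path)
    subject_id = ""
    header_fs = None
    rows: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if tok.startswith("fs="):
                        header_fs = float(tok[3:])
                    elif tok.startswith("subject="):
                        subject_id = tok[8:]
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split(",")
            try:
                val = float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"unparseable row {lineno}: {line!r}") from exc
            if not np.isfinite(val):
                raise ValueError(f"non-finite amplitude at row {lineno}")
            rows.append(val)
    rate = fs if fs is not None else header_fs
    if rate is None:
        raise ValueError(f"{path}: sampling rate missing from header and not supplied")
    return PulseSignal(np.array(rows), fs=rate, subject_id=subject_id)


def detrend_filter(
    sig: PulseSignal, low_cut: float = 0.5, high_cut: float = 20.0
) -> PulseSignal:
    """Zero-phase Butterworth band-pass; removes DC drift and high-frequency noise.

    The forward-backward (``sosfiltfilt``) pass has zero group delay, so
    fiducial landmark times are not shifted by the filter.
    """
    nyq = sig.fs / 2.0
    if not (0 <= low_cut < high_cut < nyq):
        raise ValueError(
            f"invalid band [{low_cut}, {high_cut}] Hz for fs={sig.fs} Hz"
        )
    if low_cut == 0:
        sos = sps.butter(3, high_cut / nyq, btype="low", output="sos")
        filtered = sps.sosfiltfilt(sos, sig.samples - sig.samples.mean())
    else:
        sos = sps.butter(3, [low_cut / nyq, high_cut / nyq], btype="band", output="sos")
        filtered = sps.sosfiltfilt(sos, sig.samples)
    return PulseSignal(filtered, fs=sig.fs, subject_id=sig.subject_id, meta=dict(sig.meta))


def _onset_indices(x: np.ndarray, fs: float) -> np.ndarray:
    """Pulse-onset (foot) detection: peaks of the first derivative, then
    backtracking to the nearest preceding local minimum.

    Scale-free: derivative-peak threshold is relative to the largest upstroke,
    so amplitude scaling does not change the detected onsets.
    """
    dx = np.gradient(x)
    top = dx.max()
    if top <= 0 or np.ptp(x) == 0:
        raise ValueError("no upstrokes found (flat or monotone non-increasing signal)")
    # physiological refractory window: cycles are rarely shorter than 0.3 s
    min_dist = max(1, int(round(0.3 * fs)))
    peaks, _ = sps.find_peaks(dx, height=0.4 * top, distance=min_dist)
    onsets = []
    for p in peaks:
        i = p
        while i > 0 and x[i - 1] <= x[i]:
            i -= 1
        onsets.append(i)
    onsets = np.unique(onsets)
    return onsets


def segment_cycles(sig: PulseSignal) -> list[CycleSegment]:
    """Partition the recording into cardiac cycles between consecutive onsets.

    The first and last onsets bound incomplete edge cycles, which are dropped.
    Raises if fewer than 3 cycles are found (unusable recording).
    """
    onsets = _onset_indices(sig.samples, sig.fs)
    segments: list[CycleSegment] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a < MIN_CYCLE_SAMPLES:
            continue
        segments.append(
            CycleSegment(int(a), int(b), sig.samples[a:b], float(sig.samples[a]))
        )
    if len(segments) < 3:
        raise ValueError(
            f"only {len(segments)} cycles detected; recording unusable"
        )
    return segments
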