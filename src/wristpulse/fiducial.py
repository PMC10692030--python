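"""Fiducial-point detection and time-domain pulse features.

One cardiac cycle carries seven landmarks: onset A, main (systolic) wave peak
B, main wave gap C, tidal wave peak D, dicrotic notch E, dicrotic wave peak F
and end point G. From these the classical 21 time-domain features are
derived: five amplitudes (h1..h5, measured relative to the onset baseline),
eight durations (t1..t5, cycle length T, and the 1/3 and 1/5 pulse widths
w1, w2) and eight proportional features.

The 1/3 (1/5) pulse width is the total time the waveform stays within one
third (one fifth) of the main-wave height below the peak, i.e. above the
level (1 - 1/3)*h1 over baseline; this convention makes w1 > w2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy import signal as sps

from wristpulse.signal_io import CycleSegment, PulseSignal, segment_cycles, detrend_filter

__all__ = [
    "FiducialPoints", "TimeDomainFeatures", "detect_fiducials", "pulse_width",
    "compute_features", "aggregate_subject", "extract_subject_features",
]

# dicrotic-notch search window as fractions of the cycle after the main peak
NOTCH_WINDOW = (0.15, 0.60)


@dataclass
class FiducialPoints:
    """Landmark times (s, from cycle onset) and baseline-relative amplitudes.

    ``t_c``/``t_d`` may be inferred from an inflection of the first
    derivative when the tidal wave merges into the main wave (no distinct
    extrema); ``inferred_cd`` flags that case. Missing landmarks are NaN with
    presence flags False.
    """

    t_a: float
    t_b: float
    t_c: float
    t_d: float
    t_e: float
    t_f: float
    t_g: float
    amp_a: float
    amp_b: float
    amp_c: float
    amp_d: float
    amp_e: float
    amp_f: float
    amp_g: float
    has_c: bool = True
    has_d: bool = True
    has_f: bool = True
    inferred_cd: bool = False


_RATIO_DEFS = {
    "t1_T": ("t1", "T"), "t1_t4": ("t1", "t4"), "t5_t4": ("t5", "t4"),
    "w1_T": ("w1", "T"), "w2_T": ("w2", "T"),
    "h3_h1": ("h3", "h1"), "h4_h1": ("h4", "h1"), "h5_h1": ("h5", "h1"),
}


@dataclass
class TimeDomainFeatures:
    h1: float
    h2: float
    h3: float
    h4: float
    h5: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    T: float
    w1: float
    w2: float
    t1_T: float
    t1_t4: float
    t5_t4: float
    w1_T: float
    w2_T: float
    h3_h1: float
    h4_h1: float
    h5_h1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _local_extrema(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Strict local maxima and minima indices (plateau-free interior extrema)."""
    d = np.sign(np.diff(x))
    # carry the previous non-zero slope across flat runs
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    ext = np.flatnonzero(d[1:] != d[:-1]) + 1
    maxima = [int(i) for i in ext if d[i - 1] > 0]
    minima = [int(i) for i in ext if d[i - 1] < 0]
    return maxima, minima


def detect_fiducials(cycle: CycleSegment, fs: float) -> FiducialPoints | None:
    """Locate landmarks A-G in one segmented cycle.

    B is the global maximum; E is the most prominent local minimum in a
    conventional systole/diastole window after B; F is the first local
    maximum after E. C and D are the local minimum/maximum pair between B
    and E when distinct extrema exist, otherwise they are placed at the
    strongest decelerating-to-accelerating inflection of the first
    derivative and flagged as inferred. Amplitudes are relative to the value
    at the onset A. Returns None when no dicrotic notch can be located
    (cycle unusable).
    """
    x = cycle.samples
    n = x.size
    base = float(x[0])
    i_b = int(np.argmax(x))  # earliest index wins on ties (argmax convention)

    lo = i_b + max(1, int(round(NOTCH_WINDOW[0] * n)))
    hi = min(n - 2, int(round(NOTCH_WINDOW[1] * n)))
    if lo >= hi:
        return None
    inv = -x[lo:hi + 1]
    cand, props = sps.find_peaks(inv, prominence=0)
    if cand.size == 0:
        return None
    i_e = int(cand[np.argmax(props["prominences"])]) + lo

    maxima, minima = _local_extrema(x)
    f_cands = [i for i in maxima if i > i_e]
    i_f = f_cands[0] if f_cands else None

    d_cands = [i for i in maxima if i_b < i < i_e]
    i_d = d_cands[-1] if d_cands else None
    c_cands = [i for i in minima if i_b < i < (i_d if i_d is not None else i_e)]
    i_c = c_cands[0] if c_cands else None

    inferred = False
    if i_c is None or i_d is None:
        # tidal wave merged into the main wave: place C = D at the strongest
        # negative-to-positive inflection of dx (a local minimum of the first
        # derivative) between B and E
        dx = np.gradient(x)
        seg = dx[i_b + 1:i_e]
        if seg.size >= 3:
            mins, props = sps.find_peaks(-seg, prominence=0)
            if mins.size:
                j = int(mins[np.argmax(props["prominences"])]) + i_b + 1
                i_c = i_d = j
                inferred = True
        if i_c is None or i_d is None:
            return FiducialPoints(
                t_a=0.0, t_b=i_b / fs, t_c=np.nan, t_d=np.nan, t_e=i_e / fs,
                t_f=(i_f / fs if i_f is not None else np.nan), t_g=(n - 1) / fs,
                amp_a=0.0, amp_b=float(x[i_b]) - base, amp_c=np.nan, amp_d=np.nan,
                amp_e=float(x[i_e]) - base,
                amp_f=(float(x[i_f]) - base if i_f is not None else np.nan),
                amp_g=float(x[n - 1]) - base,
                has_c=False, has_d=False, has_f=i_f is not None,
            )

    return FiducialPoints(
        t_a=0.0, t_b=i_b / fs, t_c=i_c / fs, t_d=i_d / fs, t_e=i_e / fs,
        t_f=(i_f / fs if i_f is not None else np.nan), t_g=(n - 1) / fs,
        amp_a=0.0,
        amp_b=float(x[i_b]) - base,
        amp_c=float(x[i_c]) - base,
        amp_d=float(x[i_d]) - base,
        amp_e=float(x[i_e]) - base,
        amp_f=(float(x[i_f]) - base if i_f is not None else np.nan),
        amp_g=float(x[n - 1]) - base,
        has_f=i_f is not None,
        inferred_cd=inferred,
    )


def pulse_width(
    cycle: CycleSegment, h1: float, fraction: float, fs: float,
    baseline: float | None = None,
) -> float:
    """Total time (s) the baseline-corrected waveform is >= (1 - fraction)*h1.

    Threshold crossings are located by linear interpolation between samples,
    so the width is a sub-sample quantity. ``fraction`` = 1/3 gives the 1/3
    pulse width w1, 1/5 gives w2.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if h1 <= 0:
        raise ValueError("main-wave amplitude h1 must be positive")
    base = float(cycle.samples[0]) if baseline is None else baseline
    y = cycle.samples - base
    thr = (1.0 - fraction) * h1
    above = y >= thr
    if not above.any():
        raise ValueError("waveform never reaches the width threshold (inconsistent h1)")
    width_samples = 0.0
    n = y.size
    # runs of samples above threshold, extended to interpolated crossings
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    ends = np.flatnonzero(above & ~np.roll(above, -1))
    if above[0]:
        starts = np.concatenate(([0], starts[starts != 0]))
    if above[-1]:
        ends = np.concatenate((ends[ends != n - 1], [n - 1]))
    for s, e in zip(starts, ends):
        left = float(s)
        if s > 0:
            left = s - (y[s] - thr) / (y[s] - y[s - 1])
        right = float(e)
        if e < n - 1:
            right = e + (y[e] - thr) / (y[e] - y[e + 1])
        width_samples += right - left
    return width_samples / fs


def compute_features(
    fp: FiducialPoints, cycle: CycleSegment, fs: float
) -> TimeDomainFeatures:
    """Derive the 21 time-domain features from one cycle's landmarks."""
    T = cycle.n_samples / fs
    h1 = fp.amp_b
    w1 = pulse_width(cycle, h1, 1 / 3, fs)
    w2 = pulse_width(cycle, h1, 1 / 5, fs)
    t4 = fp.t_e
    t5 = T - t4
    vals = dict(
        h1=h1, h2=fp.amp_c, h3=fp.amp_d, h4=fp.amp_e, h5=fp.amp_f,
        t1=fp.t_b, t2=fp.t_c, t3=fp.t_d, t4=t4, t5=t5, T=T, w1=w1, w2=w2,
    )
    for name, (num, den) in _RATIO_DEFS.items():
        vals[name] = vals[num] / vals[den]
    return TimeDomainFeatures(**vals)


def aggregate_subject(features: list[TimeDomainFeatures]) -> TimeDomainFeatures:
    """Per-subject summary: feature-wise median over usable cycles.

    The median is robust to the occasional mis-segmented or artefactual
    cycle. Requires at least 3 usable cycles.
    """
    if len(features) < 3:
        raise ValueError(f"only {len(features)} usable cycles; subject excluded")
    arr = {
        name: np.nanmedian([getattr(f, name) for f in features])
        for name in (f.name for f in dc_fields(TimeDomainFeatures))
    }
    return TimeDomainFeatures(**arr)


def extract_subject_features(
    sig: PulseSignal,
    band: tuple[float, float] | None = (0.5, 20.0),
) -> tuple[TimeDomainFeatures, dict]:
    """Full per-subject pipeline: (optional) band-pass, segment, detect, aggregate.

    Returns the aggregated features and a QC dict with cycle counts.
    Pass ``band=None`` to skip filtering (already-clean signals).
    """
    work = detrend_filter(sig, *band) if band is not None else sig
    segments = segment_cycles(work)
    per_cycle = []
    n_unusable = 0
    n_inferred = 0
    for seg in segments:
        fp = detect_fiducials(seg, sig.fs)
        if fp is None or not (fp.has_c and fp.has_d and fp.has_f):
            n_unusable += 1
            continue
        if fp.inferred_cd:
            n_inferred += 1
        per_cycle.append(compute_features(fp, seg, sig.fs))
    if n_unusable:
        warnings.warn(
            f"{sig.subject_id or 'subject'}: {n_unusable}/{len(segments)} "
            "cycles unusable", stacklevel=2,
        )
    agg = aggregate_subject(per_cycle)
    qc = {
        "n_cycles": len(segments),
        "n_usable": len(per_cycle),
        "n_unusable": n_unusable,
        "n_inferred_cd": n_inferred,
    }
    return agg, qc
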