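"""Synthetic wrist-pulse cohorts with per-cycle ground truth.

No public pulse dataset accompanies the clinical study design this package
supports, so every downstream stage is exercised on simulated recordings.
Two generators are provided:

* :func:`generate_signal` — a waveform-level simulator: each cardiac cycle is
  a sum of three Gaussian bumps (systolic/main wave, tidal wave, dicrotic
  wave) whose superposition produces the seven classical landmarks A-G,
  including the dicrotic notch. Cycles with jittered periods are concatenated
  end-to-start, then white noise and sinusoidal baseline wander are added.
  Ground-truth landmark positions are recorded per cycle.

* :func:`generate_feature_table` — a feature-level simulator: per-subject
  feature vectors drawn around group-specific medians (with spreads set from
  the interquartile ranges of the BNP-stratified clinical groups), used to
  test the classification and reporting stages without signal processing.

Group 1 = normal BNP, Group 2 = moderately elevated, Group 3 = highest; the
group presets move the waveform in the clinically observed direction (Group 3:
lower dicrotic-notch ratio h4/h1, shorter cycle T, narrower pulse widths).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from wristpulse.signal_io import PulseSignal

__all__ = [
    "CycleShape", "CohortConfig", "GroundTruth", "CycleTruth",
    "GROUP_SHAPES", "GROUP_PERIODS", "TIME_DOMAIN_FEATURES", "MSE_FEATURES",
    "GENERAL_INFO", "generate_cycle", "generate_signal",
    "generate_feature_table", "shape_features", "default_feature_presets",
]


@dataclass(frozen=True)
class CycleShape:
    """One cardiac cycle as a sum of three Gaussian pressure components.

    Centers ``mu_*`` and widths ``sigma_*`` are fractions of the cycle;
    amplitudes are in arbitrary pressure units. The systolic component must
    dominate (its peak is the global maximum of the cycle).
    """

    a_sys: float
    mu_sys: float
    sigma_sys: float
    a_tidal: float
    mu_tidal: float
    sigma_tidal: float
    a_dicrotic: float
    mu_dicrotic: float
    sigma_dicrotic: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_sys > self.a_tidal >= 0 and self.a_sys > self.a_dicrotic >= 0):
            raise ValueError("systolic amplitude must dominate tidal and dicrotic")
        if not (0 < self.mu_sys < self.mu_tidal < self.mu_dicrotic < 1):
            raise ValueError("component centers must satisfy 0 < sys < tidal < dicrotic < 1")
        if min(self.sigma_sys, self.sigma_tidal, self.sigma_dicrotic) <= 0:
            raise ValueError("component widths must be positive")

    def evaluate(self, frac: np.ndarray) -> np.ndarray:
        """Pressure at cycle fraction(s) ``frac`` in [0, 1)."""
        frac = np.asarray(frac, dtype=float)
        y = np.full_like(frac, self.baseline)
        for a, mu, sig in (
            (self.a_sys, self.mu_sys, self.sigma_sys),
            (self.a_tidal, self.mu_tidal, self.sigma_tidal),
            (self.a_dicrotic, self.mu_dicrotic, self.sigma_dicrotic),
        ):
            y = y + a * np.exp(-0.5 * ((frac - mu) / sig) ** 2)
        return y


# Group presets: fitted so that a dense evaluation of each shape reproduces the
# group's median waveform proportions (t1/T, notch time t4/T, h4/h1, w1/T,
# w2/T) for the three BNP strata, with physiological secondary-wave heights.
GROUP_SHAPES: dict[int, CycleShape] = {
    1: CycleShape(1.0, 0.1794, 0.0603, 0.6746, 0.3229, 0.0642, 0.5929, 0.5648, 0.1462),
    2: CycleShape(1.0, 0.1735, 0.0618, 0.6463, 0.3161, 0.0605, 0.5804, 0.5508, 0.1433),
    3: CycleShape(1.0, 0.1902, 0.0562, 0.7080, 0.3301, 0.0570, 0.5571, 0.5922, 0.1628),
}

# Median cardiac-cycle period per group (seconds).
GROUP_PERIODS: dict[int, float] = {1: 0.761, 2: 0.796, 3: 0.717}

TIME_DOMAIN_FEATURES = [
    "h1", "h2", "h3", "h4", "h5",
    "t1", "t2", "t3", "t4", "t5", "T", "w1", "w2",
    "t1_T", "t1_t4", "t5_t4", "w1_T", "w2_T", "h3_h1", "h4_h1", "h5_h1",
]
MSE_FEATURES = ["MSE_1", "MSE_2", "MSE_3", "MSE_4", "MSE_5"]
GENERAL_INFO = ["age", "sex", "bmi"]

# (median, Q1, Q3) per group for the features with published group contrasts.
_QUARTILE_PRESETS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "t5":   ((0.413, 0.341, 0.489), (0.443, 0.376, 0.509), (0.391, 0.317, 0.470)),
    "T":    ((0.761, 0.680, 0.843), (0.796, 0.726, 0.857), (0.717, 0.643, 0.846)),
    "h4_h1": ((0.478, 0.412, 0.530), (0.468, 0.412, 0.518), (0.419, 0.380, 0.503)),
    "t1_T": ((0.190, 0.169, 0.214), (0.183, 0.164, 0.205), (0.200, 0.175, 0.223)),
    "w1":   ((0.191, 0.170, 0.213), (0.196, 0.165, 0.222), (0.183, 0.135, 0.209)),
    "w2":   ((0.143, 0.122, 0.165), (0.148, 0.115, 0.172), (0.130, 0.100, 0.161)),
    "w1_T": ((0.255, 0.229, 0.279), (0.250, 0.217, 0.275), (0.240, 0.209, 0.266)),
    "w2_T": ((0.189, 0.167, 0.214), (0.185, 0.159, 0.213), (0.175, 0.149, 0.199)),
    "MSE_1": ((0.035, 0.029, 0.039), (0.033, 0.025, 0.037), (0.035, 0.028, 0.040)),
    "MSE_2": ((0.071, 0.059, 0.080), (0.067, 0.050, 0.074), (0.070, 0.057, 0.083)),
    "MSE_3": ((0.108, 0.090, 0.122), (0.102, 0.076, 0.114), (0.107, 0.087, 0.127)),
    "MSE_4": ((0.147, 0.122, 0.166), (0.138, 0.103, 0.155), (0.146, 0.118, 0.173)),
    "MSE_5": ((0.187, 0.154, 0.212), (0.176, 0.130, 0.196), (0.185, 0.149, 0.219)),
}

# Covariate distributions per group: age and BMI as mean +/- sd, sex as the
# male proportion (clinical cohort demographics).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ((66.73, 9.727), (73.87, 8.446), (72.84, 10.053)),
    "bmi": ((24.934, 3.608), (24.939, 3.960), (23.737, 3.062)),
    "male_prop": (0.450, 0.471, 0.518),
}

# IQR of a normal distribution spans 1.349 standard deviations.
_IQR_TO_SD = 1.0 / 1.349
# relative spread for features without published quartiles
_DEFAULT_CV = 0.08


def shape_features(shape: CycleShape, period: float, n_grid: int = 20001) -> dict:
    """Time-domain features of the analytic cycle on a dense grid (oracle).

    Used both as the per-subject ground-truth feature vector and, at high
    ``n_grid``, as an independent reference in tests.
    """
    frac = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    y = shape.evaluate(frac)
    d = np.sign(np.diff(y))
    ext = np.flatnonzero(d[1:] != d[:-1]) + 1
    kinds = ["max" if d[i - 1] > 0 else "min" for i in ext]
    base = y[0]
    i_b = int(np.argmax(y))
    maxima = [i for i, k in zip(ext, kinds) if k == "max"]
    minima = [i for i, k in zip(ext, kinds) if k == "min"]
    i_e = next((i for i in minima if shape.mu_tidal < frac[i] < shape.mu_dicrotic), None)
    if i_e is None:
        raise ValueError("shape has no dicrotic notch on the dense grid")
    i_f = next((i for i in maxima if i > i_e), None)
    i_d = next((i for i in reversed(maxima) if i_b < i < i_e), None)
    i_c = next((i for i in minima if i_b < i < (i_d if i_d is not None else i_e)), None)
    h1 = y[i_b] - base
    feats = {
        "h1": h1,
        "h2": (y[i_c] - base) if i_c is not None else np.nan,
        "h3": (y[i_d] - base) if i_d is not None else np.nan,
        "h4": y[i_e] - base,
        "h5": (y[i_f] - base) if i_f is not None else np.nan,
        "t1": frac[i_b] * period,
        "t2": frac[i_c] * period if i_c is not None else np.nan,
        "t3": frac[i_d] * period if i_d is not None else np.nan,
        "t4": frac[i_e] * period,
        "t5": (1.0 - frac[i_e]) * period,
        "T": period,
    }
    for fraction, name in ((1 / 3, "w1"), (1 / 5, "w2")):
        thr = base + (1 - fraction) * h1
        feats[name] = float((y >= thr).sum()) / n_grid * period
    feats["t1_T"] = feats["t1"] / period
    feats["t1_t4"] = feats["t1"] / feats["t4"]
    feats["t5_t4"] = feats["t5"] / feats["t4"]
    feats["w1_T"] = feats["w1"] / period
    feats["w2_T"] = feats["w2"] / period
    feats["h3_h1"] = feats["h3"] / h1
    feats["h4_h1"] = feats["h4"] / h1
    feats["h5_h1"] = feats["h5"] / h1
    return feats


def default_feature_presets() -> dict[str, tuple[tuple[float, float], ...]]:
    """Per-feature, per-group (median, sd) presets for the table generator.

    Features with published group quartiles use those medians and
    IQR-derived sds; the remaining features take medians consistent with the
    group waveform shapes (so the whole vector describes one coherent pulse)
    and a common relative spread.
    """
    presets: dict[str, tuple[tuple[float, float], ...]] = {}
    shape_feats = {
        g: shape_features(GROUP_SHAPES[g], GROUP_PERIODS[g], n_grid=4001)
        for g in (1, 2, 3)
    }
    for name in TIME_DOMAIN_FEATURES + MSE_FEATURES:
        if name in _QUARTILE_PRESETS:
            presets[name] = tuple(
                (m, (q3 - q1) * _IQR_TO_SD) for m, q1, q3 in _QUARTILE_PRESETS[name]
            )
        else:
            vals = [float(shape_feats[g][name]) for g in (1, 2, 3)]
            presets[name] = tuple((v, abs(v) * _DEFAULT_CV) for v in vals)
    return presets


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for both generators.

    ``n_per_group`` defaults to the clinical group sizes (249, 85, 85);
    recordings default to 60 s. The sampling rate is a convention (the
    acquisition hardware's rate is not public); 200 Hz resolves every
    landmark comfortably.
    """

    n_per_group: tuple[int, int, int] = (249, 85, 85)
    fs: float = 200.0
    duration: float = 60.0
    periods: dict[int, float] = field(default_factory=lambda: dict(GROUP_PERIODS))
    period_cv: float = 0.04          # beat-to-beat period jitter (CV)
    subject_period_cv: float = 0.08  # between-subject mean-period spread (CV)
    amp_jitter: float = 0.05         # between-subject tidal/dicrotic amplitude CV
    noise_sd: float = 0.02           # additive white noise, fraction of a_sys
    wander_amp: float = 0.10         # baseline wander amplitude, fraction of a_sys
    wander_freq: float = 0.2         # baseline wander frequency (Hz)
    shapes: dict[int, CycleShape] = field(default_factory=lambda: dict(GROUP_SHAPES))
    feature_presets: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=default_feature_presets
    )
    covariates: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 50:
            raise ValueError("sampling rate below 50 Hz cannot resolve landmarks")
        if self.duration <= 2 * max(self.periods.values()):
            raise ValueError("duration must exceed two cycle periods")
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs at least one subject")


@dataclass
class CycleTruth:
    """Ground-truth landmark sample indices (absolute) for one cycle."""

    start: int
    end: int  # half-open
    fiducials: dict[str, int | None]  # A..G -> absolute index


@dataclass
class GroundTruth:
    """Per-subject annotations emitted alongside a synthetic signal."""

    group: int
    period: float                 # subject mean cycle period (s)
    shape: CycleShape
    cycles: list[CycleTruth]
    features: dict               # dense-grid feature vector of the subject shape

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group": self.group,
            "period": self.period,
            "features": {k: float(v) for k, v in self.features.items()},
            "cycles": [
                {"start": c.start, "end": c.end,
                 "fiducials": {k: (None if v is None else int(v))
                               for k, v in c.fiducials.items()}}
                for c in self.cycles
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _cycle_truth(wave: np.ndarray, shape: CycleShape) -> dict[str, int | None]:
    """Landmarks of one sampled cycle: extrema of the discrete waveform."""
    n = wave.size
    d = np.sign(np.diff(wave))
    ext = np.flatnonzero(d[1:] != d[:-1]) + 1
    kinds = ["max" if d[i - 1] > 0 else "min" for i in ext]
    maxima = [int(i) for i, k in zip(ext, kinds) if k == "max"]
    minima = [int(i) for i, k in zip(ext, kinds) if k == "min"]
    i_b = int(np.argmax(wave))
    frac = np.arange(n) / n
    i_e = next((i for i in minima if shape.mu_tidal < frac[i] < shape.mu_dicrotic), None)
    i_f = next((i for i in maxima if i_e is not None and i > i_e), None)
    i_d = next((i for i in reversed(maxima) if i_e is not None and i_b < i < i_e), None)
    i_c = next(
        (i for i in minima
         if i_b < i < (i_d if i_d is not None else (i_e if i_e is not None else n))),
        None,
    )
    return {"A": 0, "B": i_b, "C": i_c, "D": i_d, "E": i_e, "F": i_f, "G": n - 1}


def generate_cycle(
    shape: CycleShape, period: float, fs: float
) -> tuple[np.ndarray, dict[str, int | None]]:
    """Sample one cycle of ``shape`` and return (waveform, landmark indices).

    The cycle spans ``round(period * fs)`` samples at fractions i/n of the
    cycle, so concatenated cycles never drift against the sample clock.
    """
    n = int(round(period * fs))
    if n < 10:
        raise ValueError(f"cycle of {n} samples is unresolvable (period*fs < 10)")
    wave = shape.evaluate(np.arange(n) / n)
    return wave, _cycle_truth(wave, shape)


def _subject_shape(shape: CycleShape, rng: np.random.Generator, cv: float) -> CycleShape:
    """Between-subject morphology variation: log-normal scaling of the
    secondary-wave amplitudes (kept below the systolic amplitude)."""
    if cv <= 0:
        return shape
    f_t = float(np.exp(rng.normal(0.0, cv)))
    f_d = float(np.exp(rng.normal(0.0, cv)))
    return replace(
        shape,
        a_tidal=min(shape.a_tidal * f_t, 0.95 * shape.a_sys),
        a_dicrotic=min(shape.a_dicrotic * f_d, 0.95 * shape.a_sys),
    )


def generate_signal(
    config: CohortConfig,
    group: int,
    seed: int | None = None,
    subject_id: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[PulseSignal, GroundTruth]:
    """Simulate one subject's recording with per-cycle ground truth.

    Jittered cycles are concatenated end-to-start, then additive white
    Gaussian noise and a single-frequency sinusoidal baseline wander are
    superimposed, and the strip is trimmed to the configured duration.
    Ground truth is kept only for cycles that lie entirely inside the strip.
    """
    if group not in config.shapes:
        raise ValueError(f"unknown group {group}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = _subject_shape(config.shapes[group], rng, config.amp_jitter)
    period = config.periods[group] * float(np.exp(rng.normal(0.0, config.subject_period_cv)))
    n_total = int(round(config.duration * config.fs))

    pieces: list[np.ndarray] = []
    cycles: list[CycleTruth] = []
    pos = 0
    while pos < n_total:
        p_k = max(0.3, float(rng.normal(period, config.period_cv * period)))
        wave, fid = generate_cycle(shape, p_k, config.fs)
        if pos + wave.size <= n_total:
            cycles.append(CycleTruth(
                start=pos, end=pos + wave.size,
                fiducials={k: (None if v is None else v + pos) for k, v in fid.items()},
            ))
        pieces.append(wave)
        pos += wave.size
    x = np.concatenate(pieces)[:n_total]

    a = shape.a_sys
    t = np.arange(n_total) / config.fs
    if config.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + config.wander_amp * a * np.sin(2 * np.pi * config.wander_freq * t + phase)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd * a, n_total)

    sig = PulseSignal(x, fs=config.fs, subject_id=subject_id,
                      meta={"group": group})
    truth = GroundTruth(
        group=group, period=period, shape=shape, cycles=cycles,
        features=shape_features(shape, period, n_grid=4001),
    )
    return sig, truth


def generate_feature_table(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Sample a per-subject feature table with group labels and covariates.

    Each feature is drawn from a normal distribution centred on its group
    median (so sample medians converge to the presets); sex is Bernoulli,
    age and BMI are normal, clipped to plausible ranges. Columns:
    subject_id, group, age, sex (male=1), bmi, the 21 time-domain features,
    MSE_1..MSE_5.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for g in (1, 2, 3):
        n = config.n_per_group[g - 1]
        age_m, age_sd = config.covariates["age"][g - 1]
        bmi_m, bmi_sd = config.covariates["bmi"][g - 1]
        male_p = config.covariates["male_prop"][g - 1]
        block = {
            "subject_id": [f"G{g}S{i:04d}" for i in range(n)],
            "group": np.full(n, g),
            "age": np.clip(rng.normal(age_m, age_sd, n), 18, 100),
            "sex": (rng.uniform(size=n) < male_p).astype(int),
            "bmi": np.clip(rng.normal(bmi_m, bmi_sd, n), 12, 60),
        }
        for name in TIME_DOMAIN_FEATURES + MSE_FEATURES:
            med, sd = config.feature_presets[name][g - 1]
            block[name] = rng.normal(med, sd, n) if sd > 0 else np.full(n, med)
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)
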