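"""Synthetic 4 Hz FHR recordings with controllable physiology and defects.

The generator emulates the qualitative structure of an intrapartum FHR
trace: a baseline level (normal around 140 bpm, distressed shifted lower),
band-limited beat-to-beat variability, transient accelerations, and
decelerations (deeper and more frequent under distress).  On top of the
clean physiology it injects exactly the artifact types the cleaning chain
targets — zero-valued dropouts (short and long runs, optionally touching
the recording edges), non-physiologic outliers (< 50 or > 200 bpm) and
> 25 bpm spikes — and returns a ledger of every injected defect so tests
can cross-check the cleaner's provenance counts against ground truth.

The distress signature is purely qualitative (level, variability,
deceleration changes scaled by a single ``class_separation`` knob); it makes
no attempt to match the distributional statistics of any clinical database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .record_io import ClassLabel, CTGRecord


@dataclass(frozen=True)
class FHRSimConfig:
    """Generation parameters for one cohort.

    Rates are expected defect counts per 10 minutes of recording.  The
    default duration (40 min) leaves room for the 20-min stage-1 window plus
    two 5-min backward slices and for the stage-2 window, even after some
    samples are lost to gap deletion and edge trimming.
    """

    duration_s: float = 2400.0
    fs: float = 4.0
    baseline_bpm: float = 140.0
    variability_bpm: float = 10.0
    n_accels: int = 4
    n_decels: int = 0
    accel_height_bpm: float = 15.0
    decel_depth_bpm: float = 30.0
    dropout_per_10min: float = 1.0
    outlier_per_10min: float = 1.0
    spike_per_10min: float = 1.0
    edge_zero_probability: float = 0.5
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration_s * fs must be integral")
        if min(self.dropout_per_10min, self.outlier_per_10min,
               self.spike_per_10min) < 0:
            raise ConfigError("defect rates must be >= 0")
        if not 0 <= self.edge_zero_probability <= 1:
            raise ConfigError("edge_zero_probability must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


# Distressed-class parameter offsets at class_separation = 1: a lower, less
# variable baseline with recurrent deep decelerations — the qualitative CTG
# correlates of fetal compromise.
_DISTRESS_BASELINE_DROP = 20.0
_DISTRESS_VARIABILITY_DROP = 5.0
_DISTRESS_EXTRA_DECELS = 6
_DISTRESS_EXTRA_DEPTH = 10.0


def distressed_config(config: FHRSimConfig) -> FHRSimConfig:
    """The distressed-class generation parameters implied by a normal config."""
    s = config.class_separation
    return replace(
        config,
        baseline_bpm=config.baseline_bpm - s * _DISTRESS_BASELINE_DROP,
        variability_bpm=max(2.0, config.variability_bpm - s * _DISTRESS_VARIABILITY_DROP),
        n_decels=config.n_decels + int(round(s * _DISTRESS_EXTRA_DECELS)),
        decel_depth_bpm=config.decel_depth_bpm + s * _DISTRESS_EXTRA_DEPTH,
    )


@dataclass
class Defect:
    """One injected artifact: kind in {short_gap, long_gap, edge_gap, outlier, spike}."""

    kind: str
    start: int
    length: int


def _clean_physiology(config: FHRSimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    fs = config.fs
    # slow baseline wander plus band-limited short-term variability
    wander = gaussian_filter1d(rng.standard_normal(n), sigma=120 * fs, mode="reflect")
    wander *= 5.0 / max(wander.std(), 1e-9)
    variability = gaussian_filter1d(rng.standard_normal(n), sigma=3.0, mode="reflect")
    variability *= (config.variability_bpm / 2.0) / max(variability.std(), 1e-9)
    x = config.baseline_bpm + wander + variability

    def add_events(count: int, amplitude: float, sign: float) -> None:
        for _ in range(count):
            center = rng.integers(0, n)
            width = rng.uniform(15.0, 30.0) * fs  # 15-30 s std
            t = np.arange(n)
            bump = amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)
            x[:] = x + sign * bump

    add_events(config.n_accels, config.accel_height_bpm, +1.0)
    add_events(config.n_decels, config.decel_depth_bpm, -1.0)
    return np.clip(x, 55.0, 195.0)


def _free_slot(
    rng: np.random.Generator,
    n: int,
    length: int,
    occupied: list[tuple[int, int]],
    margin: int = 40,
    n_tries: int = 200,
) -> int | None:
    """A start index whose [start-margin, start+length+margin) span is free."""
    for _ in range(n_tries):
        start = int(rng.integers(margin, n - length - margin))
        if all(
            start + length + margin <= s or start >= s + l + margin
            for s, l in occupied
        ):
            occupied.append((start, length))
            return start
    return None


def simulate_record(
    config: FHRSimConfig,
    label: ClassLabel = ClassLabel.NORMAL,
    record_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> tuple[CTGRecord, list[Defect]]:
    """Generate one labeled record plus the ledger of injected defects.

    The distressed physiology offsets are applied by the caller (see
    ``simulate_cohort`` / ``distressed_config``); here ``config`` is taken
    as-is and only the pH is drawn consistently with ``label``
    (<= 7.15 iff distressed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    x = _clean_physiology(config, rng)
    ledger: list[Defect] = []
    occupied: list[tuple[int, int]] = []
    per10 = config.duration_s / 600.0

    # interior zero runs: 70% short (interpolated), 30% long (deleted)
    for _ in range(int(rng.poisson(config.dropout_per_10min * per10))):
        if rng.random() < 0.7:
            length = int(rng.integers(2, 40))      # <= 15 s: interpolation path
            kind = "short_gap"
            start = _free_slot(rng, n, length, occupied)
        else:
            length = int(rng.integers(61, 140))    # > 15 s: deletion path
            kind = "long_gap"
            # deleting the run splices its two ends together; only place the
            # gap where the splice stays well under the 25-bpm spike trigger
            start = None
            for _try in range(50):
                cand = _free_slot(rng, n, length, occupied)
                if cand is None:
                    break
                if abs(x[cand - 1] - x[cand + length]) <= 20.0:
                    start = cand
                    break
                occupied.remove((cand, length))
        if start is None:
            continue
        x[start : start + length] = 0.0
        ledger.append(Defect(kind, start, length))

    # out-of-range outliers: brief excursions below 50 or above 200 bpm
    for _ in range(int(rng.poisson(config.outlier_per_10min * per10))):
        length = int(rng.integers(1, 4))
        start = _free_slot(rng, n, length, occupied)
        if start is None:
            continue
        value = rng.uniform(20.0, 45.0) if rng.random() < 0.5 else rng.uniform(205.0, 230.0)
        x[start : start + length] = value
        ledger.append(Defect("outlier", start, length))

    # spikes: short runs offset by > 25 bpm from the local level, kept in range
    for _ in range(int(rng.poisson(config.spike_per_10min * per10))):
        length = int(rng.integers(1, 4))
        start = _free_slot(rng, n, length, occupied)
        if start is None:
            continue
        local = x[start - 1]
        delta = rng.uniform(35.0, 50.0)
        # pick the direction with headroom so the spike stays in [50, 200]
        # while remaining > 25 bpm away from the local level
        sign = 1.0 if local <= 150.0 else -1.0
        x[start : start + length] = local + sign * delta
        ledger.append(Defect("spike", start, length))

    # optional short zero runs touching the recording edges (trim path)
    if rng.random() < config.edge_zero_probability:
        length = int(rng.integers(4, 40))
        x[:length] = 0.0
        ledger.append(Defect("edge_gap", 0, length))
    if rng.random() < config.edge_zero_probability:
        length = int(rng.integers(4, 40))
        x[n - length :] = 0.0
        ledger.append(Defect("edge_gap", n - length, length))

    if label is ClassLabel.DISTRESSED:
        ph = float(rng.uniform(6.95, 7.14))
    else:
        ph = float(rng.uniform(7.20, 7.38))
    uc = np.clip(
        20.0 + 15.0 * np.abs(gaussian_filter1d(rng.standard_normal(n), 40.0)),
        0.0, 100.0,
    )
    record = CTGRecord(record_id=record_id, fhr=x, uc=uc, fs=config.fs, ph=ph)
    return record, ledger


def simulate_cohort(
    n_normal: int,
    n_distressed: int,
    config: FHRSimConfig = FHRSimConfig(),
) -> list[tuple[CTGRecord, ClassLabel, list[Defect]]]:
    """Generate a labeled cohort; distressed physiology follows
    ``distressed_config`` scaled by ``config.class_separation``."""
    if n_normal < 0 or n_distressed < 0:
        raise ConfigError("cohort counts must be >= 0")
    if n_normal + n_distressed == 0:
        raise ConfigError("cohort must contain at least one record")
    seeds = np.random.SeedSequence(config.seed).spawn(n_normal + n_distressed)
    dist_cfg = distressed_config(config)
    cohort = []
    for i in range(n_normal + n_distressed):
        distressed = i >= n_normal
        label = ClassLabel.DISTRESSED if distressed else ClassLabel.NORMAL
        rec, ledger = simulate_record(
            dist_cfg if distressed else config,
            label=label,
            record_id=f"sim{i:04d}",
            rng=np.random.default_rng(seeds[i]),
        )
        cohort.append((rec, label, ledger))
    return cohort


def expected_provenance(ledger: list[Defect]) -> dict[str, int]:
    """Cleaning provenance implied by a defect ledger.

    Long runs (interior or edge) are deleted by the gap remover; short edge
    runs are trimmed; short interior gaps and outliers are linearly
    interpolated; spike samples are spline-replaced.
    """
    out = {
        "long_gaps_removed": 0,
        "samples_removed": 0,
        "edge_samples_trimmed": 0,
        "samples_interpolated_linear": 0,
        "samples_interpolated_spline": 0,
    }
    for d in ledger:
        if d.kind == "long_gap":
            out["long_gaps_removed"] += 1
            out["samples_removed"] += d.length
        elif d.kind == "edge_gap":
            if d.length > 60:
                out["long_gaps_removed"] += 1
                out["samples_removed"] += d.length
            else:
                out["edge_samples_trimmed"] += d.length
        elif d.kind in ("short_gap", "outlier"):
            out["samples_interpolated_linear"] += d.length
        elif d.kind == "spike":
            out["samples_interpolated_spline"] += d.length
    return out
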