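"""Rule-based cleaning of raw FHR traces.

Sensor dropout, maternal movement and electrode displacement leave three
kinds of artifact in an externally acquired FHR trace: runs of zero samples
(missing data), non-physiologic extremes (< 50 or > 200 bpm), and abrupt
spikes (adjacent-sample jumps of more than 25 bpm).  The cleaning chain is

1. delete zero-runs longer than 15 s outright (the series is concatenated
   across the deleted span);
2. trim any remaining zero-runs at the two edges of the recording;
3. linearly interpolate interior short zero-runs and out-of-range samples
   between the nearest valid neighbours;
4. replace spike runs with a natural cubic spline fitted through stable
   samples on either side, iterating until no adjacent jump exceeds 25 bpm;
5. cut the labor-stage analysis window: the first 20 minutes (stage 1) or
   the last 15 minutes (stage 2) of the cleaned series.

After step 4 the signal contains no zeros, lies within [50, 200] bpm and has
no adjacent jump above 25 bpm; those invariants are what the downstream
time-frequency representation relies on.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConvergenceError, EmptySignalError, SegmentTooShortError
from .record_io import CTGRecord

logger = logging.getLogger(__name__)

FHR_LOW = 50.0
FHR_HIGH = 200.0
MAX_DELTA = 25.0
MAX_GAP_SECONDS = 15.0


@dataclass
class Provenance:
    """Counts of what cleaning did to a signal."""

    long_gaps_removed: int = 0        # number of zero-runs deleted
    samples_removed: int = 0          # samples deleted with those runs
    edge_samples_trimmed: int = 0
    samples_interpolated_linear: int = 0
    samples_interpolated_spline: int = 0

    def __add__(self, other: "Provenance") -> "Provenance":
        return Provenance(
            self.long_gaps_removed + other.long_gaps_removed,
            self.samples_removed + other.samples_removed,
            self.edge_samples_trimmed + other.edge_samples_trimmed,
            self.samples_interpolated_linear + other.samples_interpolated_linear,
            self.samples_interpolated_spline + other.samples_interpolated_spline,
        )


@dataclass
class FHRSignal:
    """A single-channel FHR series with its cleaning provenance."""

    samples: np.ndarray
    fs: float = 4.0
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


class Stage(enum.Enum):
    """Labor stage analysed: early labor or the final pre-delivery period."""

    STAGE1 = 1  # first 20 min of the cleaned recording
    STAGE2 = 2  # last 15 min

    @property
    def window_seconds(self) -> float:
        return 1200.0 if self is Stage.STAGE1 else 900.0

    def window_samples(self, fs: float) -> int:
        n = self.window_seconds * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"window of {self.window_seconds}s not integral at fs={fs}")
        return int(round(n))


@dataclass
class Segment:
    """A fixed-length labor-stage window cut from a cleaned signal."""

    samples: np.ndarray
    stage: Stage
    record_id: str = ""
    start_index: int = 0
    fs: float = 4.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


def find_missing_runs(samples: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive zero samples as (start, length), in order."""
    x = np.asarray(samples)
    iszero = np.concatenate(([False], x == 0, [False]))
    edges = np.flatnonzero(np.diff(iszero.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def remove_long_gaps(
    signal: FHRSignal, max_gap_seconds: float = MAX_GAP_SECONDS
) -> FHRSignal:
    """Delete zero-runs strictly longer than ``max_gap_seconds``.

    Samples are excised and the remainder concatenated; runs of exactly the
    threshold length or shorter are kept for later interpolation.
    """
    x = signal.samples
    max_len = max_gap_seconds * signal.fs
    keep = np.ones(len(x), dtype=bool)
    n_runs = 0
    for start, length in find_missing_runs(x):
        if length > max_len:
            keep[start : start + length] = False
            n_runs += 1
    out = x[keep]
    if len(out) == 0:
        raise EmptySignalError("signal is entirely missing")
    prov = signal.provenance + Provenance(
        long_gaps_removed=n_runs, samples_removed=int((~keep).sum())
    )
    return FHRSignal(out, signal.fs, prov)


def trim_edges(signal: FHRSignal) -> FHRSignal:
    """Strip leading and trailing zero-runs regardless of length."""
    x = signal.samples
    nonzero = np.flatnonzero(x != 0)
    if len(nonzero) == 0:
        raise EmptySignalError("signal is entirely missing")
    lo, hi = nonzero[0], nonzero[-1] + 1
    prov = signal.provenance + Provenance(
        edge_samples_trimmed=int(lo + len(x) - hi)
    )
    return FHRSignal(x[lo:hi], signal.fs, prov)


def linear_interpolate(
    x0: float, y0: float, x1: float, y1: float, x: float
) -> float:
    """Straight-line value at ``x`` between anchors (x0, y0) and (x1, y1)."""
    if x1 == x0:
        raise ValueError("degenerate anchors: x0 == x1")
    return (y0 * (x1 - x) + y1 * (x - x0)) / (x1 - x0)


def interpolate_outliers_and_small_gaps(
    signal: FHRSignal, low: float = FHR_LOW, high: float = FHR_HIGH
) -> FHRSignal:
    """Replace zeros and out-of-range samples by linear interpolation.

    Valid samples are nonzero values in [low, high] (the bounds themselves
    are physiologic).  Invalid samples are interpolated between the nearest
    valid neighbours; an invalid run touching an edge is extended constantly
    from the nearest valid sample.
    """
    x = signal.samples.copy()
    invalid = (x == 0) | (x < low) | (x > high)
    if invalid.all():
        raise EmptySignalError("no valid samples to interpolate from")
    if invalid.any():
        idx = np.arange(len(x))
        x[invalid] = np.interp(idx[invalid], idx[~invalid], x[~invalid])
    prov = signal.provenance + Provenance(
        samples_interpolated_linear=int(invalid.sum())
    )
    return FHRSignal(x, signal.fs, prov)


def remove_spikes(
    signal: FHRSignal,
    max_delta: float = MAX_DELTA,
    anchors_per_side: int = 4,
    max_passes: int = 10,
    low: float = FHR_LOW,
    high: float = FHR_HIGH,
) -> FHRSignal:
    """Replace non-physiologic jumps (> ``max_delta`` bpm) by cubic splines.

    Scanning left to right with the first sample taken as stable: a jump of
    more than ``max_delta`` from the last stable sample opens an unstable run,
    which closes at the first later sample back within ``max_delta`` of that
    stable level.  The run is replaced by a natural cubic spline through up to
    ``anchors_per_side`` stable samples on each side (linear extension when
    the run reaches the end of the signal).  The scan repeats until no jump
    remains; replacement values are kept inside [low, high].
    """
    x = signal.samples.copy()
    n = len(x)
    if n == 0:
        raise EmptySignalError("empty signal")
    n_replaced = 0
    for _ in range(max_passes):
        if n < 2 or not np.any(np.abs(np.diff(x)) > max_delta):
            prov = signal.provenance + Provenance(
                samples_interpolated_spline=n_replaced
            )
            return FHRSignal(x, signal.fs, prov)
        i = 1
        while i < n:
            base_idx = i - 1
            if abs(x[i] - x[base_idx]) <= max_delta:
                i += 1
                continue
            base = x[base_idx]
            j = i + 1
            while j < n and abs(x[j] - base) > max_delta:
                j += 1
            left = np.arange(max(0, base_idx - anchors_per_side + 1), base_idx + 1)
            if j >= n:
                # run reaches the end: extend linearly from the left anchors
                if len(left) >= 2:
                    coef = np.polyfit(left, x[left], 1)
                    x[i:] = np.polyval(coef, np.arange(i, n))
                else:
                    x[i:] = base
            else:
                right = np.arange(j, min(n, j + anchors_per_side))
                anchors = np.concatenate([left, right])
                spline = CubicSpline(anchors, x[anchors], bc_type="natural")
                x[i:j] = spline(np.arange(i, j))
            np.clip(x[i:j if j < n else n], low, high, out=x[i:j if j < n else n])
            n_replaced += j - i
            i = j
    raise ConvergenceError(
        f"spike removal did not converge in {max_passes} passes"
    )


def segment(signal: FHRSignal, stage: Stage, record_id: str = "") -> Segment:
    """Cut the labor-stage window from a fully cleaned signal."""
    n = stage.window_samples(signal.fs)
    if len(signal) < n:
        raise SegmentTooShortError(
            f"signal of {len(signal)} samples shorter than {n}-sample "
            f"{stage.name} window"
        )
    start = 0 if stage is Stage.STAGE1 else len(signal) - n
    return Segment(
        signal.samples[start : start + n],
        stage=stage,
        record_id=record_id,
        start_index=start,
        fs=signal.fs,
    )


def clean(record: CTGRecord) -> FHRSignal:
    """Run the full cleaning chain (no segmentation) on a record's FHR channel."""
    sig = FHRSignal(record.fhr, record.fs)
    sig = remove_long_gaps(sig)
    sig = trim_edges(sig)
    sig = interpolate_outliers_and_small_gaps(sig)
    sig = remove_spikes(sig)
    return sig


def preprocess_pipeline(record: CTGRecord, stage: Stage) -> Segment:
    """Extract FHR, clean it, and cut the requested labor-stage window."""
    return segment(clean(record), stage, record_id=record.record_id)


def check_invariants(
    samples: np.ndarray,
    low: float = FHR_LOW,
    high: float = FHR_HIGH,
    max_delta: float = MAX_DELTA,
) -> bool:
    """Brute-force scan of the post-cleaning invariants."""
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        return False
    if np.any(x == 0) or np.any(x < low) or np.any(x > high):
        return False
    return not np.any(np.abs(np.diff(x)) > max_delta)
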