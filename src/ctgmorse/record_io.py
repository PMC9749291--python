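"""Reading and writing CTG recordings and their labels.

A recording pairs a fetal-heart-rate (FHR) channel in beats per minute with a
uterine-contraction (UC) channel, both sampled at the same rate (4 Hz for
intrapartum databases such as CTU-UHB).  A value of exactly 0 bpm in the FHR
channel encodes a missing sample (sensor dropout).  Records carry the
umbilical-artery pH measured at birth, which is the objective ground truth
used to label a recording as normal or distressed.

Two on-disk dialects are supported:

* a human-readable CSV dialect: header line ``fhr,uc``, one sample per row,
  with the sampling rate supplied by the caller (default 4 Hz);
* PhysioNet-style waveform records: a text ``.hea`` header naming the signal
  files, channel descriptions, gains and baselines, plus 16-bit little-endian
  sample files.  pH is read from a ``#pH <value>`` comment line in the header.
"""

from __future__ import annotations

import enum
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import LabelingError, ParseError, StructuralError

logger = logging.getLogger(__name__)

PH_DISTRESS_THRESHOLD = 7.15


class ClassLabel(enum.Enum):
    """Binary fetal condition. Distressed is the positive class throughout."""

    NORMAL = "normal"
    DISTRESSED = "distressed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class CTGRecord:
    """A raw CTG recording: paired FHR/UC traces plus clinical metadata.

    ``fhr`` is in bpm with 0 meaning missing; ``uc`` is in arbitrary units.
    ``ph`` is the umbilical-artery pH (dimensionless, > 0) or ``None``.
    """

    record_id: str
    fhr: np.ndarray
    uc: np.ndarray | None = None
    fs: float = 4.0
    ph: float | None = None

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        if self.uc is not None:
            self.uc = np.asarray(self.uc, dtype=float)
            if len(self.uc) != len(self.fhr):
                raise StructuralError(
                    f"record {self.record_id!r}: fhr length {len(self.fhr)} "
                    f"!= uc length {len(self.uc)}"
                )
        if not self.fs > 0:
            raise StructuralError(f"record {self.record_id!r}: fs must be > 0")
        if np.any(self.fhr < 0):
            raise StructuralError(
                f"record {self.record_id!r}: negative FHR values present"
            )

    def __len__(self) -> int:
        return len(self.fhr)


def read_record(
    path: str | Path, format: str = "csv", fs: float = 4.0
) -> CTGRecord:
    """Read one CTG record from disk.

    ``format`` is ``"csv"`` (two-column dialect, sampling rate from ``fs``)
    or ``"physionet"`` (``path`` is the ``.hea`` header or the record stem;
    sampling rate and pH come from the header).
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path, fs)
    if format == "physionet":
        return _read_physionet(path)
    raise ValueError(f"unknown record format: {format!r}")


def _read_csv(path: Path, fs: float) -> CTGRecord:
    if not path.exists():
        raise ParseError(f"record file not found: {path}")
    with open(path) as fh:
        header = fh.readline().strip().lower()
    columns = [c.strip() for c in header.split(",")]
    if "fhr" not in columns:
        raise StructuralError(f"{path}: no 'fhr' column in header {header!r}")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed sample row ({exc})") from exc
    if data.shape[1] != len(columns):
        raise ParseError(
            f"{path}: {data.shape[1]} columns of data for header {header!r}"
        )
    fhr = data[:, columns.index("fhr")]
    uc = data[:, columns.index("uc")] if "uc" in columns else None
    return CTGRecord(record_id=path.stem, fhr=fhr, uc=uc, fs=fs)


def write_record_csv(record: CTGRecord, path: str | Path) -> None:
    """Write a record in the CSV dialect (header ``fhr,uc``)."""
    path = Path(path)
    uc = record.uc if record.uc is not None else np.zeros_like(record.fhr)
    # %.17g keeps the write/read round trip bit-exact for float64 samples
    with open(path, "w") as fh:
        fh.write("fhr,uc\n")
        for f, u in zip(record.fhr, uc):
            fh.write(f"{f:.17g},{u:.17g}\n")


# --- minimal PhysioNet-style waveform reader (header + format-16 samples) ---

def _read_physionet(path: Path) -> CTGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise ParseError(f"header file not found: {hea}")
    lines = [
        ln.rstrip() for ln in hea.read_text().splitlines() if ln.strip()
    ]
    record_line = lines[0].split()
    if len(record_line) < 3:
        raise ParseError(f"{hea}: malformed record line {lines[0]!r}")
    name = record_line[0]
    try:
        n_sig = int(record_line[1])
        fs = float(record_line[2])
    except ValueError as exc:
        raise ParseError(f"{hea}: bad record line field ({exc})") from exc

    signals: dict[str, np.ndarray] = {}
    ph: float | None = None
    sig_lines = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            ph = _parse_ph_comment(ln, ph)
        else:
            sig_lines.append(ln)
    if len(sig_lines) < n_sig:
        raise ParseError(f"{hea}: {len(sig_lines)} signal lines, header says {n_sig}")

    for ln in sig_lines[:n_sig]:
        fields = ln.split()
        if len(fields) < 2:
            raise ParseError(f"{hea}: malformed signal line {ln!r}")
        fname, fmt = fields[0], fields[1]
        if fmt.split("x")[0] != "16":
            raise ParseError(
                f"{hea}: unsupported sample format {fmt!r} (only 16 supported)"
            )
        gain, baseline = _parse_gain(fields[2] if len(fields) > 2 else "200")
        description = fields[-1] if len(fields) > 3 else f"ch{len(signals)}"
        raw = _read_format16(hea.parent / fname)
        signals[description.upper()] = (raw - baseline) / gain

    fhr = signals.get("FHR")
    if fhr is None:
        raise StructuralError(
            f"{hea}: no channel described as FHR among {sorted(signals)}"
        )
    return CTGRecord(
        record_id=name, fhr=fhr, uc=signals.get("UC"), fs=fs, ph=ph
    )


def _parse_ph_comment(line: str, current: float | None) -> float | None:
    tokens = line.lstrip("#").split()
    for i, tok in enumerate(tokens):
        if tok.lower().rstrip(":") == "ph" and i + 1 < len(tokens):
            try:
                return float(tokens[i + 1])
            except ValueError:
                raise ParseError(f"unparseable pH comment: {line!r}")
    return current


def _parse_gain(spec: str) -> tuple[float, float]:
    """Parse a WFDB gain field ``gain(baseline)/units`` → (gain, baseline)."""
    spec = spec.split("/")[0]
    baseline = 0.0
    if "(" in spec:
        spec, rest = spec.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(spec) if spec else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def _read_format16(path: Path) -> np.ndarray:
    if not path.exists():
        raise ParseError(f"signal file not found: {path}")
    raw = path.read_bytes()
    if len(raw) % 2:
        raise ParseError(f"{path}: odd byte count for 16-bit samples")
    n = len(raw) // 2
    return np.asarray(struct.unpack(f"<{n}h", raw), dtype=float)


# --- labeling -----------------------------------------------------------

def label_by_ph(
    ph: float | None, threshold: float = PH_DISTRESS_THRESHOLD
) -> ClassLabel:
    """Label a record from umbilical-artery pH: distressed iff pH <= threshold."""
    if ph is None or not ph > 0:
        raise LabelingError(f"cannot label record: invalid pH {ph!r}")
    return ClassLabel.DISTRESSED if ph <= threshold else ClassLabel.NORMAL


def label_database(
    records: Iterable[CTGRecord], threshold: float = PH_DISTRESS_THRESHOLD
) -> tuple[dict[str, ClassLabel], tuple[int, int]]:
    """Label a collection of records; returns (labels, (n_normal, n_distressed)).

    Records with missing or non-positive pH are excluded with a warning.
    """
    labels: dict[str, ClassLabel] = {}
    n_normal = n_distressed = 0
    n_seen = 0
    for rec in records:
        n_seen += 1
        try:
            lab = label_by_ph(rec.ph, threshold)
        except LabelingError:
            logger.warning("record %s excluded: no usable pH", rec.record_id)
            continue
        labels[rec.record_id] = lab
        if lab is ClassLabel.DISTRESSED:
            n_distressed += 1
        else:
            n_normal += 1
    if n_seen == 0:
        raise LabelingError("empty record collection")
    return labels, (n_normal, n_distressed)


def write_labels_tsv(labels: Mapping[str, ClassLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tlabel\n")
        for rid, lab in labels.items():
            fh.write(f"{rid}\t{lab.value}\n")


def read_labels_tsv(path: str | Path) -> dict[str, ClassLabel]:
    labels: dict[str, ClassLabel] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("record_id"):
            raise ParseError(f"{path}: missing labels header")
        for ln in fh:
            if not ln.strip():
                continue
            rid, lab = ln.rstrip("\n").split("\t")
            labels[rid] = ClassLabel(lab)
    return labels
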