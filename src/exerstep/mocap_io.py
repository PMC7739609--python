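"""Reading, writing, validation and gap handling for marker trajectory files.

The canonical internal representation is the :class:`TrialRecording`: one
``(n_frames, 3)`` float array per marker, in meters, in the lab frame (X
medial-lateral, Y anterior-posterior toward the screen, Z up, origin at the
center of the active play area on the floor).  Missing samples are NaN, never
zero.

Two on-disk formats are supported: a tab-separated trajectory dialect (one
metadata block, one header row of ``<marker>_X/_Y/_Z`` columns, one row per
frame) and, when the optional ``ezc3d`` dependency is installed, the C3D
standard (read-only).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRecording, FormatError, MarkerSetMismatch
from .markers import CANONICAL_MARKERS, MarkerSet, resolve_label

TSV_MAGIC = "# exerstep trajectory v1"

#: Default interpolation limit: shorter than the minimum step duration, so gap
#: filling cannot fabricate a detectable event.
DEFAULT_MAX_GAP = 0.1


@dataclass(frozen=True)
class TrialMeta:
    """Condition metadata attached to one trial recording."""

    participant: str = ""
    gender: str = ""                # "female" / "male" / ""
    speed: str = ""                 # "low" / "high" / ""
    obstacles: str = ""             # "without" / "with" / ""
    repetition: int = 0

    def as_dict(self) -> dict:
        return {
            "participant": self.participant,
            "gender": self.gender,
            "speed": self.speed,
            "obstacles": self.obstacles,
            "repetition": self.repetition,
        }


@dataclass
class TrialRecording:
    """Marker positions for one trial, in lab-frame meters."""

    positions: dict[str, np.ndarray]    # marker -> (n_frames, 3)
    rate: float                         # Hz
    meta: TrialMeta = field(default_factory=TrialMeta)
    markers: MarkerSet = field(default_factory=MarkerSet)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.rate}")
        lengths = {v.shape[0] for v in self.positions.values()}
        if len(lengths) > 1:
            raise FormatError(f"marker series lengths differ: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        if not self.positions:
            return 0
        return next(iter(self.positions.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def __getitem__(self, marker: str) -> np.ndarray:
        try:
            return self.positions[marker]
        except KeyError:
            raise MarkerSetMismatch(f"marker {marker!r} not present") from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise MarkerSetMismatch(f"missing markers: {missing}")


@dataclass(frozen=True)
class GapReport:
    """One contiguous missing span in a marker series."""

    marker: str
    start_frame: int
    n_frames: int
    filled: bool


@dataclass(frozen=True)
class ValidationReport:
    n_frames: int
    rate: float
    missing_markers: tuple[str, ...]
    missing_fraction: dict[str, float]
    rate_ok: bool
    sternum_in_bounds: bool

    @property
    def ok(self) -> bool:
        return self.rate_ok and not self.missing_markers and self.sternum_in_bounds


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def write_recording(rec: TrialRecording, path: str | os.PathLike, units: str = "m") -> None:
    """Write the tab-separated trajectory dialect (meters or millimeters)."""
    if units not in ("m", "mm"):
        raise FormatError(f"units must be 'm' or 'mm', got {units!r}")
    scale = 1000.0 if units == "mm" else 1.0
    names = list(rec.positions)
    buf = io.StringIO()
    buf.write(TSV_MAGIC + "\n")
    buf.write(f"# rate_hz\t{rec.rate:g}\n")
    buf.write(f"# units\t{units}\n")
    for key, val in rec.meta.as_dict().items():
        if val not in ("", 0):
            buf.write(f"# {key}\t{val}\n")
    buf.write("frame\t" + "\t".join(
        f"{n}_{ax}" for n in names for ax in "XYZ") + "\n")
    data = np.column_stack([rec.positions[n] * scale for n in names])
    frames = np.arange(rec.n_frames)
    for i in range(rec.n_frames):
        row = "\t".join("NaN" if np.isnan(v) else f"{v:.6f}" for v in data[i])
        buf.write(f"{frames[i]}\t{row}\n")
    Path(path).write_text(buf.getvalue())


def _read_tsv(path: Path, units: str | None, aliases: dict[str, str] | None):
    rate = None
    meta_kv: dict[str, str] = {}
    file_units = None
    header = None
    data_rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    key, val = parts
                    if key == "rate_hz":
                        try:
                            rate = float(val)
                        except ValueError:
                            raise FormatError(f"unparseable rate: {val!r}") from None
                    elif key == "units":
                        file_units = val
                    else:
                        meta_kv[key] = val
                continue
            if header is None:
                header = line.split("\t")
            else:
                data_rows.append(line)
    if header is None or not data_rows:
        raise EmptyRecording(f"{path} contains no frames")
    if rate is None or rate <= 0:
        raise FormatError(f"{path}: missing or non-positive rate_hz header")
    units = units or file_units or "m"
    if units not in ("m", "mm"):
        raise FormatError(f"unknown units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0

    cols = header[1:]  # drop "frame"
    if len(cols) % 3:
        raise FormatError(f"{path}: coordinate columns not in X/Y/Z triplets")
    raw_names = []
    for j in range(0, len(cols), 3):
        stem = cols[j]
        if not stem.endswith("_X"):
            raise FormatError(f"{path}: expected *_X column, got {stem!r}")
        raw_names.append(stem[:-2])
    table = np.loadtxt(io.StringIO("\n".join(data_rows)), delimiter="\t")
    table = np.atleast_2d(table)[:, 1:] * scale

    positions = {}
    for k, raw in enumerate(raw_names):
        name = resolve_label(raw, aliases)
        positions[name] = np.ascontiguousarray(table[:, 3 * k:3 * k + 3])

    meta = TrialMeta(
        participant=meta_kv.get("participant", ""),
        gender=meta_kv.get("gender", ""),
        speed=meta_kv.get("speed", ""),
        obstacles=meta_kv.get("obstacles", ""),
        repetition=int(meta_kv.get("repetition", 0)),
    )
    return positions, rate, meta


def _read_c3d(path: Path, units: str | None, aliases: dict[str, str] | None):
    try:
        import ezc3d
    except ImportError:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading C3D requires the optional 'ezc3d' dependency "
            "(pip install exerstep[c3d])"
        ) from None
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [str(s).strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    if pts.shape[2] == 0:
        raise EmptyRecording(f"{path} contains no frames")
    unit_param = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    units = units or (unit_param[0] if unit_param else "mm")
    scale = 1e-3 if units == "mm" else 1.0
    positions = {}
    for k, raw in enumerate(labels):
        xyz = np.ascontiguousarray(pts[:3, k, :].T * scale)
        positions[resolve_label(raw, aliases)] = xyz
    return positions, rate, TrialMeta()


def load_recording(
    path: str | os.PathLike,
    format: str = "auto",
    units: str | None = None,
    aliases: dict[str, str] | None = None,
    require_full: bool = True,
) -> TrialRecording:
    """Load a trajectory file into a lab-frame, meter-unit :class:`TrialRecording`.

    Parameters
    ----------
    format
        ``tsv``, ``c3d`` or ``auto`` (by extension).
    units
        Override the file's unit declaration (``m`` or ``mm``).
    aliases
        Extra raw-label -> canonical-name mappings.
    require_full
        When True (default), raise :class:`MarkerSetMismatch` unless all 22
        canonical markers are present after aliasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyRecording(f"{path} is empty")
    if format == "auto":
        format = "c3d" if path.suffix.lower() == ".c3d" else "tsv"
    if format == "tsv":
        positions, rate, meta = _read_tsv(path, units, aliases)
    elif format == "c3d":
        positions, rate, meta = _read_c3d(path, units, aliases)
    else:
        raise FormatError(f"unknown format {format!r}")
    if not positions:
        raise EmptyRecording(f"{path} declares no markers")
    if require_full:
        missing = [m for m in CANONICAL_MARKERS if m not in positions]
        if missing:
            raise MarkerSetMismatch(f"{path}: missing markers after aliasing: {missing}")
    return TrialRecording(positions=positions, rate=rate, meta=meta)


# ---------------------------------------------------------------------------
# gap filling and validation
# ---------------------------------------------------------------------------

def _missing_runs(mask: np.ndarray):
    """Yield (start, length) of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e - s)


def fill_gaps(
    rec: TrialRecording, max_gap: float = DEFAULT_MAX_GAP
) -> tuple[TrialRecording, list[GapReport]]:
    """Linearly interpolate missing spans no longer than ``max_gap`` seconds.

    Longer spans (and spans touching the recording boundary, which cannot be
    interpolated) are left missing and flagged.  Observed samples are never
    altered, so the operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    max_frames = int(round(max_gap * rec.rate))
    report: list[GapReport] = []
    out: dict[str, np.ndarray] = {}
    for name, xyz in rec.positions.items():
        xyz = xyz.copy()
        missing = np.isnan(xyz).any(axis=1)
        for start, length in _missing_runs(missing):
            interior = start > 0 and start + length < len(missing)
            fill = interior and length <= max_frames
            if fill:
                lo, hi = start - 1, start + length
                w = np.arange(1, length + 1) / (length + 1)
                xyz[start:start + length] = (
                    (1 - w)[:, None] * xyz[lo] + w[:, None] * xyz[hi]
                )
            report.append(GapReport(name, start, length, fill))
        out[name] = xyz
    return replace(rec, positions=out), report


def validate_recording(rec: TrialRecording, sanity_bound: float = 5.0) -> ValidationReport:
    """Report marker completeness, missing fractions and sternum sanity."""
    missing_markers = tuple(m for m in rec.markers.names if m not in rec.positions)
    frac = {}
    for name, xyz in rec.positions.items():
        frac[name] = float(np.isnan(xyz).any(axis=1).mean()) if len(xyz) else 1.0
    sternum_ok = True
    if "sternum" in rec.positions:
        st = rec.positions["sternum"]
        with np.errstate(invalid="ignore"):
            sternum_ok = bool(np.nanmax(np.abs(st[:, :2]), initial=0.0) < sanity_bound)
    return ValidationReport(
        n_frames=rec.n_frames,
        rate=rec.rate,
        missing_markers=missing_markers,
        missing_fraction=frac,
        rate_ok=rec.rate > 0,
        sternum_in_bounds=sternum_ok,
    )
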