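"""Data model and file I/O for multichannel EEG and behavioral tables.

The data model mirrors a consumer-grade 14-channel 10-20-derived montage
recorded at 128 Hz: each subject contributes one recording and one behavioral
row per experimental condition (a "valid" and an "invalid" reasoning block).
Recordings travel as plain CSV (rows = channels in canonical montage order)
or 16-bit EDF; behavioral data as a flat CSV. All analysis outputs are
CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MontageError, ValidationError

GROUPS = ("ASD", "ADHD", "CONTROL")
CONDITIONS = ("valid", "invalid")

#: Canonical channel order of the 14-channel montage (frontal to occipital,
#: left hemisphere first, mirrored on the right).
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

_LOCATIONS = {
    "AF3": "Anterio-frontal, left", "F7": "Frontal-temporal, left",
    "F3": "Frontal, left", "FC5": "Frontal-central, left",
    "T7": "Temporal, left", "P7": "Parietal, left",
    "O1": "Occipital, left", "O2": "Occipital, right",
    "P8": "Parietal, right", "T8": "Temporal, right",
    "FC6": "Frontal-central, right", "F4": "Frontal, right",
    "F8": "Frontal-temporal, right", "AF4": "Anterio-frontal, right",
}


def channel_hemisphere(name: str) -> str:
    """'left' for odd-suffixed channels, 'right' for even-suffixed ones."""
    m = re.search(r"(\d+)$", name)
    if not m:
        raise MontageError(f"channel {name!r} has no numeric suffix")
    return "left" if int(m.group(1)) % 2 == 1 else "right"


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered, unique channel names with scalp-location labels."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    locations: Mapping[str, str] = field(default_factory=lambda: dict(_LOCATIONS))

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise MontageError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise MontageError(f"channel {name!r} not in montage") from None

    def canonical_order(self, names: Sequence[str]) -> list[int]:
        """Positions of ``names`` rearranged into canonical montage order.

        Raises :class:`MontageError` naming missing/extra channels.
        """
        missing = [c for c in self.channels if c not in names]
        extra = [c for c in names if c not in self.channels]
        if missing or extra:
            raise MontageError(
                f"channel mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
            )
        lookup = {c: i for i, c in enumerate(names)}
        return [lookup[c] for c in self.channels]


DEFAULT_MONTAGE = ChannelMontage()


@dataclass
class EEGRecording:
    """One subject/condition multichannel signal (channels x samples, µV)."""

    subject_id: str
    group: str
    condition: str
    sampling_rate: float
    samples: np.ndarray
    montage: ChannelMontage = DEFAULT_MONTAGE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.montage):
            raise MontageError(
                f"expected {len(self.montage)} channel rows, got shape {self.samples.shape}"
            )
        if not np.isfinite(self.samples).all():
            raise ValidationError(
                f"non-finite samples in recording {self.subject_id}/{self.condition}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.montage.index(name)]


@dataclass(frozen=True)
class SubjectBehavior:
    """One subject/condition behavioral row: age, SAM triplet, confidence.

    SAM (Self-Assessment Manikin) scores are 9-point integer ratings of
    valence, arousal and dominance; confidence is a 0-100 % certainty
    self-report.
    """

    subject_id: str
    group: str
    condition: str
    age: float
    sam_valence: int
    sam_arousal: int
    sam_dominance: int
    confidence_percent: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        for name in ("sam_valence", "sam_arousal", "sam_dominance"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 9):
                raise ValidationError(f"{name} must be an integer in 1..9, got {v!r}")
        if not 0 <= self.confidence_percent <= 100:
            raise ValidationError(
                f"confidence_percent must be in [0, 100], got {self.confidence_percent}"
            )


# ---------------------------------------------------------------------------
# EEG CSV
# ---------------------------------------------------------------------------

_STEM_RE = re.compile(r"^(?P<subject>.+)_(?P<group>ASD|ADHD|CONTROL)_(?P<condition>valid|invalid)$")


def _meta_from_stem(stem: str) -> tuple[str, str, str]:
    m = _STEM_RE.match(stem)
    if not m:
        raise ValidationError(
            f"cannot parse subject/group/condition from filename stem {stem!r} "
            "(expected subject_group_condition)"
        )
    return m.group("subject"), m.group("group"), m.group("condition")


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV: one row per channel, first column 'channel'."""
    path = Path(path)
    df = pd.DataFrame(recording.samples, index=list(recording.montage.channels))
    df.index.name = "channel"
    df.to_csv(path, float_format="%.17g")
    return path


def read_eeg_csv(
    path: str | Path,
    montage: ChannelMontage = DEFAULT_MONTAGE,
    sampling_rate: float = 128.0,
) -> EEGRecording:
    """Read a channels-as-rows CSV, reordering rows into canonical order.

    Subject/group/condition metadata come from the filename convention
    ``subject_group_condition.csv``.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col="channel")
    order = montage.canonical_order(list(df.index))
    samples = df.to_numpy(dtype=float)[order]
    if not np.isfinite(samples).all():
        raise ValidationError(f"non-finite samples in {path.name}")
    subject, group, condition = _meta_from_stem(path.stem)
    return EEGRecording(subject, group, condition, sampling_rate, samples, montage)


# ---------------------------------------------------------------------------
# EDF (16-bit, standard header)
# ---------------------------------------------------------------------------

def _largest_divisor_leq(n: int, cap: int) -> int:
    for d in range(min(cap, n), 0, -1):
        if n % d == 0:
            return d
    return 1


def write_eeg_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a minimal standard EDF file (16-bit samples).

    Samples are mapped onto the full signed 16-bit digital range from each
    channel's physical min/max, so the round-trip quantization step is
    (max - min) / 65535 per channel.
    """
    path = Path(path)
    n_ch = recording.samples.shape[0]
    n_samp = recording.n_samples
    spr = _largest_divisor_leq(n_samp, 4096)  # samples per data record
    n_rec = n_samp // spr
    duration = spr / recording.sampling_rate

    def ascii8(v: float) -> str:
        # widest representation that fits the 8-char header field
        for prec in range(8, 0, -1):
            s = f"{v:.{prec}g}"
            if len(s) <= 8:
                return s
        raise ValidationError(f"cannot encode {v} in an 8-char EDF field")

    # quantize against the values as actually written, so the round-trip
    # error is bounded by half a digital step
    phys_min_s = [ascii8(v) for v in recording.samples.min(axis=1)]
    phys_max_s = [ascii8(v) for v in recording.samples.max(axis=1)]
    phys_min = np.array([float(s) for s in phys_min_s])
    phys_max = np.array([float(s) for s in phys_max_s])
    span = phys_max - phys_min
    span[span == 0] = 1.0
    dig_min, dig_max = -32768, 32767
    scaled = (recording.samples - phys_min[:, None]) / span[:, None]
    digital = np.clip(
        np.round(scaled * (dig_max - dig_min) + dig_min), dig_min, dig_max
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValidationError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),
        pad(f"{recording.subject_id} {recording.group}", 80),
        pad(f"condition {recording.condition}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad(f"{duration:g}", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        (16, list(recording.montage.channels)),
        (80, ["EEG"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, phys_min_s),
        (8, phys_max_s),
        (8, [str(dig_min)] * n_ch),
        (8, [str(dig_max)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())
    return path


def read_eeg_edf(
    path: str | Path, montage: ChannelMontage = DEFAULT_MONTAGE
) -> EEGRecording:
    """Read an EDF file written by :func:`write_eeg_edf`.

    Metadata are taken from the filename convention ``subject_group_condition.edf``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244])
        duration = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch)

        def col(width: int, pos: int) -> list[str]:
            base = pos
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        off = 0
        labels = col(16, off); off += 16 * n_ch
        off += 80 * n_ch + 8 * n_ch  # transducer, unit
        phys_min = np.array([float(v) for v in col(8, off)]); off += 8 * n_ch
        phys_max = np.array([float(v) for v in col(8, off)]); off += 8 * n_ch
        dig_min = np.array([int(v) for v in col(8, off)]); off += 8 * n_ch
        dig_max = np.array([int(v) for v in col(8, off)]); off += 8 * n_ch
        off += 80 * n_ch
        spr = np.array([int(v) for v in col(8, off)])
        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = int(spr.sum())
    raw = raw[: per_rec * n_rec].reshape(n_rec, per_rec)
    data = np.empty((n_ch, int(spr[0]) * n_rec))
    start = 0
    for i in range(n_ch):
        chan = raw[:, start:start + spr[i]].reshape(-1).astype(float)
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (chan - dig_min[i]) * scale + phys_min[i]
        start += spr[i]
    order = montage.canonical_order(labels)
    data = data[order]
    sampling_rate = spr[0] / duration
    subject, group, condition = _meta_from_stem(path.stem)
    return EEGRecording(subject, group, condition, sampling_rate, data, montage)


def read_eeg(
    path: str | Path,
    montage: ChannelMontage = DEFAULT_MONTAGE,
    sampling_rate: float = 128.0,
) -> EEGRecording:
    """Read an EEG recording, dispatching on the file extension (.csv / .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path, montage)
    if path.suffix.lower() == ".csv":
        return read_eeg_csv(path, montage, sampling_rate)
    raise ValidationError(f"unsupported EEG format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

BEHAVIOR_COLUMNS = (
    "subject_id", "group", "condition", "age",
    "sam_valence", "sam_arousal", "sam_dominance", "confidence_percent",
)


def write_behavior(rows: Iterable[SubjectBehavior], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {c: getattr(r, c) for c in BEHAVIOR_COLUMNS} for r in rows
    ], columns=list(BEHAVIOR_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_behavior(path: str | Path) -> list[SubjectBehavior]:
    """Read and validate a behavioral CSV; duplicates and missing values are errors."""
    df = pd.read_csv(path)
    missing_cols = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"behavior table missing columns {missing_cols}")
    if df[list(BEHAVIOR_COLUMNS)].isna().any().any():
        bad = df[list(BEHAVIOR_COLUMNS)].isna().any()
        raise ValidationError(
            f"missing values in behavior columns {list(bad[bad].index)} (no imputation)"
        )
    dupes = df.duplicated(subset=["subject_id", "condition"])
    if dupes.any():
        pair = df.loc[dupes.idxmax(), ["subject_id", "condition"]].tolist()
        raise ValidationError(f"duplicate (subject, condition) row: {pair}")
    rows = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        for k in ("sam_valence", "sam_arousal", "sam_dominance"):
            v = d[k]
            if float(v) != int(v):
                raise ValidationError(f"{k} must be an integer, got {v}")
            d[k] = int(v)
        rows.append(SubjectBehavior(
            subject_id=str(d["subject_id"]), group=str(d["group"]),
            condition=str(d["condition"]), age=float(d["age"]),
            sam_valence=d["sam_valence"], sam_arousal=d["sam_arousal"],
            sam_dominance=d["sam_dominance"],
            confidence_percent=float(d["confidence_percent"]),
        ))
    return rows


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write result DataFrames as full-precision CSVs plus a JSON manifest.

    Every table must be non-empty; identical inputs produce identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if df is None or len(df) == 0:
            raise ValidationError(f"refusing to write empty table {name!r}")
        p = out_dir / f"{name}.csv"
        df.to_csv(p, float_format="%.17g")
        written.append(p)
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
    return written
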