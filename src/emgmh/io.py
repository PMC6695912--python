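"""Reading and writing recordings, manifests, feature matrices and configs.

The canonical on-disk layout is plain text: one RFC-4180 CSV per trial
(header row = channel codes, one row per sample), a JSON manifest per
cohort, and CSV feature matrices carrying instance-identity columns so
that leave-one-patient-out grouping is always reconstructible downstream.
EDF is supported as a read-only convenience for standard biosignal files
(plus a minimal EDF+ writer used for round-trip checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ID_COLUMNS = ["patient", "limb", "motion", "repetition"]
LABEL_COLUMN = "label"


class FormatError(ValueError):
    """Raised when an input file does not match its declared structure."""


@dataclass
class Recording:
    """One multi-channel sEMG trial.

    samples are [n_samples x n_channels] in (opaque) signal units; features
    downstream are unit-covariant where applicable.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D [n_samples x n_channels] array")
        if self.samples.shape[0] == 0:
            raise FormatError("recording has zero samples")
        if self.samples.shape[1] != len(self.channel_names):
            raise FormatError(
                f"{self.samples.shape[1]} columns but {len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 2 * 400.0:
            raise FormatError("sampling_rate must exceed 800 Hz (2 x band-pass upper edge)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rec.samples, columns=rec.channel_names).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def read_recording(path: str | Path, manifest_entry: dict | None = None) -> Recording:
    """Read a per-trial CSV; channel order and count come from the header.

    If ``manifest_entry`` is given its channel list (when present) must match
    the header, and its metadata is attached to the returned recording.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # non-numeric cells etc.
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: recording has zero samples")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row {row}")
    meta = dict(manifest_entry or {})
    declared = meta.get("channels")
    if declared is not None and list(df.columns) != list(declared):
        raise FormatError(
            f"{path}: header channels {list(df.columns)} != declared {list(declared)}"
        )
    fs = float(meta.get("sampling_rate", 1925.93))
    return Recording(df.to_numpy(float), fs, list(df.columns), meta)


# ---------------------------------------------------------------------------
# EDF (read via mne; minimal EDF+ writer for round trips)

def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording; mixed per-channel rates rejected."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne resamples mixed-rate EDF channels silently; detect from the header
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode().strip())
        fh.seek(256 + ns * 216)
        n_per_record = [int(fh.read(8).decode().strip()) for _ in range(ns)]
    if len(set(n_per_record)) > 1:
        raise FormatError(f"{path}: mixed per-channel sampling rates are unsupported")
    data = raw.get_data().T
    # mne rescales dimensioned channels to SI (uV -> V); undo so values
    # round-trip in the file's own (opaque) units
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for j, name in enumerate(raw.ch_names):
        if orig_units.get(name, "").lower() in ("uv", "µv"):
            data[:, j] *= 1e6
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a minimal single-record EDF+ file (16-bit quantization)."""
    path = Path(path)
    n_ch = rec.n_channels
    x = rec.samples
    pmin = x.min(axis=0)
    pmax = x.max(axis=0)
    span = np.where(pmax > pmin, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767
    digital = np.round((x - pmin) / span * (dmax - dmin) + dmin).astype("<i2")

    n_samp = rec.n_samples
    record_dur = n_samp / rec.sampling_rate

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + n_ch * 256), 8), pad("EDF+C", 44),
        pad("1", 8), pad(f"{record_dur:.6f}", 8), pad(str(n_ch), 4),
    ])
    sig_hdr = b"".join([
        b"".join(pad(name, 16) for name in rec.channel_names),
        b"".join(pad("EMG", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:.6g}", 8) for v in pmin),
        b"".join(pad(f"{v:.6g}", 8) for v in np.where(pmax > pmin, pmax, pmin + 1.0)),
        b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        fh.write(digital.T.tobytes())  # record: all samples of ch1, then ch2, ...
    return path


# ---------------------------------------------------------------------------
# Manifests

@dataclass
class DatasetManifest:
    """Cohort manifest: trial entries plus labelling scheme and covariates."""

    trials: list[dict]
    label_scheme: str = "healthy-vs-injured"
    sampling_rate: float = 1925.93
    covariates: dict[str, dict] | None = None  # patient -> ordinal codes
    root: Path | None = None

    def validate(self) -> None:
        if self.label_scheme == "healthy-vs-injured":
            limbs: dict[str, set] = {}
            for t in self.trials:
                limbs.setdefault(t["patient"], set()).add(t["limb"])
            short = [p for p, ls in limbs.items() if len(ls) < 2]
            if short:
                raise FormatError(
                    f"patients with a single limb under healthy-vs-injured: {short}"
                )
        if self.covariates:
            for pid, cov in self.covariates.items():
                for key, val in cov.items():
                    if not (isinstance(val, (int, np.integer)) and val > 0):
                        raise FormatError(
                            f"covariate {key}={val!r} for {pid} is not a non-zero ordinal code"
                        )


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    data = json.loads(path.read_text())
    m = DatasetManifest(
        trials=data["trials"],
        label_scheme=data.get("label_scheme", "healthy-vs-injured"),
        sampling_rate=float(data.get("sampling_rate", 1925.93)),
        covariates=data.get("covariates"),
        root=path.parent,
    )
    m.validate()
    return m


def iter_recordings(manifest: DatasetManifest):
    """Yield (entry, Recording) for every trial in the manifest."""
    for entry in manifest.trials:
        e = dict(entry)
        e.setdefault("sampling_rate", manifest.sampling_rate)
        yield e, read_recording((manifest.root or Path(".")) / e["path"], e)


# ---------------------------------------------------------------------------
# Feature matrices

def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature matrix (id columns + label + feature columns) to CSV."""
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise FormatError(f"duplicate feature columns: {dupes}")
    path = Path(path)
    matrix.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in ID_COLUMNS + [LABEL_COLUMN] if c not in df.columns]
    if missing and len(df):
        raise FormatError(f"feature matrix lacks identity columns: {missing}")
    return df


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    skip = set(ID_COLUMNS + [LABEL_COLUMN, "qc_missing"])
    return [c for c in matrix.columns if c not in skip]


# ---------------------------------------------------------------------------
# Run configuration

def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration."""
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    known = {
        "manifest", "out_dir", "seed", "feature_sets", "classifiers",
        "vote_schemes", "segmenter", "features", "relieff", "model",
    }
    unknown = set(cfg) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("feature_sets", ["FS1", "FS2", "FS3", "FS4", "FS5", "FS5opt"])
    cfg.setdefault("classifiers", ["lda", "svm", "rf"])
    cfg.setdefault("vote_schemes", ["all", "top", "weighted"])
    return cfg
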