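"""Reading, writing and re-referencing of multichannel EEG recordings.

A :class:`Recording` is the package's in-memory container: a channels x
samples matrix in microvolts, a sampling rate, ordered channel labels and a
per-sample artifact mask.  Two on-disk formats are supported:

* European Data Format (EDF), the field's standard interchange format.
  Reading goes through MNE; writing uses a minimal 16-bit EDF writer
  implemented here (only the plain-EDF subset this package needs).
* A delimited-text dialect for human-readable fixtures: a header line
  ``# labels=<comma list> fs=<Hz>`` followed by one whitespace-separated
  row per channel.

Cohort metadata (two sessions per subject, group label, reference
channels) travels as a TSV manifest.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The 27-electrode analysis montage (10-20 extended), in fixed order.
ANALYSIS_CHANNELS_27 = [
    "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8",
    "Fz", "Cz", "Pz",
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6",
    "TP9", "TP10",
]

#: Earlobe electrodes used to build the average reference.
EARLOBE_CHANNELS = ["A1", "A2"]


class FormatError(ValueError):
    """Raised when a file does not parse under the requested format."""


@dataclass
class Recording:
    """One EEG session: channels x samples in microvolts.

    Parameters
    ----------
    data
        Real matrix, shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz, > 0.
    channel_labels
        Unique label per channel, same order as the rows of ``data``.
    artifact_mask
        Boolean per sample, True where contaminated.  Defaults to all
        clean.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.data.shape[1],):
            raise ValueError("artifact_mask length must equal sample count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            artifact_mask=self.artifact_mask.copy(),
        )

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Return a new Recording with channels reordered/subset to `labels`."""
        idx = [self._index(lab) for lab in labels]
        return replace(
            self,
            data=self.data[idx],
            channel_labels=list(labels),
            artifact_mask=self.artifact_mask.copy(),
        )

    def _index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channel_labels}"
            ) from None


@dataclass
class CohortManifest:
    """Per-subject session bookkeeping for a two-session cohort."""

    subject_id: str
    group: str
    session1_path: str
    session2_path: str
    reference_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def _parse_text_header(line: str) -> tuple[list[str], float]:
    line = line.strip()
    if not line.startswith("#"):
        raise FormatError("missing header line ('# labels=... fs=...')")
    body = line.lstrip("#").strip()
    fields: dict[str, str] = {}
    for token in body.split():
        if "=" not in token:
            raise FormatError(f"malformed header token {token!r}")
        key, _, val = token.partition("=")
        fields[key] = val
    if "labels" not in fields:
        raise FormatError("header is missing field 'labels'")
    if "fs" not in fields:
        raise FormatError("header is missing field 'fs'")
    labels = [s for s in fields["labels"].split(",") if s]
    try:
        fs = float(fields["fs"])
    except ValueError:
        raise FormatError(f"header field 'fs' is not numeric: {fields['fs']!r}")
    return labels, fs


def read_text(path: str | Path) -> Recording:
    """Read the delimited-text dialect (header line + one row per channel)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        labels, fs = _parse_text_header(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.split()
            rows.append(vals)
    if len(rows) != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} labels in header but {len(rows)} data rows"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(f"{path}: inconsistent row lengths {sorted(lengths)}")
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample value ({exc})") from None
    return Recording(data=data, fs=fs, channel_labels=labels)


def write_text(rec: Recording, path: str | Path) -> None:
    """Write the delimited-text dialect, full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# labels={','.join(rec.channel_labels)} fs={rec.fs:g}\n")
        for row in rec.data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field too long: {value!r} (> {width})")
    return s.ljust(width).encode("ascii")


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel amplitude resolution (µV) of :func:`write_edf`'s encoding."""
    pmax = np.maximum(np.abs(rec.data).max(axis=1), 1.0)
    return 2 * pmax / (2 * 32767)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a plain-EDF file (16-bit, physical dimension uV).

    Each channel is scaled to a symmetric physical range covering its own
    amplitude extremes, so the quantization step is
    ``2*max|x| / 65534`` µV per channel (see :func:`edf_quantization_step`).
    """
    path = Path(path)
    data = rec.data
    ns = rec.n_channels
    n = rec.n_samples
    # largest samples-per-record that divides the sample count, at most fs
    spr = 1
    for cand in range(min(n, int(round(rec.fs))), 0, -1):
        if n % cand == 0:
            spr = cand
            break
    n_records = n // spr
    duration = spr / rec.fs

    pmax = np.maximum(np.abs(data).max(axis=1), 1.0)
    pmin = -pmax
    # symmetric digital range so physical = digital * pmax / 32767 exactly
    dmax, dmin = 32767, -32767
    gain = 32767 / pmax
    digital = np.clip(np.round(data * gain[:, None]), dmin, dmax).astype("<i2")

    header = _io.BytesIO()
    header.write(_edf_field("0", 8))
    header.write(_edf_field("X X X X", 80))
    header.write(_edf_field("Startdate 01-JAN-2001 X X X", 80))
    header.write(_edf_field("01.01.01", 8))
    header.write(_edf_field("00.00.00", 8))
    header.write(_edf_field(str(256 * (1 + ns)), 8))
    header.write(_edf_field("", 44))
    header.write(_edf_field(str(n_records), 8))
    header.write(_edf_field(f"{duration:.6g}", 8))
    header.write(_edf_field(str(ns), 4))
    for lab in rec.channel_labels:
        header.write(_edf_field(lab, 16))
    for _ in range(ns):
        header.write(_edf_field("", 80))         # transducer
    for _ in range(ns):
        header.write(_edf_field("uV", 8))
    for v in pmin:
        header.write(_edf_field(f"{v:.6g}"[:8], 8))
    for v in pmax:
        header.write(_edf_field(f"{v:.6g}"[:8], 8))
    for _ in range(ns):
        header.write(_edf_field(str(dmin), 8))
    for _ in range(ns):
        header.write(_edf_field(str(dmax), 8))
    for _ in range(ns):
        header.write(_edf_field("", 80))         # prefiltering
    for _ in range(ns):
        header.write(_edf_field(str(spr), 8))
    for _ in range(ns):
        header.write(_edf_field("", 32))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        # record-interleaved: for each record, spr samples of each signal
        blocks = digital.reshape(ns, n_records, spr)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE; amplitudes are converted to microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: not readable as EDF ({exc})") from exc
    data = raw.get_data() * 1e6  # MNE holds volts internally
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "auto") -> Recording:
    """Read a recording in the named format (``edf``, ``delimited_text``).

    ``auto`` dispatches on the file suffix (``.edf`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited_text"
    if format == "edf":
        return read_edf(path)
    if format == "delimited_text":
        return read_text(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited_text"
    if format == "edf":
        write_edf(rec, path)
    elif format == "delimited_text":
        write_text(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def rereference(
    rec: Recording,
    reference_channels: Sequence[str],
    drop: bool = True,
) -> Recording:
    """Subtract the per-sample mean of ``reference_channels`` from every channel.

    This rebuilds the montage against an average-earlobe (or any listed)
    reference.  With ``drop=True`` the reference channels are removed from
    the output, since after subtraction they carry only their own deviation
    from the common reference.
    """
    idx = [rec._index(lab) for lab in reference_channels]
    ref = rec.data[idx].mean(axis=0)
    out = rec.data - ref[None, :]
    labels = list(rec.channel_labels)
    if drop:
        keep = [i for i in range(rec.n_channels) if i not in set(idx)]
        out = out[keep]
        labels = [labels[i] for i in keep]
    return Recording(
        data=out, fs=rec.fs, channel_labels=labels,
        artifact_mask=rec.artifact_mask.copy(),
    )


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "subject_id", "group", "session1_path", "session2_path", "reference_channels",
]


def read_manifest(path: str | Path) -> list[CohortManifest]:
    """Read a cohort manifest TSV (one row per subject, two session paths)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"manifest is missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        refs = [
            s for s in str(row.get("reference_channels", "")).split(",") if s
        ]
        out.append(
            CohortManifest(
                subject_id=row["subject_id"],
                group=row["group"],
                session1_path=row["session1_path"],
                session2_path=row["session2_path"],
                reference_channels=refs,
            )
        )
    return out


def write_manifest(entries: Sequence[CohortManifest], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "group": e.group,
                "session1_path": e.session1_path,
                "session2_path": e.session2_path,
                "reference_channels": ",".join(e.reference_channels),
            }
            for e in entries
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
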