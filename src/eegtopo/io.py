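"""Readers and writers for recordings, distance matrices, diagrams and features.

Recordings come in as EDF (via :mod:`mne`) or as plain CSV whose first row
lists the channel names and whose following rows each hold one channel's
samples (channels x samples).  Group labels (patient / control) live in an
optional JSON sidecar next to the recording file, ``<stem>.json`` with keys
``subject_id`` and ``group``; absent a sidecar the label is ``unknown``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_recording",
    "write_recording_csv",
    "write_diagram",
    "read_diagram",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_feature_table",
    "read_feature_table",
]

GROUP_LABELS = ("patient", "control", "unknown")


@dataclasses.dataclass
class Recording:
    """A multichannel signal block.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the block was recorded from.
    group_label : str
        One of ``patient``, ``control`` or ``unknown``.
    data : ndarray of shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per row of ``data``.
    """

    subject_id: str
    group_label: str
    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.n_channels < 2:
            raise ValueError("a recording needs at least 2 channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match n_channels")
        if len(set(self.channel_names)) != self.n_channels:
            raise ValueError("channel_names must be unique")
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = self.channel_names[int(np.argwhere(bad.any(axis=1))[0][0])]
            raise ValueError(f"non-finite samples in channel {ch!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a recording from an EDF or CSV file.

    The CSV layout is channels x samples: the first row holds the channel
    names, each following row one channel.  ``format`` is inferred from the
    file extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    meta = _read_sidecar(path)
    subject_id = meta.get("subject_id", path.stem)
    group = meta.get("group", "unknown")
    if format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - mne error classes vary
            raise ValueError(f"could not parse {path} as EDF: {exc}") from exc
        data = raw.get_data() * 1e6  # mne loads volts; store microvolts
        names = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    elif format == "csv":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header:
                raise ValueError(f"{path}: empty file")
            names = [c.strip() for c in header.split(",")]
            try:
                data = np.loadtxt(fh, delimiter=",", ndmin=2)
            except ValueError as exc:
                raise ValueError(f"could not parse {path} as CSV: {exc}") from exc
        fs = float(meta.get("fs", 1.0))
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return Recording(
        subject_id=subject_id,
        group_label=group,
        data=data,
        fs=fs,
        channel_names=names,
    )


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write a recording as channels x samples CSV plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data, delimiter=",", fmt="%.17g")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"subject_id": rec.subject_id, "group": rec.group_label, "fs": rec.fs},
            fh,
            indent=2,
        )
    return path


# ---------------------------------------------------------------------------
# persistence diagrams

def write_diagram(pd_obj, path: str | Path) -> Path:
    """Serialize a persistence diagram as a birth,death,dim CSV.

    Essential classes are stored with the literal token ``inf`` so the file
    is lossless and language neutral.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("birth,death,dim\n")
        for b, d, q in pd_obj.pairs:
            death = "inf" if np.isinf(d) else f"{d:.17g}"
            fh.write(f"{b:.17g},{death},{int(q)}\n")
    return path


def read_diagram(path: str | Path, n_nodes: int | None = None):
    """Read a diagram written by :func:`write_diagram`."""
    from .homology import PersistenceDiagram

    path = Path(path)
    pairs = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["birth", "death", "dim"]:
            raise ValueError(f"{path}: expected header birth,death,dim")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                b = float(parts[0])
                d = float(parts[1])
                q = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            pairs.append((b, d, q))
    arr = np.array(pairs, dtype=float).reshape(-1, 3)
    if n_nodes is None:
        n_nodes = int((arr[:, 2] == 0).sum()) if len(arr) else 0
    finite_deaths = arr[np.isfinite(arr[:, 1]), 1] if len(arr) else np.empty(0)
    max_filt = float(finite_deaths.max()) if len(finite_deaths) else 0.0
    return PersistenceDiagram(pairs=arr, n_nodes=n_nodes, max_filtration=max_filt)


# ---------------------------------------------------------------------------
# distance matrices and feature tables

def write_distance_matrix(dm, path: str | Path) -> Path:
    df = pd.DataFrame(dm.D, columns=dm.node_names)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_distance_matrix(path: str | Path):
    from .connectivity import DistanceMatrix

    df = pd.read_csv(path)
    return DistanceMatrix(D=df.to_numpy(dtype=float), node_names=list(df.columns))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    table.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
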