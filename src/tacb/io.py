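"""Reading recordings and writing analysis results.

Time series come in as delimited text (channels as columns, header row of
labels), as raw binary with a JSON sidecar describing shape/dtype/rate, or —
when an EDF backend is installed — as EDF.  Results go out as TSV with a
single ``#``-prefixed JSON metadata line and ``%.12g`` number formatting, so
equal runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, ValidationError
from .group import SubjectQSet
from .spectral import EpochedRecording

__all__ = [
    "read_recording",
    "read_delimited",
    "write_delimited",
    "read_raw_binary",
    "write_raw_binary",
    "read_edf",
    "write_table",
    "read_table",
    "read_qset",
]

FLOAT_FMT = "%.12g"


def _epoch(data: np.ndarray, fs: float, epoch_seconds: float) -> np.ndarray:
    """(channels, samples) -> (channels, epochs, samples_per_epoch), dropping tail."""
    epoch_len = int(round(epoch_seconds * fs))
    if epoch_len < 2:
        raise ValidationError(f"epoch of {epoch_seconds} s too short at fs={fs}")
    n_epochs = data.shape[1] // epoch_len
    if n_epochs < 1:
        raise ValidationError(
            f"{data.shape[1]} samples shorter than one epoch of {epoch_len}"
        )
    return data[:, : n_epochs * epoch_len].reshape(data.shape[0], n_epochs, epoch_len)


def read_delimited(
    path: str | Path,
    fs: float,
    epoch_seconds: float,
    delimiter: str = "\t",
) -> EpochedRecording:
    """Delimited text matrix: one column per channel, header row of labels."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: could not parse delimited matrix: {exc}") from exc
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    try:
        data = frame.to_numpy(dtype=float).T
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values: {exc}") from exc
    labels = [str(c) for c in frame.columns]
    return EpochedRecording(
        data=_epoch(data, fs, epoch_seconds), fs=fs, channel_labels=labels
    )


def write_delimited(rec: EpochedRecording, path: str | Path, delimiter: str = "\t") -> None:
    """Inverse of :func:`read_delimited`; epochs are concatenated in order."""
    path = Path(path)
    c, e, s = rec.data.shape
    flat = rec.data.reshape(c, e * s).T
    header = delimiter.join(rec.channel_labels)
    np.savetxt(path, flat, fmt=FLOAT_FMT, delimiter=delimiter, header=header, comments="")


def read_raw_binary(path: str | Path, sidecar: str | Path | None = None) -> EpochedRecording:
    """Raw numeric array described by a JSON sidecar.

    The sidecar (default ``<path>.json``) must provide ``shape`` (3 ints:
    channels, epochs, samples), ``dtype``, ``fs`` and optionally
    ``channel_labels``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    try:
        meta = json.loads(sidecar.read_text())
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{sidecar}: could not read sidecar: {exc}") from exc
    for key in ("shape", "dtype", "fs"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing required key {key!r}")
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    shape = tuple(int(s) for s in meta["shape"])
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: {data.size} values do not fill shape {shape}"
        )
    return EpochedRecording(
        data=data.reshape(shape).astype(float),
        fs=float(meta["fs"]),
        channel_labels=meta.get("channel_labels"),
    )


def write_raw_binary(rec: EpochedRecording, path: str | Path) -> None:
    path = Path(path)
    rec.data.astype(np.float64).tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(rec.data.shape),
                "dtype": "float64",
                "fs": rec.fs,
                "channel_labels": rec.channel_labels,
            },
            indent=1,
        )
    )


def read_edf(path: str | Path, epoch_seconds: float) -> EpochedRecording:
    """EDF input via ``pyedflib`` or ``mne`` when available (optional extras)."""
    path = Path(path)
    try:
        import pyedflib  # type: ignore[import-not-found]
    except ImportError:
        pyedflib = None
    if pyedflib is not None:
        reader = pyedflib.EdfReader(str(path))
        try:
            n = reader.signals_in_file
            fs = float(reader.getSampleFrequency(0))
            data = np.stack([reader.readSignal(i) for i in range(n)])
            labels = list(reader.getSignalLabels())
        finally:
            reader.close()
        return EpochedRecording(
            data=_epoch(data, fs, epoch_seconds), fs=fs, channel_labels=labels
        )
    try:
        import mne  # type: ignore[import-not-found]
    except ImportError as exc:
        raise ImportError(
            "EDF input requires the optional 'pyedflib' or 'mne' package"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EpochedRecording(
        data=_epoch(raw.get_data(), float(raw.info["sfreq"]), epoch_seconds),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def read_recording(
    path: str | Path,
    fs: float | None = None,
    epoch_seconds: float | None = None,
    fmt: str | None = None,
    delimiter: str = "\t",
) -> EpochedRecording:
    """Dispatch on file extension (or explicit ``fmt``): tsv/csv/txt, bin, edf."""
    path = Path(path)
    fmt = fmt or {
        ".tsv": "delimited",
        ".txt": "delimited",
        ".csv": "delimited",
        ".bin": "binary",
        ".dat": "binary",
        ".edf": "edf",
    }.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"{path}: cannot infer format from extension")
    if fmt == "binary":
        return read_raw_binary(path)
    if epoch_seconds is None:
        raise ValidationError("epoch_seconds is required for text/EDF input")
    if fmt == "edf":
        return read_edf(path, epoch_seconds)
    if fs is None:
        raise ValidationError("fs is required for delimited input")
    if path.suffix.lower() == ".csv" and delimiter == "\t":
        delimiter = ","
    return read_delimited(path, fs, epoch_seconds, delimiter=delimiter)


def write_table(frame: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """TSV with one ``#``-prefixed JSON metadata line and %.12g formatting."""
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("package_version", __version__)
    lines = ["# " + json.dumps(meta, sort_keys=True)]
    lines.append("\t".join(str(c) for c in frame.columns))
    for row in frame.itertuples(index=False):
        cells = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                cells.append(FLOAT_FMT % v)
            elif isinstance(v, (bool, np.bool_)):
                cells.append("1" if v else "0")
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                metadata = json.loads(first.lstrip("# ").strip())
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:1: bad metadata line: {exc}") from exc
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t")
    return frame, metadata


def read_qset(path: str | Path, subject: str | None = None, group: str | None = None) -> SubjectQSet:
    """Build a per-subject Q set from a per-triple statistics TSV.

    Expects columns ``i``, ``j``, ``k`` (integer channel indices) and ``q``;
    channel labels and count are taken from the metadata line when present.
    """
    frame, meta = read_table(path)
    for col in ("i", "j", "k", "q"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    n_channels = int(meta.get("n_channels", frame[["i", "j", "k"]].to_numpy().max() + 1))
    order = np.lexsort((frame["k"], frame["j"], frame["i"]))
    return SubjectQSet(
        subject=subject or str(meta.get("subject", Path(path).stem)),
        n_channels=n_channels,
        q=frame["q"].to_numpy()[order],
        channel_labels=list(meta.get("channel_labels", [])),
        group=group,
    )
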