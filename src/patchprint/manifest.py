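"""Reading and writing recordings and dataset manifests.

Canonical on-disk layout: one UTF-8 text file per recording with one current
value (pA) per line, optional ``#``-prefixed header lines carrying metadata,
plus a JSON manifest (an array of entry records) living next to the trace
files.  A minimal Axon-text (ATF) dialect is supported on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError
from .gating import Recording

MANIFEST_NAME = "manifest.json"

# Header keys written by write_recording, in order.
_HEADER_KEYS = ("recording_id", "cell_label", "potential_mV", "sampling_rate_Hz")


@dataclass(frozen=True)
class ManifestEntry:
    recording_id: str
    file: str  # path relative to the manifest's directory
    cell_label: str
    potential_mV: float
    sampling_rate_Hz: float
    provenance: dict

    def to_json(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "file": self.file,
            "cell_label": self.cell_label,
            "potential_mV": self.potential_mV,
            "sampling_rate_Hz": self.sampling_rate_Hz,
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class DatasetManifest:
    root: Path
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.recording_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise DataError("manifest contains duplicate recording_ids")
        for e in self.entries:
            if not np.isfinite(e.potential_mV):
                raise DataError(f"non-finite potential for {e.recording_id!r}")


def write_recording(recording: Recording, path: str | Path, dialect: str = "plain") -> Path:
    """Write a recording as text; round-trips with :func:`read_recording`.

    Values are printed with 6 decimal places (the pA resolution of the
    acquisition hardware), which makes repeated writes byte-identical.
    """
    if dialect != "plain":
        raise DataError(f"cannot write dialect {dialect!r}; only 'plain' is supported")
    path = Path(path)
    lines = [
        f"# recording_id: {recording.recording_id}",
        f"# cell_label: {recording.cell_label}",
        f"# potential_mV: {recording.potential:g}",
        f"# sampling_rate_Hz: {recording.sampling_rate:g}",
    ]
    lines.extend(f"{v:.6f}" for v in recording.trace)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _parse_plain(lines: list[str], path: Path) -> tuple[np.ndarray, dict]:
    meta: dict = {}
    values: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise DataError(f"{path}: non-numeric value on line {lineno}: {line!r}") from None
    return np.asarray(values, dtype=float), meta


def _parse_atf(lines: list[str], path: Path) -> tuple[np.ndarray, dict]:
    # ATF layout: "ATF <version>", then "<nHeader> <nColumns>", nHeader
    # optional header records, one column-title line, then the data table.
    # The current column is the last one (first column is usually time).
    try:
        n_header = int(lines[1].split()[0])
    except (IndexError, ValueError):
        raise DataError(f"{path}: malformed ATF header") from None
    data_start = 2 + n_header + 1
    values: list[float] = []
    for lineno, raw in enumerate(lines[data_start:], start=data_start + 1):
        line = raw.strip()
        if not line:
            continue
        try:
            values.append(float(line.split()[-1]))
        except ValueError:
            raise DataError(f"{path}: non-numeric value on line {lineno}: {line!r}") from None
    return np.asarray(values, dtype=float), {}


def read_recording(path: str | Path, dialect: str = "auto") -> Recording:
    """Read one trace file (values in pA) into a :class:`Recording`.

    ``dialect`` is ``plain``, ``atf`` or ``auto`` (sniffs the ATF magic).
    Header metadata is attached when present; missing metadata falls back to
    the file stem and benign defaults.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"trace file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not any(line.strip() for line in lines):
        raise DataError(f"{path}: empty trace file")
    if dialect == "auto":
        dialect = "atf" if lines and lines[0].startswith("ATF") else "plain"
    if dialect == "plain":
        values, meta = _parse_plain(lines, path)
    elif dialect == "atf":
        values, meta = _parse_atf(lines, path)
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    if values.size == 0:
        raise DataError(f"{path}: no data lines")
    return Recording(
        recording_id=meta.get("recording_id", path.stem),
        cell_label=meta.get("cell_label", "unknown"),
        potential=float(meta.get("potential_mV", "nan"))
        if "potential_mV" in meta
        else 0.0,
        trace=values,
        sampling_rate=float(meta.get("sampling_rate_Hz", 1.0)),
        provenance={},
    )


def write_dataset(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write trace files plus ``manifest.json``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.recording_id}.txt"
        write_recording(rec, out_dir / fname)
        entries.append(
            ManifestEntry(
                recording_id=rec.recording_id,
                file=fname,
                cell_label=rec.cell_label,
                potential_mV=rec.potential,
                sampling_rate_Hz=rec.sampling_rate,
                provenance=dict(rec.provenance),
            )
        )
    manifest = DatasetManifest(root=out_dir, entries=tuple(entries))
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(
        json.dumps([e.to_json() for e in manifest.entries], indent=1, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    return manifest_path


def read_manifest(manifest_path: str | Path) -> DatasetManifest:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    try:
        raw = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed manifest {manifest_path}: {exc}") from exc
    entries = tuple(
        ManifestEntry(
            recording_id=e["recording_id"],
            file=e["file"],
            cell_label=e["cell_label"],
            potential_mV=float(e["potential_mV"]),
            sampling_rate_Hz=float(e["sampling_rate_Hz"]),
            provenance=e.get("provenance", {}),
        )
        for e in raw
    )
    return DatasetManifest(root=manifest_path.parent, entries=entries)


def load_dataset(
    manifest_path: str | Path,
    labels: list[str] | None = None,
    potentials: list[float] | None = None,
) -> dict[tuple[str, float], list[Recording]]:
    """Load recordings grouped by (cell_label, potential).

    Filters are applied to the manifest before any file is read.  Filtering
    to an unknown label or potential yields an empty result with a warning.
    """
    manifest = read_manifest(manifest_path)
    entries = list(manifest.entries)
    if labels is not None:
        known = {e.cell_label for e in entries}
        unknown = set(labels) - known
        if unknown:
            warnings.warn(f"filter labels not in manifest: {sorted(unknown)}")
        entries = [e for e in entries if e.cell_label in set(labels)]
    if potentials is not None:
        known_u = {e.potential_mV for e in entries}
        unknown_u = set(potentials) - known_u
        if unknown_u:
            warnings.warn(f"filter potentials not in manifest: {sorted(unknown_u)}")
        entries = [e for e in entries if e.potential_mV in set(potentials)]

    grouped: dict[tuple[str, float], list[Recording]] = {}
    for e in entries:
        fpath = manifest.root / e.file
        if not fpath.exists():
            raise DataError(f"missing trace file for recording {e.recording_id!r}: {fpath}")
        rec = read_recording(fpath)
        rec = Recording(
            recording_id=e.recording_id,
            cell_label=e.cell_label,
            potential=e.potential_mV,
            trace=rec.trace,
            sampling_rate=e.sampling_rate_Hz,
            provenance=dict(e.provenance),
        )
        grouped.setdefault((e.cell_label, e.potential_mV), []).append(rec)
    return grouped
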