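"""File I/O: a minimal WFDB codec, plain-text traces, and segment archives.

The WFDB support here is a deliberately small codec for single-signal
format-16 records (the layout used by the PhysioNet ECG databases this
system targets): a text header `<name>.hea` plus little-endian int16
samples in `<name>.dat`, amplitude scaled by the ADC gain.  It reads what
it writes and the common single-lead subset of real headers; multi-signal
records and the exotic formats are out of scope.

Plain-text traces are one sample per line with the sampling rate and
labels in a JSON sidecar `<name>.json`.

Segment archives are NumPy `.npz` containers with an index of
(identity, offset) pairs, written by the preprocess CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocessing import ECGRecording, ECGSegment

__all__ = [
    "write_wfdb", "read_wfdb", "write_text_record", "read_text_record",
    "write_segments", "read_segments", "write_registry", "read_registry",
]

_WFDB_GAIN = 1000.0  # ADC units per physical unit; plenty for z-scored mV-scale ECG


def write_wfdb(recording: ECGRecording, directory, record_name: str) -> Path:
    """Write a single-signal format-16 WFDB record; returns the header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = recording.samples.size
    quant = np.clip(np.round(recording.samples * _WFDB_GAIN), -32768, 32767)
    data = quant.astype("<i2")
    (directory / f"{record_name}.dat").write_bytes(data.tobytes())
    checksum = int(data.astype(np.int64).sum() % 65536)
    rate = recording.sampling_rate
    rate_str = f"{rate:g}"
    header = (
        f"{record_name} 1 {rate_str} {n}\n"
        f"{record_name}.dat 16 {_WFDB_GAIN:g} 16 0 {int(data[0])} {checksum} 0 ECG\n"
        f"# identity_id: {recording.identity_id}\n"
        f"# database_id: {recording.database_id}\n"
        f"# session_start: {recording.session_start}\n"
    )
    (directory / f"{record_name}.hea").write_text(header)
    return directory / f"{record_name}.hea"


def read_wfdb(header_path) -> ECGRecording:
    """Read a single-signal format-16 WFDB record written by this package
    or any conforming single-lead record."""
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text().splitlines() if ln.strip()]
    rec_fields = lines[0].split()
    record_name, n_sig = rec_fields[0], int(rec_fields[1])
    if n_sig != 1:
        raise ValueError(f"only single-signal records supported, got {n_sig}")
    rate = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else -1
    sig = lines[1].split()
    fname, fmt = sig[0], sig[1]
    if fmt.split("+")[0] != "16":
        raise ValueError(f"only format 16 supported, got {fmt}")
    gain = float(sig[2].split("(")[0].split("/")[0]) if len(sig) > 2 else 200.0
    if gain == 0:
        gain = 200.0
    meta = {"identity_id": record_name, "database_id": "", "session_start": 0.0}
    for ln in lines[2:]:
        if ln.startswith("#") and ":" in ln:
            key, _, val = ln[1:].partition(":")
            key = key.strip()
            if key in meta:
                meta[key] = val.strip()
    raw = np.frombuffer((header_path.parent / fname).read_bytes(), dtype="<i2")
    if n_samples > 0:
        raw = raw[:n_samples]
    return ECGRecording(
        samples=raw.astype(np.float64) / gain,
        sampling_rate=rate,
        identity_id=str(meta["identity_id"]),
        database_id=str(meta["database_id"]),
        session_start=float(meta["session_start"]),
    )


def write_text_record(recording: ECGRecording, path) -> Path:
    """One sample per line; rate and labels in a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, recording.samples, fmt="%.9g")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "identity_id": recording.identity_id,
        "database_id": recording.database_id,
        "session_start": recording.session_start,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_text_record(path) -> ECGRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    samples = np.loadtxt(path, ndmin=1)
    return ECGRecording(samples=samples, **sidecar)


def write_segments(segments: list[ECGSegment], path) -> Path:
    """Segments to an .npz archive with an (identity, offset) index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.stack([s.values for s in segments]) if segments else np.empty((0, 384))
    identities = np.array([s.source_identity for s in segments], dtype=object)
    offsets = np.array([s.source_offset for s in segments], dtype=np.int64)
    standardized = np.array([s.standardized for s in segments], dtype=bool)
    np.savez(path, values=values, identities=identities, offsets=offsets,
             standardized=standardized, allow_pickle=True)
    return path


def read_segments(path) -> list[ECGSegment]:
    with np.load(path, allow_pickle=True) as archive:
        return [
            ECGSegment(values=v, source_identity=str(i), source_offset=int(o),
                       standardized=bool(s))
            for v, i, o, s in zip(archive["values"], archive["identities"],
                                  archive["offsets"], archive["standardized"])
        ]


def write_registry(registry, directory, extra_meta: dict | None = None) -> Path:
    """A registry as WFDB records plus a JSON manifest of identities,
    session times, and split ratios."""
    from .dataset import DatabaseRegistry  # local import avoids a cycle

    assert isinstance(registry, DatabaseRegistry)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"databases": [], "meta": extra_meta or {}}
    for db in registry.databases:
        entry = {"database_id": db.database_id,
                 "sampling_rate": db.sampling_rate,
                 "split_ratio": list(db.split_ratio),
                 "identities": {}}
        for ident, recs in db.recordings.items():
            names = []
            for i, rec in enumerate(recs):
                name = f"{ident}_r{i}"
                write_wfdb(rec, directory, name)
                names.append(name)
            entry["identities"][ident] = names
        manifest["databases"].append(entry)
    (directory / "registry.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_registry(directory):
    from .dataset import DatabaseEntry, DatabaseRegistry

    directory = Path(directory)
    manifest = json.loads((directory / "registry.json").read_text())
    databases = []
    for entry in manifest["databases"]:
        recordings = {
            ident: [read_wfdb(directory / f"{name}.hea") for name in names]
            for ident, names in entry["identities"].items()
        }
        databases.append(DatabaseEntry(
            database_id=entry["database_id"],
            sampling_rate=entry["sampling_rate"],
            recordings=recordings,
            split_ratio=tuple(entry["split_ratio"])))
    return DatabaseRegistry(databases)
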