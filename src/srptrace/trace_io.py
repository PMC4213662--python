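"""Reading and writing trace datasets in stable text formats.

Canonical interchange format: one TSV file per trace (columns ``time``,
``donor``, ``acceptor``, ``trna``; UTF-8, '.' decimal) plus a JSON
manifest.  Floats are written in their shortest round-trip representation
(Python ``repr``), which makes write -> read -> write byte-stable.  The
ground-truth sidecar produced by the simulator lives in the same
directory under a clearly separated name (``ground_truth.json``) so the
analysis chain can be run blind to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DATASET_SCHEMA = "srptrace-dataset/1"
MANIFEST_NAME = "manifest.json"
SIDECAR_NAME = "ground_truth.json"


@dataclass
class Trace:
    """One three-channel fluorescence time series.

    ``times`` are frame midpoints (s); the three channels are per-frame
    intensities in arbitrary units.  ``meta`` carries at least the frame
    interval and the RNC identifier.
    """

    rnc_id: str
    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    trna: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.trna = np.asarray(self.trna, dtype=float)
        n = self.times.size
        if not (self.donor.size == self.acceptor.size == self.trna.size == n):
            raise ValueError(f"trace {self.rnc_id}: ragged channel lengths")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError(f"trace {self.rnc_id}: times not uniformly spaced")

    @property
    def frame_interval(self) -> float:
        if "frame_interval" in self.meta:
            return float(self.meta["frame_interval"])
        if self.times.size >= 2:
            return float(self.times[1] - self.times[0])
        raise ValueError("frame interval unknown")


@dataclass
class Dataset:
    """A list of traces plus dataset-level metadata."""

    traces: list[Trace]
    manifest: dict = field(default_factory=lambda: {"schema": DATASET_SCHEMA})

    def __post_init__(self) -> None:
        ids = [t.rnc_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rnc_ids in dataset")
        schema = self.manifest.get("schema")
        if schema != DATASET_SCHEMA:
            raise ValueError(f"unrecognized dataset schema {schema!r}")

    def __len__(self) -> int:
        return len(self.traces)


def _fmt(x: float) -> str:
    """Shortest round-trip decimal representation of a float."""
    return repr(float(x))


def write_dataset(
    ds: Dataset, path, ground_truth: list | None = None, container: str = "tsv"
) -> None:
    """Write a dataset as per-trace TSV files plus a JSON manifest.

    ``ground_truth`` (optional) is the simulator sidecar; it is serialized
    to ``ground_truth.json`` next to the manifest.  ``container="hdf5"``
    writes a single HDF5 file at ``path`` instead, with the identical
    logical schema (one group per trace, manifest and sidecar as JSON
    attributes).
    """
    if container == "hdf5":
        _write_hdf5(ds, path, ground_truth)
        return
    if container != "tsv":
        raise ValueError(f"unknown container {container!r}")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in ds.traces:
        for name, ch in (
            ("donor", tr.donor),
            ("acceptor", tr.acceptor),
            ("trna", tr.trna),
        ):
            if np.any(~np.isfinite(ch)):
                raise ValueError(f"trace {tr.rnc_id}: non-finite {name} intensities")
        fname = f"{tr.rnc_id}.tsv"
        lines = ["time\tdonor\tacceptor\ttrna"]
        for t, d, a, f in zip(tr.times, tr.donor, tr.acceptor, tr.trna):
            lines.append(f"{_fmt(t)}\t{_fmt(d)}\t{_fmt(a)}\t{_fmt(f)}")
        (root / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
        entries.append({"rnc_id": tr.rnc_id, "file": fname, "meta": tr.meta})
    manifest = dict(ds.manifest)
    manifest["traces"] = entries
    (root / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    if ground_truth is not None:
        (root / SIDECAR_NAME).write_text(
            json.dumps(_gt_payload(ground_truth)) + "\n", encoding="utf-8"
        )


def _gt_payload(ground_truth: list) -> list:
    payload = []
    for gt in ground_truth:
        payload.append(
            {
                "rnc_id": gt.rnc_id,
                "seed": gt.seed,
                "join_time": gt.join_time,
                "bleach_time": gt.bleach_time,
                "duration": gt.duration,
                "codon_completion_times": list(map(float, gt.codon_completion_times)),
                "srp_intervals": [list(iv) for iv in gt.srp_intervals],
                "trna_intervals": [list(iv) for iv in gt.trna_intervals],
            }
        )
    return payload


def _write_hdf5(ds: Dataset, path, ground_truth: list | None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        manifest = dict(ds.manifest)
        manifest["traces"] = [
            {"rnc_id": tr.rnc_id, "meta": tr.meta} for tr in ds.traces
        ]
        fh.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        grp = fh.create_group("traces")
        for tr in ds.traces:
            for name, ch in (("donor", tr.donor), ("acceptor", tr.acceptor),
                             ("trna", tr.trna)):
                if np.any(~np.isfinite(ch)):
                    raise ValueError(
                        f"trace {tr.rnc_id}: non-finite {name} intensities"
                    )
            g = grp.create_group(tr.rnc_id)
            for name, ch in (("time", tr.times), ("donor", tr.donor),
                             ("acceptor", tr.acceptor), ("trna", tr.trna)):
                g.create_dataset(name, data=np.asarray(ch, dtype=float))
        if ground_truth is not None:
            fh.attrs["ground_truth"] = json.dumps(_gt_payload(ground_truth))


def _read_hdf5(path) -> Dataset:
    import h5py

    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs["manifest"])
        schema = manifest.get("schema")
        if schema != DATASET_SCHEMA:
            raise ValueError(f"unknown dataset schema {schema!r}")
        meta_by_id = {e["rnc_id"]: e.get("meta", {}) for e in manifest.pop("traces", [])}
        traces = []
        for rid in fh["traces"]:
            g = fh["traces"][rid]
            traces.append(
                Trace(
                    rnc_id=rid,
                    times=g["time"][()],
                    donor=g["donor"][()],
                    acceptor=g["acceptor"][()],
                    trna=g["trna"][()],
                    meta=dict(meta_by_id.get(rid, {})),
                )
            )
    return Dataset(traces=traces, manifest=manifest)


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Accepts either the TSV directory layout or the single-file HDF5
    container.  Validates the manifest schema and per-trace channel
    invariants; never touches the ground-truth sidecar.
    """
    root = Path(path)
    if root.is_file():
        return _read_hdf5(root)
    mpath = root / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"missing dataset manifest: {mpath}")
    manifest = json.loads(mpath.read_text(encoding="utf-8"))
    schema = manifest.get("schema")
    if schema != DATASET_SCHEMA:
        raise ValueError(f"unknown dataset schema {schema!r}")
    traces = []
    for entry in manifest.pop("traces", []):
        fpath = root / entry["file"]
        cols = {"time": [], "donor": [], "acceptor": [], "trna": []}
        with open(fpath, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["time", "donor", "acceptor", "trna"]:
                raise ValueError(f"trace {entry['rnc_id']}: bad TSV header {header}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(
                        f"trace {entry['rnc_id']}: ragged channel lengths"
                    )
                for key, val in zip(cols, parts):
                    cols[key].append(float(val))
        traces.append(
            Trace(
                rnc_id=entry["rnc_id"],
                times=np.array(cols["time"]),
                donor=np.array(cols["donor"]),
                acceptor=np.array(cols["acceptor"]),
                trna=np.array(cols["trna"]),
                meta=dict(entry.get("meta", {})),
            )
        )
    return Dataset(traces=traces, manifest=manifest)


def read_ground_truth(path) -> list:
    """Load the simulator sidecar (for oracle tests only)."""
    from .simulate import StateTrajectory

    root = Path(path)
    payload = json.loads((root / SIDECAR_NAME).read_text(encoding="utf-8"))
    out = []
    for d in payload:
        out.append(
            StateTrajectory(
                rnc_id=d["rnc_id"],
                seed=d["seed"],
                join_time=d["join_time"],
                bleach_time=d["bleach_time"],
                duration=d["duration"],
                codon_completion_times=np.array(d["codon_completion_times"]),
                srp_intervals=[tuple(iv) for iv in d["srp_intervals"]],
                trna_intervals=[tuple(iv) for iv in d["trna_intervals"]],
            )
        )
    return out


def events_to_tsv(df, path) -> None:
    """Export a result table (events, fits, profiles) as TSV."""
    df.to_csv(path, sep="\t", index=False)
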