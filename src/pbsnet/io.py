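"""Readers and writers for the pipeline's on-disk formats.

NIfTI volumes (masks, label maps) go through nibabel; streamlines are read
from TRK/TCK via ``nibabel.streamlines`` or from a plain JSON point-list
dialect used for fixtures; matrices and tidy tables are TSV with JSON
sidecars carrying metadata (node sizes, parcellation id, kind).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .voxel_graph import GrayMatterMask
from .networks import StreamlineSet, ConnectivityMatrix


# ---------- NIfTI volumes ----------

def save_mask(mask: GrayMatterMask, path) -> None:
    affine = np.diag(list(mask.voxel_size) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path, threshold: float = 0.5) -> GrayMatterMask:
    """Load a binary or probabilistic mask; probabilistic maps are
    thresholded (default 0.5)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return GrayMatterMask(data >= threshold, voxel_size=vs)


def save_labels(label_volume: np.ndarray, path, voxel_size=(1., 1., 1.)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(label_volume.astype(np.int32), affine), str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int32)


# ---------- streamlines ----------

def save_streamlines_json(sls: StreamlineSet, path) -> None:
    payload = {"frame": sls.frame,
               "streamlines": [s.tolist() for s in sls.streamlines]}
    Path(path).write_text(json.dumps(payload))


def load_streamlines(path, frame: str | None = None) -> StreamlineSet:
    """Load TRK/TCK (via nibabel) or the JSON point-list dialect."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return StreamlineSet(streamlines=[np.asarray(s) for s in payload["streamlines"]],
                             frame=payload.get("frame", frame or "voxel"))
    tf = nib.streamlines.load(str(path))
    return StreamlineSet(streamlines=list(tf.streamlines), frame=frame or "mm")


def save_streamlines_tck(sls: StreamlineSet, path) -> None:
    t = nib.streamlines.Tractogram(sls.streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(t, str(path))


# ---------- matrices and tables ----------

def save_connectivity(c: ConnectivityMatrix, path) -> None:
    """TSV matrix plus a .json sidecar with node sizes, kind and id."""
    path = Path(path)
    np.savetxt(path, c.weights, delimiter="\t")
    sidecar = {"kind": c.kind, "parcellation_id": int(c.parcellation_id),
               "node_sizes": [int(s) for s in c.node_sizes]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    w = read_tsv_matrix(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConnectivityMatrix(weights=w,
                              node_sizes=np.array(sidecar["node_sizes"]),
                              kind=sidecar["kind"],
                              parcellation_id=sidecar["parcellation_id"])


def read_tsv_matrix(path) -> np.ndarray:
    """Strict TSV matrix reader: ragged rows raise with the line number."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(f"{path}: ragged row at line {lineno} "
                                 f"({len(cells)} fields, expected {width})")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value at line {lineno}") from exc
    return np.asarray(rows)


def save_mfcv_table(mfcvs: list, path) -> None:
    """Tidy TSV store: subject, session, parcellation_rank, mean_fc."""
    recs = [(m.subject, m.session, r, v)
            for m in mfcvs for r, v in enumerate(m.values)]
    pd.DataFrame(recs, columns=["subject", "session", "parcellation_rank",
                                "mean_fc"]).to_csv(path, sep="\t", index=False)


def load_mfcv_table(path) -> list:
    from .fingerprint import MeanFCVector
    df = pd.read_csv(path, sep="\t")
    out = []
    for (subj, sess), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("parcellation_rank")
        out.append(MeanFCVector(subject=int(subj), session=int(sess),
                                values=grp["mean_fc"].to_numpy()))
    return out


# ---------- run manifest ----------

@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    tool_version: str
    config: dict
    seeds: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    error: str | None = None
    _t0: dict = field(default_factory=dict, repr=False)

    def hash_input(self, path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_hashes[str(path)] = h

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.timings[stage] = round(time.perf_counter() - self._t0.pop(stage), 3)

    def write(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        Path(path).write_text(json.dumps(d, indent=2, default=str))
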