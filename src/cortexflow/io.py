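"""Serialization: HDF5 for weights, TIFF/CSV for stimuli and responses."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import tifffile

from .classifiers import CNN, CNNConfig, MLP, Perceptron
from .midstage import CellPlaneNet, HebbNet
from .mosaic import Mosaic, MosaicConfig
from .neural_field import FieldParams, FieldState


# -- neural fields ----------------------------------------------------------

def _write_csr(grp: h5py.Group, name: str, m: sp.csr_matrix) -> None:
    g = grp.create_group(name)
    g.create_dataset("data", data=m.data)
    g.create_dataset("indices", data=m.indices)
    g.create_dataset("indptr", data=m.indptr)
    g.attrs["shape"] = m.shape


def _read_csr(grp: h5py.Group, name: str) -> sp.csr_matrix:
    g = grp[name]
    return sp.csr_matrix(
        (g["data"][...], g["indices"][...], g["indptr"][...]),
        shape=tuple(g.attrs["shape"]),
    )


def _write_params(grp: h5py.Group, params: FieldParams) -> None:
    grp.attrs["params_json"] = json.dumps(dataclasses.asdict(params))


def _read_params(grp: h5py.Group) -> FieldParams:
    d = json.loads(grp.attrs["params_json"])
    d["aff_window"] = tuple(d["aff_window"])
    d["settle_window"] = tuple(d["settle_window"])
    return FieldParams(**d)


def write_field(grp: h5py.Group, state: FieldState) -> None:
    _write_params(grp, state.params)
    grp.create_dataset("W_aff", data=state.W_aff)
    _write_csr(grp, "E", state.E)
    _write_csr(grp, "I", state.I)
    grp.create_dataset("eta", data=state.eta)
    grp.create_dataset("eta_prev", data=state.eta_prev)


def read_field(grp: h5py.Group) -> FieldState:
    return FieldState(
        params=_read_params(grp),
        W_aff=grp["W_aff"][...],
        E=_read_csr(grp, "E"),
        I=_read_csr(grp, "I"),
        eta=grp["eta"][...],
        eta_prev=grp["eta_prev"][...],
    )


def save_field(path, state: FieldState) -> None:
    with h5py.File(path, "w") as f:
        write_field(f, state)


def load_field(path) -> FieldState:
    with h5py.File(path, "r") as f:
        return read_field(f)


# -- mosaics ----------------------------------------------------------------

def save_mosaic(path, mosaic: Mosaic) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["grid"] = mosaic.config.grid
        f.attrs["share_weights"] = mosaic.config.share_weights
        f.attrs["side"] = mosaic.config.side
        for i, st in enumerate(mosaic.tiles):
            write_field(f.create_group(f"tile_{i:03d}"), st)


def load_mosaic(path) -> Mosaic:
    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if k.startswith("tile_"))
        tiles = [read_field(f[k]) for k in names]
        cfg = MosaicConfig(
            grid=int(f.attrs["grid"]),
            tile_params=tiles[0].params,
            share_weights=bool(f.attrs["share_weights"]),
            side=int(f.attrs["side"]),
        )
    return Mosaic(cfg, tiles)


# -- mid-stage and output nets ----------------------------------------------

def save_cpnw(path, net: CellPlaneNet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=net.W)
        f.attrs["grid"] = net.grid
        if net.plane_labels is not None:
            f.create_dataset("plane_labels", data=net.plane_labels)


def load_cpnw(path) -> CellPlaneNet:
    with h5py.File(path, "r") as f:
        labels = f["plane_labels"][...] if "plane_labels" in f else None
        return CellPlaneNet(W=f["W"][...], plane_labels=labels, grid=int(f.attrs["grid"]))


def save_hbnw(path, net: HebbNet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=net.W)
        f.attrs["grid"] = net.grid


def load_hbnw(path) -> HebbNet:
    with h5py.File(path, "r") as f:
        return HebbNet(W=f["W"][...], grid=int(f.attrs["grid"]))


def save_perceptron(path, model: Perceptron) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("classes", data=np.asarray(model.classes))


def load_perceptron(path) -> Perceptron:
    with h5py.File(path, "r") as f:
        return Perceptron(W=f["W"][...], classes=f["classes"][...])


def save_mlp(path, model: MLP) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layer_sizes"] = model.layer_sizes
        for i, (W, b) in enumerate(model.weights):
            g = f.create_group(f"layer_{i}")
            g.create_dataset("W", data=W)
            g.create_dataset("b", data=b)


def load_mlp(path) -> MLP:
    with h5py.File(path, "r") as f:
        sizes = tuple(int(s) for s in f.attrs["layer_sizes"])
        weights = [
            (f[f"layer_{i}"]["W"][...], f[f"layer_{i}"]["b"][...])
            for i in range(len(sizes) - 1)
        ]
    return MLP(weights=weights, layer_sizes=sizes)


def save_cnn(path, model: CNN) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(model.config))
        f.create_dataset("K", data=model.K)
        f.create_dataset("bK", data=model.bK)
        if model.mu is not None:
            f.create_dataset("mu", data=model.mu)
        for i, (W, b) in enumerate(model.fc):
            g = f.create_group(f"fc_{i}")
            g.create_dataset("W", data=W)
            g.create_dataset("b", data=b)


def load_cnn(path) -> CNN:
    with h5py.File(path, "r") as f:
        d = json.loads(f.attrs["config_json"])
        d["fc_sizes"] = tuple(d["fc_sizes"])
        cfg = CNNConfig(**d)
        fc = [
            (f[f"fc_{i}"]["W"][...], f[f"fc_{i}"]["b"][...])
            for i in range(len(cfg.fc_sizes) + 1)
        ]
        mu = f["mu"][...] if "mu" in f else None
        return CNN(config=cfg, K=f["K"][...], bK=f["bK"][...], fc=fc, mu=mu)


# -- stimuli ----------------------------------------------------------------

def save_sequence(path, seq) -> None:
    """Multi-page TIFF plus a JSON sidecar with the motion spec."""
    path = Path(path)
    tifffile.imwrite(path, (seq.frames * 255).astype(np.uint8), photometric="minisblack")
    meta = {
        "kind": seq.spec.kind,
        "direction_deg": seq.spec.direction_deg,
        "speed": seq.spec.speed,
        "n_frames": seq.spec.n_frames,
        "seed": seq.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def save_manifest(path, rows) -> None:
    """Dataset manifest CSV with columns path, split, class_label."""
    pd.DataFrame(rows, columns=["path", "split", "class_label"]).to_csv(
        path, index=False
    )


def save_rsm_csv(path, rsm) -> None:
    labels = [f"{c}|{i}" for c, i in rsm.row_labels]
    pd.DataFrame(rsm.matrix, index=labels, columns=labels).to_csv(path)
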