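"""HDF5 and TSV persistence for simulated volumes, runs, and label maps."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synthetic import BoldRun, ColumnLabelMap, LaminarSheet, Volume


def save_volume(path: str, volume: Volume,
                labels: ColumnLabelMap | None = None) -> None:
    """Write a volume (and optionally its label map) to an HDF5 container."""
    sheet = volume.sheet
    with h5py.File(path, "w") as h5:
        h5.create_dataset("/volume", data=volume.data)
        h5.create_dataset("/depth_axis_mm", data=sheet.depth_axis)
        h5.create_dataset("/thickness_mm", data=sheet.thickness)
        h5.attrs["dx_mm"] = sheet.dx
        if labels is not None:
            h5.create_dataset("/labels", data=labels.labels)
            h5["/labels"].attrs["centers_json"] = labels.centers.to_json()


def load_volume(path: str) -> tuple[Volume, ColumnLabelMap | None]:
    with h5py.File(path, "r") as h5:
        data = h5["/volume"][()]
        depth_axis = h5["/depth_axis_mm"][()]
        thickness = h5["/thickness_mm"][()]
        dx = float(h5.attrs["dx_mm"])
        labels = None
        if "/labels" in h5:
            centers = pd.read_json(
                h5["/labels"].attrs["centers_json"])
            labels = ColumnLabelMap(labels=h5["/labels"][()],
                                    centers=centers, dx=dx)
    ny, nx = thickness.shape
    sheet = LaminarSheet(nx=nx, ny=ny, dx=dx, thickness=thickness,
                         depth_axis=depth_axis)
    return Volume(sheet=sheet, data=data), labels


def save_run(path: str, run: BoldRun) -> None:
    """Write a simulated BOLD run to HDF5 (/series, /events, /motion)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("/series", data=run.series)
        h5.create_dataset("/motion", data=run.motion)
        h5.attrs["tr_s"] = run.tr
        h5.attrs["events_json"] = run.events.to_json()
        if run.seed is not None:
            h5.attrs["seed"] = run.seed


def load_run(path: str) -> BoldRun:
    with h5py.File(path, "r") as h5:
        events = pd.read_json(h5.attrs["events_json"])
        return BoldRun(
            tr=float(h5.attrs["tr_s"]),
            series=h5["/series"][()],
            events=events,
            motion=h5["/motion"][()],
            seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None,
        )


def save_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_config(path: str, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
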