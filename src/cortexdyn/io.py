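"""Plain-text tabular readers and writers for geometries, maps and tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ParcelGeometry

__all__ = [
    "write_geometry",
    "read_geometry",
    "write_map_table",
    "read_map_table",
    "write_timeseries",
    "read_timeseries",
]

_SEP = "\t"


def write_geometry(path, geometry: ParcelGeometry) -> None:
    df = pd.DataFrame({
        "parcel_id": geometry.parcel_id,
        "sphere_x": geometry.sphere_xyz[:, 0],
        "sphere_y": geometry.sphere_xyz[:, 1],
        "sphere_z": geometry.sphere_xyz[:, 2],
        "anat_x": geometry.anat_xyz[:, 0],
        "anat_y": geometry.anat_xyz[:, 1],
        "anat_z": geometry.anat_xyz[:, 2],
        "medial_wall": geometry.medial_wall.astype(int),
    })
    df.to_csv(path, sep=_SEP, index=False, float_format="%.12g")


def read_geometry(path) -> ParcelGeometry:
    df = pd.read_csv(path, sep=_SEP)
    return ParcelGeometry(
        df["parcel_id"].to_numpy(),
        df[["sphere_x", "sphere_y", "sphere_z"]].to_numpy(float),
        df[["anat_x", "anat_y", "anat_z"]].to_numpy(float),
        df["medial_wall"].to_numpy().astype(bool),
    )


def write_map_table(path, parcel_ids, columns: dict) -> None:
    """One row per parcel; one column per parameter (NaN for missing)."""
    df = pd.DataFrame({"parcel_id": np.asarray(parcel_ids)})
    for name, values in columns.items():
        df[name] = np.asarray(values, dtype=float)
    df.to_csv(path, sep=_SEP, index=False, float_format="%.12g", na_rep="NaN")


def read_map_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)


def write_timeseries(path, timeseries, fs: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        np.savetxt(fh, np.asarray(timeseries, dtype=float), fmt="%.8g")


def read_timeseries(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header")
        fs = float(header.split("=", 1)[1])
        data = np.loadtxt(fh)
    return data, fs


def subject_table(records, parameter_order) -> pd.DataFrame:
    """Long-format table: one row per (subject, parcel), map columns."""
    rows = []
    for rec in records:
        n = len(next(iter(rec.maps.values())))
        for j in range(n):
            row = {"subject_id": rec.subject_id, "group": rec.group_label,
                   "parcel_id": j}
            for p in parameter_order:
                row[p] = rec.maps[p][j] if p in rec.maps else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
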