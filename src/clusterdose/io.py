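"""CSV/JSON readers and writers for the pipeline's tabular interfaces.

All tables are plain CSV with a header row:

* fICSD:               particle, energy_mev_u, nu, f_per_um
* C_k:                 particle, energy_mev_u, k, ck_per_um
* voxel tracks:        voxel_id, particle, energy_mev_u, track_length_um, voxel_volume_um3
* voxel cluster dose:  voxel_id, k, ip_voxel_per_um, fluence_per_um2, g_per_pg
* survival:            dataset, particle, energy_mev_u, dose_gy, fluence_per_um2,
                       dose_per_fluence_gy_um2, survival
                       (dose_gy or fluence_per_um2 may be empty per row, not both)
* cluster-dose points: dataset, particle, energy_mev_u, k, g_per_pg, survival
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .icsd import FICSD, CkTable
from .survival import ClusterDosePoint, SurvivalPoint
from .voxel import VoxelClusterDose, VoxelTrackRecord

__all__ = [
    "read_ficsd_csv",
    "write_ficsd_csv",
    "read_ck_csv",
    "write_ck_csv",
    "read_voxel_tracks_csv",
    "write_voxel_cluster_dose_csv",
    "read_survival_csv",
    "write_survival_csv",
    "read_cluster_dose_points_csv",
    "write_cluster_dose_points_csv",
    "write_json",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_ficsd_csv(path: str | Path) -> list[FICSD]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["particle", "energy_mev_u", "nu", "f_per_um"], path)
    out = []
    for (particle, energy), grp in df.groupby(["particle", "energy_mev_u"], sort=True):
        freqs = {int(nu): float(f) for nu, f in zip(grp["nu"], grp["f_per_um"])}
        out.append(FICSD(str(particle), float(energy), freqs))
    return out


def write_ficsd_csv(ficsds: Iterable[FICSD], path: str | Path) -> None:
    rows = [
        {"particle": f.particle, "energy_mev_u": f.energy, "nu": nu, "f_per_um": freq}
        for f in ficsds
        for nu, freq in f.frequencies.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ck_csv(path: str | Path) -> list[CkTable]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["particle", "energy_mev_u", "k", "ck_per_um"], path)
    out = []
    for (particle, energy), grp in df.groupby(["particle", "energy_mev_u"], sort=True):
        values = {int(k): float(c) for k, c in zip(grp["k"], grp["ck_per_um"])}
        out.append(CkTable(str(particle), float(energy), values))
    return out


def write_ck_csv(tables: Iterable[CkTable], path: str | Path) -> None:
    rows = [
        {"particle": t.particle, "energy_mev_u": t.energy, "k": k, "ck_per_um": ck}
        for t in tables
        for k, ck in t.values.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_voxel_tracks_csv(path: str | Path) -> list[VoxelTrackRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["voxel_id", "particle", "energy_mev_u", "track_length_um", "voxel_volume_um3"],
        path,
    )
    return [
        VoxelTrackRecord(
            voxel_id=str(r.voxel_id),
            particle=str(r.particle),
            energy=float(r.energy_mev_u),
            track_length=float(r.track_length_um),
            voxel_volume=float(r.voxel_volume_um3),
        )
        for r in df.itertuples()
    ]


def write_voxel_cluster_dose_csv(
    results: Iterable[VoxelClusterDose], path: str | Path
) -> None:
    rows = [
        {
            "voxel_id": r.voxel_id,
            "k": r.k,
            "ip_voxel_per_um": r.ip_voxel,
            "fluence_per_um2": r.fluence,
            "g_per_pg": r.g,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> list[SurvivalPoint]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["dataset", "particle", "energy_mev_u", "survival"], path)
    points = []
    for i, r in enumerate(df.to_dict("records")):
        def _opt(key: str) -> float | None:
            v = r.get(key)
            return None if v is None or pd.isna(v) else float(v)

        try:
            points.append(
                SurvivalPoint(
                    dataset=str(r["dataset"]),
                    particle=str(r["particle"]),
                    energy=float(r["energy_mev_u"]),
                    survival=float(r["survival"]),
                    dose=_opt("dose_gy"),
                    fluence=_opt("fluence_per_um2"),
                    dose_per_fluence=_opt("dose_per_fluence_gy_um2"),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}, row {i + 2}: {err}") from err
    return points


def write_survival_csv(points: Iterable[SurvivalPoint], path: str | Path) -> None:
    rows = [
        {
            "dataset": p.dataset,
            "particle": p.particle,
            "energy_mev_u": p.energy,
            "dose_gy": p.dose,
            "fluence_per_um2": p.fluence,
            "dose_per_fluence_gy_um2": p.dose_per_fluence,
            "survival": p.survival,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cluster_dose_points_csv(path: str | Path) -> list[ClusterDosePoint]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ["dataset", "particle", "energy_mev_u", "k", "g_per_pg", "survival"], path
    )
    return [
        ClusterDosePoint(
            dataset=str(r.dataset),
            particle=str(r.particle),
            energy=float(r.energy_mev_u),
            k=int(r.k),
            g=float(r.g_per_pg),
            survival=float(r.survival),
        )
        for r in df.itertuples()
    ]


def write_cluster_dose_points_csv(
    points: Iterable[ClusterDosePoint], path: str | Path
) -> None:
    rows = [
        {
            "dataset": p.dataset,
            "particle": p.particle,
            "energy_mev_u": p.energy,
            "k": p.k,
            "g_per_pg": p.g,
            "survival": p.survival,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: object, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
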