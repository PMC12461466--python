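"""Voxel-level dosimetry: fluence, voxel-averaged I_p, and cluster dose.

In a macroscopic (mm-sized) voxel j traversed by a mix of particle classes c
(type + energy), the voxel-averaged ionization parameter is the
track-length-weighted mean of the per-class values,

    I_p^{φ_j} = Σ_c t_j^c I_p^c / Σ_c t_j^c ,

fluence is total charged-particle track length per voxel volume,
φ_j = Σ_c t_j^c / V_j, and the cluster dose is

    g_j = φ_j · I_p^{φ_j} / ρ0   [pg⁻¹],

with ρ0 the density of the reference medium (liquid water,
1 pg/μm³) in which the nanoscopic f(ν) were scored.  With those units g is
the number of qualifying clusters per picogram.

Per-class I_p here is C_k at a configurable k, resolved through a
:class:`CkLibrary` that clamps out-of-range energies to the nearest
tabulated boundary and maps in-range energies to the nearest grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .icsd import DEFAULT_K_MAX, FICSD, CkTable, compute_ck_table

__all__ = [
    "VoxelTrackRecord",
    "VoxelClusterDose",
    "CkLibrary",
    "voxel_average_ip",
    "fluence",
    "cluster_dose",
    "voxel_cluster_dose",
]

#: density of liquid water in pg/μm³
RHO_WATER = 1.0


@dataclass(frozen=True)
class VoxelTrackRecord:
    """Summed track length of one particle class inside one voxel."""

    voxel_id: str
    particle: str
    energy: float  # MeV/u
    track_length: float  # μm, summed over all particles of the class
    voxel_volume: float  # μm³

    def __post_init__(self) -> None:
        if self.track_length < 0:
            raise ValueError(f"track_length must be >= 0, got {self.track_length}")
        if self.voxel_volume <= 0:
            raise ValueError(f"voxel_volume must be > 0, got {self.voxel_volume}")


@dataclass(frozen=True)
class VoxelClusterDose:
    """Cluster dose and its factors for one voxel at one k."""

    voxel_id: str
    k: int
    ip_voxel: float  # clusters/μm
    fluence: float  # particles/μm²
    g: float  # pg⁻¹
    rho0: float  # pg/μm³


class CkLibrary:
    """Lookup of C_k tables by particle class with boundary clamping.

    Energies below (above) the tabulated range for a particle map to the
    lowest (highest) tabulated energy; in-range energies map to the nearest
    grid point.  ``energy_metric`` selects the distance used for
    nearest-neighbour matching: ``"log"`` (default; particle data tables are
    typically log-spaced) or ``"linear"``.  Ties resolve to the lower energy.
    """

    def __init__(
        self,
        tables: Iterable[CkTable],
        energy_metric: Literal["log", "linear"] = "log",
    ) -> None:
        if energy_metric not in ("log", "linear"):
            raise ValueError(f"unknown energy metric {energy_metric!r}")
        self.energy_metric = energy_metric
        self._tables: dict[str, dict[float, CkTable]] = {}
        for t in tables:
            by_e = self._tables.setdefault(t.particle, {})
            if t.energy in by_e:
                raise ValueError(
                    f"duplicate C_k table for {t.particle} at {t.energy} MeV/u"
                )
            if energy_metric == "log" and t.energy <= 0:
                raise ValueError("log energy metric requires positive energies")
            by_e[t.energy] = t
        if not self._tables:
            raise ValueError("CkLibrary requires at least one table")

    @classmethod
    def from_ficsds(
        cls,
        ficsds: Iterable[FICSD],
        k_max: int = DEFAULT_K_MAX,
        energy_metric: Literal["log", "linear"] = "log",
    ) -> "CkLibrary":
        return cls(
            (compute_ck_table(f, k_max) for f in ficsds), energy_metric=energy_metric
        )

    @property
    def particles(self) -> list[str]:
        return sorted(self._tables)

    def energies(self, particle: str) -> list[float]:
        return sorted(self._energies_of(particle))

    def _energies_of(self, particle: str) -> dict[float, CkTable]:
        try:
            return self._tables[particle]
        except KeyError:
            raise KeyError(
                f"particle {particle!r} not in C_k library "
                f"(available: {', '.join(self.particles)})"
            ) from None

    def clamp_energy(self, particle: str, energy: float) -> float:
        """Resolve a query energy to the tabulated grid for ``particle``.

        Below-range and above-range energies clamp to the grid boundaries;
        in-range energies snap to the nearest grid point under the
        configured metric.
        """
        grid = sorted(self._energies_of(particle))
        if energy <= grid[0]:
            return grid[0]
        if energy >= grid[-1]:
            return grid[-1]
        if self.energy_metric == "log":
            dist = lambda e: abs(math.log(energy) - math.log(e))  # noqa: E731
        else:
            dist = lambda e: abs(energy - e)  # noqa: E731
        return min(grid, key=lambda e: (dist(e), e))

    def table(self, particle: str, energy: float) -> CkTable:
        by_e = self._energies_of(particle)
        return by_e[self.clamp_energy(particle, energy)]

    def ck(self, particle: str, energy: float, k: int) -> float:
        """C_k (clusters/μm) for the class nearest to (particle, energy)."""
        return self.table(particle, energy)[k]


def fluence(records: Sequence[VoxelTrackRecord]) -> float:
    """Fluence of one voxel: total track length / voxel volume (/μm²)."""
    if not records:
        return 0.0
    volumes = {r.voxel_volume for r in records}
    if len(volumes) > 1:
        raise ValueError(
            f"inconsistent voxel_volume values within one voxel: {sorted(volumes)}"
        )
    voxels = {r.voxel_id for r in records}
    if len(voxels) > 1:
        raise ValueError(f"records span multiple voxels: {sorted(voxels)}")
    total = math.fsum(r.track_length for r in records)
    return total / records[0].voxel_volume


def voxel_average_ip(
    records: Sequence[VoxelTrackRecord], library: CkLibrary, k: int
) -> float:
    """Track-length-weighted mean of per-class C_k over one voxel."""
    if not records:
        raise ValueError("no track records supplied for voxel average")
    total_t = math.fsum(r.track_length for r in records)
    if total_t <= 0:
        raise ValueError("all track lengths are zero; voxel average undefined")
    weighted = math.fsum(
        r.track_length * library.ck(r.particle, r.energy, k) for r in records
    )
    return weighted / total_t


def cluster_dose(fluence_value: float, ip: float, rho0: float = RHO_WATER) -> float:
    """Cluster dose g = φ · I_p / ρ0 in pg⁻¹.

    With ρ0 = 1 pg/μm³ (water), g numerically equals clusters per μm³,
    i.e. the number of qualifying clusters in a water cube of 1 μm width.
    """
    if rho0 <= 0:
        raise ValueError(f"rho0 must be positive, got {rho0}")
    return fluence_value * ip / rho0


def voxel_cluster_dose(
    records: Sequence[VoxelTrackRecord],
    library: CkLibrary,
    k: int,
    rho0: float = RHO_WATER,
) -> VoxelClusterDose:
    """Full per-voxel result: I_p^{φ_j}, φ_j, and g_j at one k."""
    phi = fluence(records)
    ip = voxel_average_ip(records, library, k)
    return VoxelClusterDose(
        voxel_id=records[0].voxel_id,
        k=int(k),
        ip_voxel=ip,
        fluence=phi,
        g=cluster_dose(phi, ip, rho0),
        rho0=rho0,
    )
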