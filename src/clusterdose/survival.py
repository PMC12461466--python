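"""Survival measurements and their mapping to cluster-dose survival points.

A survival measurement records the surviving fraction S of a cell
population after irradiation with a known particle class at a known absorbed
dose or fluence.  When only absorbed dose D (Gy) is reported, fluence is
recovered through the simulated dose-per-fluence factor for that beam and
depth: φ = D / (dose per fluence).  Each point is then mapped to a cluster
dose g = φ · C_k(class) / ρ0 for the k under study, giving the
cluster-dose survival curve on which all dispersion statistics operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .voxel import RHO_WATER, CkLibrary

__all__ = ["SurvivalPoint", "ClusterDosePoint", "to_cluster_dose_points", "sort_by_cluster_dose"]


@dataclass(frozen=True)
class SurvivalPoint:
    """One measured survival fraction with its beam-quality annotation.

    At least one of ``dose`` (Gy) and ``fluence`` (/μm²) must be present;
    ``dose_per_fluence`` (Gy·μm²) is required when only dose is given and is
    carried per point because it varies with beam, particle, and depth.
    """

    dataset: str
    particle: str
    energy: float  # MeV/u
    survival: float  # surviving fraction, must be > 0
    dose: Optional[float] = None  # Gy
    fluence: Optional[float] = None  # /μm²
    dose_per_fluence: Optional[float] = None  # Gy·μm²

    def __post_init__(self) -> None:
        if not (self.survival > 0):
            raise ValueError(
                f"survival must be > 0 for a defined ln S "
                f"({self.dataset}/{self.particle}@{self.energy}: S={self.survival})"
            )
        if self.fluence is None:
            if self.dose is None:
                raise ValueError(
                    f"point {self.dataset}/{self.particle}@{self.energy} has "
                    "neither dose nor fluence"
                )
            if self.dose_per_fluence is None or self.dose_per_fluence <= 0:
                raise ValueError(
                    "dose_per_fluence (Gy·μm², positive) is required to convert "
                    f"dose to fluence for {self.dataset}/{self.particle}@{self.energy}"
                )
            if self.dose < 0:
                raise ValueError(f"dose must be >= 0, got {self.dose}")
            object.__setattr__(self, "fluence", self.dose / self.dose_per_fluence)
        elif self.fluence < 0:
            raise ValueError(f"fluence must be >= 0, got {self.fluence}")


@dataclass(frozen=True)
class ClusterDosePoint:
    """One survival measurement on the cluster-dose axis for a given k."""

    dataset: str
    particle: str
    energy: float
    k: int
    g: float  # pg⁻¹
    survival: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"cluster dose must be >= 0, got {self.g}")
        if not (self.survival > 0):
            raise ValueError(f"survival must be > 0, got {self.survival}")

    @property
    def log_survival(self) -> float:
        return math.log(self.survival)


def to_cluster_dose_points(
    points: Sequence[SurvivalPoint],
    library: CkLibrary,
    k: int,
    rho0: float = RHO_WATER,
) -> list[ClusterDosePoint]:
    """Map survival points to cluster-dose points at one k.

    g_i = φ_i · C_k(class_i) / ρ0, with the particle class resolved through
    the library's energy clamping.  Input order is preserved.
    """
    if rho0 <= 0:
        raise ValueError(f"rho0 must be positive, got {rho0}")
    out = []
    for p in points:
        ck = library.ck(p.particle, p.energy, k)
        out.append(
            ClusterDosePoint(
                dataset=p.dataset,
                particle=p.particle,
                energy=p.energy,
                k=int(k),
                g=p.fluence * ck / rho0,
                survival=p.survival,
            )
        )
    return out


def sort_by_cluster_dose(points: Sequence[ClusterDosePoint]) -> list[ClusterDosePoint]:
    """Stable ascending sort in g, deterministic lexicographic tie-break.

    Ties in g (possible when different particles produce identical cluster
    doses) break by (dataset, particle, energy, survival) so that
    window-based statistics are reproducible.
    """
    return sorted(
        points, key=lambda p: (p.g, p.dataset, p.particle, p.energy, p.survival)
    )
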