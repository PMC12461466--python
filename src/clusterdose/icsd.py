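"""Ionization cluster-size distributions and C_k ionization parameters.

The frequency ionization cluster-size distribution (fICSD) records, for one
particle class (type + specific energy), the frequency f(ν) of nanoscopic
ionization clusters of size ν per micrometre of track and per source
particle.  Collapsing an fICSD with the tail-sum operator yields the C_k
family of ionization parameters: C_k is the number of clusters of k or more
ionizations per unit track length,

    C_k = Σ_{ν=k}^{ν_max} f(ν)   [clusters/μm].

Both f(ν) and C_k are fluence-independent, per-particle, per-track-length
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FICSD",
    "CkTable",
    "compute_ck",
    "compute_ck_table",
    "mean_chord_length",
]

DEFAULT_K_MAX = 10


def mean_chord_length(radius_nm: float, length_nm: float) -> float:
    """Mean chord length of a cylinder (Cauchy 4V/S), in micrometres.

    Used to normalize raw cluster counts to a per-track-length frequency
    when the sensitive volume is a cylinder of the given radius and length
    (both in nanometres).

    For a cylinder, 4V/S = 4(πr²L) / (2πr² + 2πrL) = 2rL / (r + L).
    """
    if radius_nm <= 0 or length_nm <= 0:
        raise ValueError(
            f"cylinder dimensions must be positive, got radius={radius_nm} nm, "
            f"length={length_nm} nm"
        )
    chord_nm = 2.0 * radius_nm * length_nm / (radius_nm + length_nm)
    return chord_nm * 1e-3  # nm -> μm


@dataclass(frozen=True)
class FICSD:
    """Frequency ionization cluster-size distribution for one particle class.

    Parameters
    ----------
    particle:
        Particle label, e.g. ``"p"``, ``"He"``, ``"C"``, ``"Ne"``, ``"Ar"``.
    energy:
        Specific energy in MeV/u.
    frequencies:
        Map from cluster size ν (integer ≥ 1) to f(ν) in clusters per μm of
        track per source particle.  Entries at ν = 0 (no ionization) are
        dropped silently; they carry no cluster information.
    """

    particle: str
    energy: float
    frequencies: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for nu, f in self.frequencies.items():
            if not isinstance(nu, (int,)) or isinstance(nu, bool):
                if isinstance(nu, float) and nu.is_integer():
                    nu = int(nu)
                else:
                    raise ValueError(f"cluster size must be an integer, got {nu!r}")
            if nu == 0:
                continue  # 'no ionization' entries are ignored by convention
            if nu < 0:
                raise ValueError(f"cluster size must be >= 1, got {nu}")
            if f < 0:
                raise ValueError(f"frequency f({nu}) must be >= 0, got {f}")
            clean[int(nu)] = float(f)
        object.__setattr__(self, "frequencies", dict(sorted(clean.items())))

    @property
    def nu_max(self) -> int:
        """Largest cluster size with nonzero frequency (0 if empty)."""
        support = [nu for nu, f in self.frequencies.items() if f > 0]
        return max(support) if support else 0

    @classmethod
    def from_raw_counts(
        cls,
        particle: str,
        energy: float,
        counts: Mapping[int, float],
        n_particles: int,
        *,
        radius_nm: float = 30.4,
        length_nm: float = 161.0,
    ) -> "FICSD":
        """Build an fICSD from raw cluster counts.

        Counts are divided by (number of source particles × mean chord length
        of the sensitive cylinder) to obtain per-particle, per-μm frequencies.
        The default cylinder emulates a chromatin-fibre-sized sensitive
        volume (radius 30.4 nm, length 161 nm).
        """
        if n_particles <= 0:
            raise ValueError(f"n_particles must be positive, got {n_particles}")
        norm = n_particles * mean_chord_length(radius_nm, length_nm)
        return cls(particle, energy, {nu: c / norm for nu, c in counts.items()})


@dataclass(frozen=True)
class CkTable:
    """C_k values for one particle class, k = 1..k_max.

    ``values`` maps k to C_k in clusters/μm.  C_k is non-increasing in k
    because the C_k are nested tail sums of the same fICSD.
    """

    particle: str
    energy: float
    values: Mapping[int, float]

    def __post_init__(self) -> None:
        vals = dict(sorted((int(k), float(v)) for k, v in self.values.items()))
        ks = list(vals)
        if not ks:
            raise ValueError("CkTable requires at least one k")
        if ks != list(range(1, ks[-1] + 1)):
            raise ValueError("CkTable must cover k = 1..k_max contiguously")
        for k in ks[:-1]:
            if vals[k] + 1e-12 * max(1.0, abs(vals[k])) < vals[k + 1]:
                raise ValueError(f"C_k must be non-increasing: C_{k} < C_{k + 1}")
        if vals[ks[-1]] < 0:
            raise ValueError("C_k values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def k_max(self) -> int:
        return max(self.values)

    def __getitem__(self, k: int) -> float:
        return self.values[k]


def _validate_k(k: int) -> int:
    if isinstance(k, bool) or (isinstance(k, float) and not k.is_integer()):
        raise ValueError(f"k must be an integer, got {k!r}")
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return k


def compute_ck(ficsd: FICSD, k: int) -> float:
    """Number of clusters of ``k`` or more ionizations per μm of track.

    Tail sum of the fICSD from ν = k to ν_max; zero above the support.
    """
    k = _validate_k(k)
    # plain left-to-right accumulation over the ν-sorted support: summation
    # order is part of the contract so independent implementations agree
    # bit-for-bit
    total = 0.0
    for nu, f in ficsd.frequencies.items():
        if nu >= k:
            total += f
    return total


def compute_ck_table(ficsd: FICSD, k_max: int = DEFAULT_K_MAX) -> CkTable:
    """Tabulate C_k for k = 1..k_max from one fICSD."""
    k_max = _validate_k(k_max)
    if not ficsd.frequencies:
        raise ValueError(
            f"fICSD for {ficsd.particle} at {ficsd.energy} MeV/u records no clusters"
        )
    values = {k: compute_ck(ficsd, k) for k in range(1, k_max + 1)}
    return CkTable(ficsd.particle, ficsd.energy, values)
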