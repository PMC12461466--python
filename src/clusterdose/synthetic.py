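"""Synthetic fICSDs and cluster-dose survival data with known ground truth.

The generator emulates the two ingredients the analysis pipeline consumes —
a per-class C_k library and a multi-particle survival dataset — with a
designated "true" cluster-size threshold k* built in, so that the whole
preferred-I_p selection machinery can be validated by parameter recovery.

Each particle class q gets a geometric fICSD,

    f_q(ν) = A_q (1 − p_q) p_q^{ν−1},   ν = 1..ν_max,

whose tail sums have the closed form C_k = A_q p_q^{k−1} (up to a known
truncation term), giving a testable generator with a single shape knob p_q
playing the role of radiation quality.  Survival is an exact
linear-quadratic function of the cluster dose computed at k*,

    ln S = −α g* − β (g*)² + ε,    ε ~ N(0, noise_sd²),

i.e. multiplicative lognormal noise on S.  Because the classes have
distinct p_q, the ratio C_k/C_{k*} = p_q^{k−k*} varies across classes for
any k ≠ k*, so survival plotted against the "wrong" cluster dose cannot
collapse onto one curve: dispersion at k ≠ k* strictly exceeds dispersion
at k* in the noiseless limit.  Survival may slightly exceed 1 at low g and
is intentionally not clamped, preserving the assumed error structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .icsd import FICSD, compute_ck
from .survival import SurvivalPoint
from .voxel import CkLibrary

__all__ = [
    "ClassSpec",
    "SyntheticScenario",
    "GroundTruth",
    "generate_ficsd",
    "make_library",
    "generate_survival",
    "scenario_presets",
    "scenario_from_yaml",
    "scenario_to_yaml",
    "PRESET_NAMES",
]

DEFAULT_NU_MAX = 30


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic particle class: geometric fICSD shape parameters."""

    label: str
    energy: float  # MeV/u
    amplitude: float  # A_q, clusters/μm (equals C_1 up to truncation)
    p: float  # geometric decay, in (0, 1)

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError(f"geometric parameter p must be in (0, 1), got {self.p}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")

    def ck_closed_form(self, k: int, nu_max: int = DEFAULT_NU_MAX) -> float:
        """Exact C_k of the truncated geometric fICSD."""
        if k > nu_max:
            return 0.0
        return self.amplitude * self.p ** (k - 1) * (1 - self.p ** (nu_max - k + 1))


@dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of one synthetic study condition."""

    name: str
    oxygen_label: str  # aerobic | hypoxic
    true_k: int  # designated k*
    alpha: float  # pg
    beta: float  # pg²
    noise_sd: float  # SD of additive noise on ln S
    classes: tuple[ClassSpec, ...]
    fluence_grids: Mapping[str, tuple[float, ...]]  # label -> /μm² values
    rho0: float = 1.0  # pg/μm³
    seed: int = 0
    nu_max: int = DEFAULT_NU_MAX

    def __post_init__(self) -> None:
        if self.oxygen_label not in ("aerobic", "hypoxic"):
            raise ValueError(f"unknown oxygen label {self.oxygen_label!r}")
        if self.true_k < 1:
            raise ValueError(f"true_k must be >= 1, got {self.true_k}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.rho0 <= 0:
            raise ValueError(f"rho0 must be > 0, got {self.rho0}")
        distinct_p = {c.p for c in self.classes}
        if len(distinct_p) < 3:
            raise ValueError(
                "need at least 3 classes with distinct p so that wrong-k cluster "
                f"doses misalign across classes, got {sorted(distinct_p)}"
            )
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate class labels: {labels}")
        grids = {}
        for c in self.classes:
            if c.label not in self.fluence_grids:
                raise ValueError(f"no fluence grid for class {c.label!r}")
            grid = tuple(float(x) for x in self.fluence_grids[c.label])
            if len(grid) < 3:
                raise ValueError(f"fluence grid for {c.label!r} needs >= 3 points")
            if any(x <= 0 for x in grid):
                raise ValueError(f"fluences must be positive for {c.label!r}")
            grids[c.label] = grid
        object.__setattr__(self, "fluence_grids", grids)
        object.__setattr__(self, "classes", tuple(self.classes))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters emitted alongside a synthetic dataset."""

    true_k: int
    alpha: float
    beta: float
    noise_sd: float
    seed: int
    g_true: tuple[float, ...]  # per-point cluster dose at k*, input order
    log_survival_clean: tuple[float, ...]  # noise-free ln S, input order


def generate_ficsd(spec: ClassSpec, nu_max: int = DEFAULT_NU_MAX) -> FICSD:
    """Truncated geometric fICSD for one synthetic class."""
    if nu_max < 1:
        raise ValueError(f"nu_max must be >= 1, got {nu_max}")
    freqs = {
        nu: spec.amplitude * (1 - spec.p) * spec.p ** (nu - 1)
        for nu in range(1, nu_max + 1)
    }
    return FICSD(spec.label, spec.energy, freqs)


def make_library(
    scenario: SyntheticScenario, k_max: int = 10
) -> CkLibrary:
    """C_k library over the scenario's classes (k = 1..k_max)."""
    return CkLibrary.from_ficsds(
        (generate_ficsd(c, scenario.nu_max) for c in scenario.classes), k_max=k_max
    )


def generate_survival(
    scenario: SyntheticScenario,
) -> tuple[list[SurvivalPoint], GroundTruth]:
    """Survival points that are exactly LQ in the k* cluster dose plus noise.

    For each class q and fluence φ on its grid, the true cluster dose is
    g* = φ·C_{k*}(q)/ρ0 (C from the generated fICSD, so generator and
    pipeline agree exactly), and ln S = −α g* − β g*² + ε with seeded
    Gaussian ε.  Points are emitted class by class, in grid order.
    """
    rng = np.random.default_rng(scenario.seed)
    points: list[SurvivalPoint] = []
    g_true: list[float] = []
    lns_clean: list[float] = []
    for spec in scenario.classes:
        ficsd = generate_ficsd(spec, scenario.nu_max)
        ck_star = compute_ck(ficsd, scenario.true_k)
        for phi in scenario.fluence_grids[spec.label]:
            g = phi * ck_star / scenario.rho0
            lns = -scenario.alpha * g - scenario.beta * g**2
            eps = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
            points.append(
                SurvivalPoint(
                    dataset=scenario.name,
                    particle=spec.label,
                    energy=spec.energy,
                    fluence=phi,
                    survival=math.exp(lns + eps),
                )
            )
            g_true.append(g)
            lns_clean.append(lns)
    truth = GroundTruth(
        true_k=scenario.true_k,
        alpha=scenario.alpha,
        beta=scenario.beta,
        noise_sd=scenario.noise_sd,
        seed=scenario.seed,
        g_true=tuple(g_true),
        log_survival_clean=tuple(lns_clean),
    )
    return points, truth


def _g_grid(alpha: float, beta: float, n: int = 8) -> np.ndarray:
    """Log-spaced cluster-dose grid spanning survival ≈ 0.9 down to 1e-3.

    Endpoints solve α g + β g² = −ln S for S = 0.9 and S = 1e-3, so both the
    α-dominated shoulder and the β-dominated tail are sampled.
    """

    def g_at(target_lns: float) -> float:
        if beta == 0:
            return -target_lns / alpha
        return (-alpha + math.sqrt(alpha**2 - 4 * beta * target_lns)) / (2 * beta)

    g_lo = g_at(math.log(0.9))
    g_hi = g_at(math.log(1e-3))
    return np.geomspace(g_lo, g_hi, n)


#: default radiation-quality ladder: five classes whose geometric decay
#: parameter spans the clinically relevant spread from sparse to dense
#: ionization (proton-like to argon-like)
_DEFAULT_CLASSES = (
    ClassSpec("p", 150.0, amplitude=20.0, p=0.35),
    ClassSpec("He", 150.0, amplitude=20.0, p=0.45),
    ClassSpec("C", 290.0, amplitude=20.0, p=0.55),
    ClassSpec("Ne", 425.0, amplitude=20.0, p=0.65),
    ClassSpec("Ar", 570.0, amplitude=20.0, p=0.75),
)

PRESET_NAMES = ("aerobic_like", "hypoxic_like")


def scenario_presets(name: str, seed: int = 0) -> SyntheticScenario:
    """Named study conditions with documented ground truth.

    ``aerobic_like``: k* = 5, α = 0.3 pg, β = 0.02 pg², noise_sd = 0.08 —
    oxygenated cells, radiosensitive.  ``hypoxic_like``: k* = 7,
    α = 0.12 pg, β = 0.01 pg², noise_sd = 0.08 — radioresistant cells
    requiring larger ionization clusters per lethal event.  Both use five
    classes with p ∈ {0.35, 0.45, 0.55, 0.65, 0.75} and 8 fluences per
    class, chosen so every class shares the same 8-point cluster-dose grid
    at k* (same cluster dose, different particle — the comparison the
    dispersion statistics are built for).
    """
    if name == "aerobic_like":
        true_k, alpha, beta, oxygen = 5, 0.3, 0.02, "aerobic"
    elif name == "hypoxic_like":
        true_k, alpha, beta, oxygen = 7, 0.12, 0.01, "hypoxic"
    else:
        raise KeyError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    noise_sd = 0.08
    g_grid = _g_grid(alpha, beta, n=8)
    grids = {}
    for spec in _DEFAULT_CLASSES:
        ck_star = compute_ck(generate_ficsd(spec, DEFAULT_NU_MAX), true_k)
        grids[spec.label] = tuple(float(g) / ck_star for g in g_grid)  # rho0 = 1
    return SyntheticScenario(
        name=name,
        oxygen_label=oxygen,
        true_k=true_k,
        alpha=alpha,
        beta=beta,
        noise_sd=noise_sd,
        classes=_DEFAULT_CLASSES,
        fluence_grids=grids,
        rho0=1.0,
        seed=seed,
    )


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    """Write a scenario to a YAML file mirroring its fields."""
    import yaml

    doc = {
        "name": scenario.name,
        "oxygen_label": scenario.oxygen_label,
        "true_k": scenario.true_k,
        "alpha": scenario.alpha,
        "beta": scenario.beta,
        "noise_sd": scenario.noise_sd,
        "rho0": scenario.rho0,
        "seed": scenario.seed,
        "nu_max": scenario.nu_max,
        "classes": [
            {"label": c.label, "energy": c.energy, "amplitude": c.amplitude, "p": c.p}
            for c in scenario.classes
        ],
        "fluence_grids": {
            label: list(grid) for label, grid in scenario.fluence_grids.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def scenario_from_yaml(path) -> SyntheticScenario:
    """Load a scenario from the YAML schema written by ``scenario_to_yaml``."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    classes = tuple(
        ClassSpec(c["label"], float(c["energy"]), float(c["amplitude"]), float(c["p"]))
        for c in doc["classes"]
    )
    return SyntheticScenario(
        name=doc["name"],
        oxygen_label=doc["oxygen_label"],
        true_k=int(doc["true_k"]),
        alpha=float(doc["alpha"]),
        beta=float(doc["beta"]),
        noise_sd=float(doc["noise_sd"]),
        classes=classes,
        fluence_grids={k: tuple(v) for k, v in doc["fluence_grids"].items()},
        rho0=float(doc.get("rho0", 1.0)),
        seed=int(doc.get("seed", 0)),
        nu_max=int(doc.get("nu_max", DEFAULT_NU_MAX)),
    )
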