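"""Vesicle biophysics and synthetic population generation.

A particle moving electrokinetically (electrophoresis + electroosmosis,
mobility ``μEK = μEP + μEOF``) through a constricted channel experiences a
dielectrophoretic mobility

    μDEP = εm r² fCM / (3 η)

with ``r`` the particle radius, ``fCM`` the Clausius–Mossotti factor and
``εm, η`` the medium permittivity and viscosity.  The ratio

    EKMr = μEK / μDEP      [V/m²]

is the particle-intrinsic quantity the separation indexes on: a particle is
trapped at the first gate whose capture-parameter threshold meets or exceeds
its EKMr.

Synthetic populations are specified *EKMr-first*: subpopulations are mixture
components over EKMr (log-normal by default, matching the positive support
and right skew of mobility ratios), and the physical parameters
``(r, μEK, fCM)`` are back-filled consistently.  This mirrors how the
experiment characterizes subpopulations — solely by where they are trapped
on the EKMr axis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MediumProperties",
    "Vesicle",
    "VesiclePopulation",
    "MixtureComponent",
    "MixtureConfig",
    "dep_mobility",
    "ekmr",
    "sample_population",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Default back-fill radius: mid-range of the 150–200 nm vesicle radii the
#: enriched fractions contain.
DEFAULT_RADIUS_M = 1.75e-7
#: Default back-fill Clausius–Mossotti magnitude (dimensionless, |fCM| < 1).
DEFAULT_FCM = 0.5


@dataclass(frozen=True)
class MediumProperties:
    """Suspension-medium permittivity (F/m) and viscosity (Pa·s).

    Defaults describe the sucrose-containing low-conductivity separation
    buffer: relative permittivity ≈ 78 and viscosity slightly above water.
    """

    dielectric_constant: float = 78.0 * VACUUM_PERMITTIVITY
    viscosity: float = 1.2e-3

    def __post_init__(self) -> None:
        if self.dielectric_constant <= 0 or self.viscosity <= 0:
            raise ValueError("medium properties must be positive")


def dep_mobility(r: float, fcm: float, medium: MediumProperties) -> float:
    """Dielectrophoretic mobility ``εm r² fCM / (3η)`` in m⁴/(V²·s).

    Sign follows ``fcm``; ``r`` must be positive.
    """
    if r <= 0:
        raise ValueError("particle radius must be positive")
    return medium.dielectric_constant * r * r * fcm / (3.0 * medium.viscosity)


def ekmr(mu_ek: float, mu_dep: float) -> float:
    """Electrokinetic-to-dielectrophoretic mobility ratio ``μEK/μDEP``, V/m²."""
    if mu_dep == 0:
        raise ZeroDivisionError("dielectrophoretic mobility must be nonzero")
    return mu_ek / mu_dep


@dataclass(frozen=True)
class Vesicle:
    """One particle: radius (m), EK mobility components (m²/V·s), fCM, weight.

    ``mu_ek`` is stored through its electrophoretic and electroosmotic
    parts; the combined mobility is their sum.
    """

    radius: float
    mu_ep: float
    mu_eof: float
    fcm: float
    fluorescence_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.fluorescence_weight < 0:
            raise ValueError("fluorescence weight must be non-negative")

    @property
    def mu_ek(self) -> float:
        return self.mu_ep + self.mu_eof

    def ekmr(self, medium: MediumProperties) -> float:
        return ekmr(self.mu_ek, dep_mobility(self.radius, self.fcm, medium))


@dataclass(frozen=True)
class MixtureComponent:
    """One subpopulation: mixture weight, EKMr location/dispersion, brightness.

    ``location`` is the component median EKMr (V/m²); ``dispersion`` is the
    log-space standard deviation of the log-normal (0 ⇒ a point mass).
    """

    weight: float
    location: float
    dispersion: float = 0.0
    fluorescence_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("component weight must be positive")
        if self.location <= 0:
            raise ValueError("EKMr location must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass(frozen=True)
class MixtureConfig:
    """Mixture of EKMr subpopulations plus sampling bookkeeping."""

    components: tuple[MixtureComponent, ...]
    particle_count: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        if self.particle_count < 1:
            raise ValueError("particle_count must be >= 1")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component weights must sum to 1, got {total}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


@dataclass
class VesiclePopulation:
    """A labelled, reproducible collection of particles."""

    particles: list[Vesicle]
    condition_label: str
    replicate_id: str
    rng_seed: int
    medium: MediumProperties = field(default_factory=MediumProperties)
    component_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.particles:
            raise ValueError("population must be non-empty")

    def __len__(self) -> int:
        return len(self.particles)

    def ekmr_values(self) -> np.ndarray:
        """EKMr per particle, V/m² (vectorized)."""
        r = np.array([p.radius for p in self.particles])
        fcm = np.array([p.fcm for p in self.particles])
        mu_ek = np.array([p.mu_ek for p in self.particles])
        mu_dep = self.medium.dielectric_constant * r * r * fcm / (
            3.0 * self.medium.viscosity
        )
        return mu_ek / mu_dep

    def weights(self) -> np.ndarray:
        return np.array([p.fluorescence_weight for p in self.particles])


def sample_population(
    config: MixtureConfig,
    condition_label: str,
    replicate_id: str = "r1",
    *,
    medium: MediumProperties | None = None,
    radius: float = DEFAULT_RADIUS_M,
    fcm: float = DEFAULT_FCM,
    mu_eof: float = 0.0,
) -> VesiclePopulation:
    """Draw a synthetic vesicle population from an EKMr mixture.

    Each particle's EKMr is drawn from its component's log-normal and
    back-filled into physical parameters: the radius and Clausius–Mossotti
    factor take the supplied defaults (a mid-range vesicle radius and a
    positive fCM), the dielectrophoretic mobility follows from them, and the
    EK mobility is set to ``EKMr × μDEP``.  The electroosmotic part defaults
    to zero — the channel is BSA-passivated, suppressing electroosmosis —
    so ``μEP = μEK − μEOF`` carries the particle-to-particle variation.

    Identical ``(config, label, replicate_id)`` always produce identical
    populations.
    """
    medium = medium or MediumProperties()
    # mix the labels into the stream so replicates differ but are individually
    # reproducible; crc32 is stable across processes (str hash is salted)
    rng = np.random.default_rng(
        [
            config.seed,
            zlib.crc32(condition_label.encode()),
            zlib.crc32(str(replicate_id).encode()),
        ]
    )
    n = config.particle_count
    comp_ids = rng.choice(len(config.components), size=n, p=config.weights)
    mu_dep0 = dep_mobility(radius, fcm, medium)

    particles: list[Vesicle] = []
    z = rng.standard_normal(n)
    for k in range(n):
        comp = config.components[comp_ids[k]]
        value = comp.location * np.exp(comp.dispersion * z[k])
        mu_ek = value * mu_dep0
        particles.append(
            Vesicle(
                radius=radius,
                mu_ep=mu_ek - mu_eof,
                mu_eof=mu_eof,
                fcm=fcm,
                fluorescence_weight=comp.fluorescence_scale,
            )
        )
    return VesiclePopulation(
        particles=particles,
        condition_label=condition_label,
        replicate_id=replicate_id,
        rng_seed=config.seed,
        medium=medium,
        component_ids=comp_ids,
    )
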