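"""Reference study conditions and the synthetic experiment generator.

Emulates the layout of the two-condition vesicle comparison: untreated
("n") and glucose-stimulated ("g") vesicle preparations run through the
27-gate device at readout voltages 1800 → 600 V, with 3 biological
replicates for the n condition and 4 for g, producing one intensity row per
(condition, replicate, voltage, gate).

Mixture locations anchor to the EKMr features reported for the two
conditions (n: ~3.5×10⁹, ~5.5×10⁹, 1.2×10¹⁰, 1.8×10¹⁰ V/m²; g: ~4×10⁹,
~7.5×10⁹, 1.1×10¹⁰, 2.3×10¹⁰ V/m²).  Component weights, dispersions and
brightnesses are illustrative defaults — the experiment does not quantify
them — and the absolute threshold scale is calibrated by pinning the last
gate's threshold at 1800 V to the largest EKMr at which signal was observed
(2.3×10¹⁰ V/m²), since the capture-parameter magnitude depends on tooth
shape details that are configurable here rather than measured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .field import GateProfile, gate_thresholds, solve_potential
from .geometry import ChannelGeometry, build_reference_geometry, rasterize
from .particles import MixtureComponent, MixtureConfig, sample_population
from .scanner import ScanProtocol, make_protocol, run_scan

__all__ = [
    "mixture_preset",
    "reference_profile",
    "calibrate",
    "simulate_experiment",
    "REFERENCE_REPLICATES",
    "CALIBRATION_ANCHOR_EKMR",
]

#: Biological replicates per condition in the reference comparison.
REFERENCE_REPLICATES = {"n": 3, "g": 4}

#: EKMr pinned to the last gate at 1800 V: the largest value with signal.
CALIBRATION_ANCHOR_EKMR = 2.3e10
CALIBRATION_ANCHOR_VOLTAGE = 1800.0

_PRESET_LOCATIONS = {
    "n": (3.5e9, 5.5e9, 1.2e10, 1.8e10),
    "g": (4.0e9, 7.5e9, 1.1e10, 2.3e10),
}
_PRESET_DISPERSION = 0.18  # log-space sd: narrow, well-defined subpopulations


def mixture_preset(
    condition: str, *, particle_count: int = 20_000, seed: int = 0
) -> MixtureConfig:
    """Equal-weight four-component EKMr mixture for condition "n" or "g"."""
    try:
        locations = _PRESET_LOCATIONS[condition]
    except KeyError:
        raise ValueError(f"unknown preset {condition!r}; choose 'n' or 'g'") from None
    k = len(locations)
    return MixtureConfig(
        components=tuple(
            MixtureComponent(weight=1.0 / k, location=loc, dispersion=_PRESET_DISPERSION)
            for loc in locations
        ),
        particle_count=particle_count,
        seed=seed,
    )


def calibrate(
    profile: GateProfile,
    *,
    anchor_ekmr: float = CALIBRATION_ANCHOR_EKMR,
    anchor_voltage: float = CALIBRATION_ANCHOR_VOLTAGE,
) -> GateProfile:
    """Rescale a profile so the last gate at ``anchor_voltage`` equals ``anchor_ekmr``."""
    factor = anchor_ekmr / (profile.unit_thresholds[-1] * anchor_voltage)
    return GateProfile(
        unit_thresholds=profile.unit_thresholds * factor,
        mask=profile.mask,
        calibration=profile.calibration * factor,
    )


def reference_profile(
    *,
    spacing_um: float = 3.0,
    solve_voltage: float = 1000.0,
    calibrated: bool = True,
) -> tuple[ChannelGeometry, GateProfile]:
    """Solve the reference device and return its geometry and gate profile.

    One full-channel Laplace solve at the given raster spacing; thresholds
    are voltage-normalized, so ``solve_voltage`` is arbitrary.
    """
    geometry = build_reference_geometry()
    mask = rasterize(geometry, spacing_um)
    solution = solve_potential(mask, solve_voltage)
    profile = gate_thresholds(solution)
    if calibrated:
        profile = calibrate(profile)
    return geometry, profile


def _jitter_mixture(
    config: MixtureConfig,
    rng: np.random.Generator,
    weight_concentration: float,
    location_log_sd: float,
) -> MixtureConfig:
    """Replicate-level biological variability: perturb weights and locations.

    Weights are redrawn from a Dirichlet centered on the nominal mixture
    (``weight_concentration`` scales how tightly), locations get a small
    log-normal jitter — one vesicle preparation is never an exact copy of
    another.
    """
    base_w = config.weights
    w = rng.dirichlet(base_w * weight_concentration) if weight_concentration > 0 else base_w
    w = w / w.sum()
    comps = tuple(
        MixtureComponent(
            weight=float(wk),
            location=c.location * float(np.exp(location_log_sd * rng.standard_normal())),
            dispersion=c.dispersion,
            fluorescence_scale=c.fluorescence_scale,
        )
        for wk, c in zip(w, config.components)
    )
    return MixtureConfig(comps, config.particle_count, config.seed)


def simulate_experiment(
    profile: GateProfile,
    *,
    seed: int = 0,
    replicates: dict[str, int] | None = None,
    particle_count: int = 20_000,
    protocol: ScanProtocol | None = None,
    noise_sigma_frac: float = 0.02,
    background_frac: float = 0.05,
    replicate_weight_concentration: float = 50.0,
    replicate_location_log_sd: float = 0.05,
) -> pd.DataFrame:
    """Simulate the full two-condition scanning experiment.

    For each condition and biological replicate, perturbs the condition's
    mixture preset (Dirichlet-jittered component weights, ~5% log-normal
    jitter on component locations — replicate preparations are biologically
    variable), draws a fresh population, runs the scanning protocol, and
    stacks the per-gate intensity rows.  Readout noise and a flat imaging
    background are added in proportion to the mean per-gate signal, so
    downstream background subtraction and normalization have work to do.

    Returns the combined raw intensity table (columns ``condition,
    replicate, voltage_V, gate_index, intensity, background``).
    """
    replicates = replicates or dict(REFERENCE_REPLICATES)
    protocol = protocol or make_protocol()
    rng = np.random.default_rng([seed, 0x5CA])
    tables = []
    for condition, n_rep in sorted(replicates.items()):
        config = mixture_preset(
            condition, particle_count=particle_count, seed=seed
        )
        for rep in range(1, n_rep + 1):
            rep_config = _jitter_mixture(
                config, rng, replicate_weight_concentration, replicate_location_log_sd
            )
            pop = sample_population(rep_config, condition, replicate_id=f"r{rep}")
            scale = particle_count / profile.n_gates
            table, _ = run_scan(
                pop,
                profile,
                protocol,
                noise_sigma=noise_sigma_frac * scale,
                background=background_frac * scale,
                rng=rng,
            )
            tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    if "background" not in out:
        out["background"] = 0.0
    return out
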