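"""From per-gate intensity tables to EKMr spectra.

Processing order mirrors the measurement pipeline: per-gate background
subtraction, per-(replicate, voltage) normalization, aggregation of the
three consecutive same-width gates that share one EKMr value, then replicate
averaging (mean ± SEM).  Normalizing each replicate before averaging keeps
replicates on a common [0, 1] scale.

The EKMr coordinate of a gate triplet at voltage ``V`` is ``V`` times the
group-representative unit threshold (the mean of the near-identical member
thresholds — members differ only through discretization).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .field import GateProfile
from .geometry import ChannelGeometry

__all__ = [
    "subtract_background",
    "normalize_per_voltage",
    "aggregate_gate_triplets",
    "triplet_observations",
    "build_spectrum",
]


def subtract_background(raw, background):
    """Background-corrected intensity ``max(raw − background, 0)``.

    Accepts scalars or aligned arrays; negative inputs are rejected.  The
    result is clamped at zero — a gate dimmer than the nearby open channel
    carries no signal.
    """
    raw_a = np.asarray(raw, dtype=float)
    bg_a = np.asarray(background, dtype=float)
    if np.any(raw_a < 0) or np.any(bg_a < 0):
        raise ValueError("intensities and backgrounds must be non-negative")
    out = np.maximum(raw_a - bg_a, 0.0)
    return float(out) if out.ndim == 0 else out


def _corrected(table: pd.DataFrame, background) -> pd.DataFrame:
    t = table.copy()
    if background is None:
        background = t["background"] if "background" in t else 0.0
    t["intensity"] = subtract_background(t["intensity"].to_numpy(), background)
    return t.drop(columns=["background"], errors="ignore")


def normalize_per_voltage(
    table: pd.DataFrame,
    *,
    mode: str = "max",
    background=None,
) -> pd.DataFrame:
    """Normalize intensities within each (condition, replicate, voltage) group.

    ``mode="max"`` divides by the group maximum (each voltage's brightest
    gate becomes 1); ``mode="sum"`` divides by the group total.  A background
    column (or explicit ``background``) is subtracted first.  All-zero groups
    pass through unchanged with a warning.
    """
    if mode not in ("max", "sum"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    t = _corrected(table, background)
    keys = ["condition", "replicate", "voltage_V"]
    denom = t.groupby(keys)["intensity"].transform("max" if mode == "max" else "sum")
    zero = denom == 0
    if zero.any():
        warnings.warn(
            "all-zero intensity group(s) left unnormalized", stacklevel=2
        )
    t["intensity"] = np.where(zero, t["intensity"], t["intensity"] / denom.where(~zero, 1.0))
    return t


def _group_ekmr(
    geometry: ChannelGeometry, profile: GateProfile, voltage: float
) -> np.ndarray:
    """EKMr coordinate per width group: voltage × mean unit threshold."""
    groups = geometry.width_groups()
    return np.array(
        [voltage * profile.unit_thresholds[g].mean() for g in groups]
    )


def triplet_observations(
    table: pd.DataFrame,
    geometry: ChannelGeometry,
    profile: GateProfile,
    voltage: float,
) -> pd.DataFrame:
    """Per-replicate aggregated intensities at one voltage.

    Averages each replicate's (already normalized) intensities over the
    gates of each width group.  Returns columns ``condition, replicate,
    ekmr_level, ekmr_value, intensity`` — the observation layout the
    two-condition comparison consumes.
    """
    if len(profile.unit_thresholds) != geometry.n_gates:
        raise ValueError("profile does not match geometry gate count")
    sub = table[table["voltage_V"] == voltage]
    if sub.empty:
        raise ValueError(f"no rows at voltage {voltage}")
    groups = geometry.width_groups()
    ek = _group_ekmr(geometry, profile, voltage)
    gate_to_group = {}
    for k, grp in enumerate(groups):
        for i in grp:
            gate_to_group[i + 1] = k
    sub = sub.assign(ekmr_level=sub["gate_index"].map(gate_to_group))
    if sub["ekmr_level"].isna().any():
        raise ValueError("table contains gate indices outside the geometry")
    obs = (
        sub.groupby(["condition", "replicate", "ekmr_level"], as_index=False)[
            "intensity"
        ]
        .mean()
        .assign(ekmr_value=lambda d: ek[d["ekmr_level"].to_numpy()])
    )
    return obs


def aggregate_gate_triplets(
    table: pd.DataFrame,
    geometry: ChannelGeometry,
    profile: GateProfile,
    voltage: float,
) -> pd.DataFrame:
    """Spectrum rows at one voltage: mean ± SEM across replicates per triplet.

    Returns columns ``condition, voltage_V, ekmr_value,
    mean_normalized_intensity, sem, n_replicates``, ordered by increasing
    EKMr within each condition.  SEM is NaN for a single replicate.
    """
    obs = triplet_observations(table, geometry, profile, voltage)

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    rows = (
        obs.groupby(["condition", "ekmr_value"], as_index=False)
        .agg(
            mean_normalized_intensity=("intensity", "mean"),
            sem=("intensity", _sem),
            n_replicates=("intensity", "size"),
        )
        .assign(voltage_V=voltage)
        .sort_values(["condition", "ekmr_value"], ignore_index=True)
    )
    return rows[
        [
            "condition",
            "voltage_V",
            "ekmr_value",
            "mean_normalized_intensity",
            "sem",
            "n_replicates",
        ]
    ]


def build_spectrum(
    table: pd.DataFrame,
    geometry: ChannelGeometry,
    profile: GateProfile,
    *,
    mode: str = "max",
    background=None,
) -> pd.DataFrame:
    """Full pipeline over every voltage present in the table."""
    norm = normalize_per_voltage(table, mode=mode, background=background)
    parts = [
        aggregate_gate_triplets(norm, geometry, profile, v)
        for v in sorted(norm["voltage_V"].unique(), reverse=True)
    ]
    return pd.concat(parts, ignore_index=True)
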