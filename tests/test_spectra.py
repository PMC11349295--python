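"""Background subtraction, normalization, and gate-triplet aggregation."""

import numpy as np
import pandas as pd
import pytest

from idepsep.field import GateProfile
from idepsep.geometry import build_reference_geometry
from idepsep.particles import MixtureComponent, MixtureConfig, sample_population
from idepsep.scanner import make_protocol, run_scan
from idepsep.spectra import (
    aggregate_gate_triplets,
    build_spectrum,
    normalize_per_voltage,
    subtract_background,
    triplet_observations,
)


class TestSubtractBackground:
    @pytest.mark.parametrize(
        "raw,bg,expected", [(100, 30, 70), (30, 30, 0), (10, 30, 0)]
    )
    def test_clamped_subtraction(self, raw, bg, expected):
        assert subtract_background(raw, bg) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(-1, 0)
        with pytest.raises(ValueError):
            subtract_background(1, -2)

    def test_vectorized(self):
        out = subtract_background([100, 30, 10], 30)
        assert np.array_equal(out, [70, 0, 0])


def _table(intensities, voltage=1000.0, condition="n", replicate="r1"):
    return pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "voltage_V": voltage,
            "gate_index": np.arange(1, len(intensities) + 1),
            "intensity": intensities,
        }
    )


class TestNormalizePerVoltage:
    def test_max_normalization(self):
        out = normalize_per_voltage(_table([2.0, 4.0, 8.0]))
        assert np.allclose(out["intensity"], [0.25, 0.5, 1.0])

    def test_sum_normalization(self):
        out = normalize_per_voltage(_table([2.0, 4.0, 8.0]), mode="sum")
        assert np.allclose(out["intensity"], [2 / 14, 4 / 14, 8 / 14])

    def test_all_zero_group_passes_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_per_voltage(_table([0.0, 0.0]))
        assert np.allclose(out["intensity"], 0.0)

    def test_idempotent(self):
        once = normalize_per_voltage(_table([2.0, 4.0, 8.0]))
        twice = normalize_per_voltage(once)
        assert np.allclose(once["intensity"], twice["intensity"])

    def test_groups_normalized_independently(self):
        t = pd.concat(
            [_table([1.0, 2.0], voltage=1000.0), _table([5.0, 50.0], voltage=500.0)],
            ignore_index=True,
        )
        out = normalize_per_voltage(t)
        assert out.groupby("voltage_V")["intensity"].max().eq(1.0).all()

    def test_background_column_subtracted_first(self):
        t = _table([40.0, 70.0])
        t["background"] = 10.0
        out = normalize_per_voltage(t)
        assert np.allclose(out["intensity"], [0.5, 1.0])


@pytest.fixture(scope="module")
def ref27():
    """Reference geometry with hand-set, width-group-constant thresholds."""
    geometry = build_reference_geometry()
    unit = np.repeat(np.geomspace(1e6, 1.2e7, 9), 3)
    return geometry, GateProfile(unit_thresholds=unit, mask=None)


class TestAggregateGateTriplets:
    def test_27_gates_collapse_to_9_rows(self, ref27):
        geometry, profile = ref27
        table = _table(np.linspace(1, 27, 27))
        spec = aggregate_gate_triplets(table, geometry, profile, 1000.0)
        assert len(spec) == 9
        assert spec["ekmr_value"].is_monotonic_increasing

    def test_ekmr_is_voltage_times_group_threshold(self, ref27):
        geometry, profile = ref27
        table = _table(np.ones(27), voltage=1200.0)
        spec = aggregate_gate_triplets(table, geometry, profile, 1200.0)
        expected = 1200.0 * profile.unit_thresholds.reshape(9, 3).mean(axis=1)
        assert np.allclose(np.sort(spec["ekmr_value"]), expected)

    def test_group_mean_identity(self, ref27):
        geometry, profile = ref27
        table = _table(np.full(27, 0.7))
        spec = aggregate_gate_triplets(table, geometry, profile, 1000.0)
        assert np.allclose(spec["mean_normalized_intensity"], 0.7)

    def test_single_replicate_sem_is_nan(self, ref27):
        geometry, profile = ref27
        spec = aggregate_gate_triplets(_table(np.ones(27)), geometry, profile, 1000.0)
        assert spec["sem"].isna().all()
        assert (spec["n_replicates"] == 1).all()

    def test_replicate_mean_and_sem(self, ref27):
        geometry, profile = ref27
        t = pd.concat(
            [
                _table(np.full(27, 0.4), replicate="r1"),
                _table(np.full(27, 0.8), replicate="r2"),
            ],
            ignore_index=True,
        )
        spec = aggregate_gate_triplets(t, geometry, profile, 1000.0)
        assert np.allclose(spec["mean_normalized_intensity"], 0.6)
        # sd of {0.4, 0.8} is 0.2√2; SEM = sd/√2 = 0.2
        assert np.allclose(spec["sem"], 0.2)
        assert (spec["n_replicates"] == 2).all()

    def test_aggregation_commutes_with_rescaling(self, ref27):
        geometry, profile = ref27
        base = _table(np.linspace(0.1, 1.0, 27))
        a = aggregate_gate_triplets(base, geometry, profile, 1000.0)
        scaled = base.assign(intensity=base["intensity"] * 3.0)
        b = aggregate_gate_triplets(scaled, geometry, profile, 1000.0)
        assert np.allclose(
            b["mean_normalized_intensity"], 3.0 * a["mean_normalized_intensity"]
        )

    def test_unknown_gate_rejected(self, ref27):
        geometry, profile = ref27
        bad = _table(np.ones(28))  # gate 28 does not exist
        with pytest.raises(ValueError):
            aggregate_gate_triplets(bad, geometry, profile, 1000.0)


class TestSpectrumFromScan:
    def test_point_mass_population_occupies_single_row(self, ref27):
        geometry, profile = ref27
        cfg = MixtureConfig(
            components=(MixtureComponent(1.0, 5e9),), particle_count=100, seed=0
        )
        pop = sample_population(cfg, "n")
        protocol = make_protocol(20_000.0, 1000.0, 1000.0, 100.0)
        table, _ = run_scan(pop, profile, protocol)
        spec = build_spectrum(table, geometry, profile)
        nonzero = spec[spec["mean_normalized_intensity"] > 0]
        assert len(nonzero) == 1

    def test_two_component_peak_recovery(self, reference):
        """Spectrum argmax rows bracket well-separated component EKMr values
        within one gate-threshold spacing."""
        geometry, profile = reference
        voltage = 1200.0
        locations = (3e9, 9e9)
        cfg = MixtureConfig(
            components=tuple(MixtureComponent(0.5, loc, 0.02) for loc in locations),
            particle_count=4000,
            seed=4,
        )
        pop = sample_population(cfg, "n")
        protocol = make_protocol(21_000.0, voltage, voltage, 100.0)
        table, _ = run_scan(pop, profile, protocol)
        spec = build_spectrum(table, geometry, profile)
        spec = spec.sort_values("ekmr_value", ignore_index=True)
        ek = spec["ekmr_value"].to_numpy()
        intensity = spec["mean_normalized_intensity"].to_numpy()
        # the two largest rows should sit within one level spacing of truth
        top2 = np.sort(np.argsort(intensity)[-2:])
        for loc, idx in zip(sorted(locations), top2):
            lo = ek[idx - 1] if idx > 0 else 0.0
            hi = ek[idx + 1] if idx + 1 < len(ek) else np.inf
            assert lo <= loc <= hi


class TestTripletObservations:
    def test_observation_layout(self, ref27):
        geometry, profile = ref27
        t = pd.concat(
            [
                _table(np.random.default_rng(0).random(27), replicate=f"r{i}")
                for i in (1, 2, 3)
            ],
            ignore_index=True,
        )
        obs = triplet_observations(t, geometry, profile, 1000.0)
        assert set(obs.columns) == {
            "condition",
            "replicate",
            "ekmr_level",
            "ekmr_value",
            "intensity",
        }
        assert len(obs) == 9 * 3
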