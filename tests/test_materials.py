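"""Materials: volume fractions, homogenisation, mixture heat capacity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestherm.materials import (
    AIR,
    BEACH_SAND,
    NEST_SAND,
    QUARTZITE,
    WATER,
    ConstituentPhase,
    MixtureSpec,
    egg_properties,
    mixture_from_cores,
    mixture_heat_capacity,
    mori_tanaka_conductivity,
    nest_sand_density,
    properties_table,
    sand_effective_properties,
    volume_fractions,
)


def hashin_shtrikman_bounds(k1: float, f1: float, k2: float, f2: float):
    """Independent two-phase Hashin-Shtrikman bounds (k1 <= k2)."""
    assert k1 <= k2
    lower = k1 + f2 / (1.0 / (k2 - k1) + f1 / (3.0 * k1)) if k2 > k1 else k1
    upper = k2 + f1 / (1.0 / (k1 - k2) + f2 / (3.0 * k2)) if k2 > k1 else k2
    return lower, upper


class TestVolumeFractions:
    def test_fully_solid_limit(self):
        assert volume_fractions(2650.0, 2650.0, 0.0) == (1.0, 0.0, 0.0)

    def test_beach_sand_fractions(self):
        f_s, f_w, f_a = volume_fractions(1282.2, 2650.0, 0.04, 1000.0)
        assert f_s == pytest.approx(0.4839, abs=1e-4)
        assert f_w == pytest.approx(0.0513, abs=1e-4)
        assert f_a == pytest.approx(0.4648, abs=1e-4)
        assert f_s + f_w + f_a == pytest.approx(1.0, abs=1e-12)

    def test_overdense_input_rejected(self):
        with pytest.raises(ValueError):
            volume_fractions(2700.0, 2650.0, 0.04)

    def test_oversaturated_rejected(self):
        with pytest.raises(ValueError):
            volume_fractions(2000.0, 2650.0, 0.5)

    @given(
        db=st.floats(200.0, 2600.0),
        moisture=st.floats(0.0, 0.2),
    )
    @settings(deadline=None, max_examples=100)
    def test_round_trip(self, db, moisture):
        """Reconstructed bulk density and moisture equal the inputs."""
        try:
            f_s, f_w, f_a = volume_fractions(db, 2650.0, moisture, 1000.0)
        except ValueError:
            return  # oversaturated draw
        db_back = f_s * 2650.0
        water_mass = f_w * 1000.0
        assert db_back == pytest.approx(db, rel=1e-9)
        if db > 0:
            assert water_mass / db_back == pytest.approx(moisture, rel=1e-9, abs=1e-12)


class TestMoriTanaka:
    def test_homogeneous_limit(self):
        same = ConstituentPhase("x", 1000.0, 2.0, 1000.0)
        k = mori_tanaka_conductivity(same, [(same, 0.3), (same, 0.2)])
        assert k == pytest.approx(2.0, rel=1e-12)

    def test_no_inclusions_returns_matrix(self):
        assert mori_tanaka_conductivity(QUARTZITE, []) == QUARTZITE.conductivity

    def test_published_sand_conductivities(self):
        beach = sand_effective_properties(BEACH_SAND)
        nest = sand_effective_properties(NEST_SAND)
        assert beach.conductivity == pytest.approx(2.2, abs=0.05)
        assert nest.conductivity == pytest.approx(1.7, abs=0.05)
        # looser nest sand conducts less than denser beach sand
        assert nest.conductivity < beach.conductivity

    def test_rejects_nonpositive_conductivity(self):
        with pytest.raises(ValueError):
            bad = ConstituentPhase.__new__(ConstituentPhase)
            object.__setattr__(bad, "name", "bad")
            object.__setattr__(bad, "density", 1.0)
            object.__setattr__(bad, "conductivity", -1.0)
            object.__setattr__(bad, "heat_capacity", 1.0)
            mori_tanaka_conductivity(QUARTZITE, [(bad, 0.1)])

    @given(
        k_m=st.floats(0.1, 10.0),
        k_i=st.floats(0.01, 10.0),
        f_i=st.floats(0.0, 0.95),
    )
    @settings(deadline=None, max_examples=150)
    def test_two_phase_within_hashin_shtrikman(self, k_m, k_i, f_i):
        matrix = ConstituentPhase("m", 1.0, k_m, 1.0)
        incl = ConstituentPhase("i", 1.0, k_i, 1.0)
        k_eff = mori_tanaka_conductivity(matrix, [(incl, f_i)])
        lo_k, hi_k = sorted((k_m, k_i))
        if lo_k == k_m:
            lo, hi = hashin_shtrikman_bounds(k_m, 1 - f_i, k_i, f_i)
        else:
            lo, hi = hashin_shtrikman_bounds(k_i, f_i, k_m, 1 - f_i)
        assert lo - 1e-9 <= k_eff <= hi + 1e-9
        assert lo_k - 1e-12 <= k_eff <= hi_k + 1e-12

    @given(
        k_i=st.floats(0.05, 8.0),
        bump=st.floats(0.01, 2.0),
        f_i=st.floats(0.05, 0.9),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_inclusion_conductivity(self, k_i, bump, f_i):
        matrix = ConstituentPhase("m", 1.0, 3.0, 1.0)
        lo = mori_tanaka_conductivity(matrix, [(ConstituentPhase("a", 1, k_i, 1), f_i)])
        hi = mori_tanaka_conductivity(
            matrix, [(ConstituentPhase("a", 1, k_i + bump, 1), f_i)]
        )
        assert hi >= lo - 1e-12


class TestMixtureHeatCapacity:
    def test_single_phase(self):
        assert mixture_heat_capacity([(WATER, 1.0)], basis="mass") == WATER.heat_capacity

    def test_equal_mass_phases_average(self):
        a = ConstituentPhase("a", 1.0, 1.0, 1000.0)
        b = ConstituentPhase("b", 1.0, 1.0, 3000.0)
        assert mixture_heat_capacity([(a, 0.5), (b, 0.5)], basis="mass") == 2000.0

    def test_published_sand_heat_capacities(self):
        """The published subdomain table carries the volumetric rule-of-
        mixtures values in kJ m-3 K-1 (the egg row equals water's rho*c)."""
        beach = sand_effective_properties(BEACH_SAND)
        nest = sand_effective_properties(NEST_SAND)
        assert beach.volumetric_heat_capacity / 1000 == pytest.approx(829.9, abs=1.0)
        assert nest.volumetric_heat_capacity / 1000 == pytest.approx(661.3, abs=1.0)
        egg = egg_properties()
        assert egg.volumetric_heat_capacity / 1000 == pytest.approx(4177.6, abs=0.1)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mixture_heat_capacity([(WATER, 0.5), (AIR, 0.4)])

    def test_bounded_by_phase_values(self):
        f = BEACH_SAND.fractions()
        phases = [(QUARTZITE, f[0]), (WATER, f[1]), (AIR, f[2])]
        c_vol = mixture_heat_capacity(phases, basis="volume")
        vols = [p.density * p.heat_capacity for p, _ in phases]
        assert min(vols) <= c_vol <= max(vols)
        c_mass = mixture_heat_capacity(phases, basis="mass")
        caps = [p.heat_capacity for p, _ in phases]
        assert min(caps) <= c_mass <= max(caps)


class TestNestSandDensity:
    def test_identity_packing(self):
        assert nest_sand_density(1282.2, 0.015, 0.018, 0.003) == pytest.approx(1282.2)

    def test_field_volume_reconstruction(self):
        rho = nest_sand_density(1282.2, 0.012, 0.018, 0.003)
        assert rho == pytest.approx(1282.2 * 0.012 / 0.015, rel=1e-12)
        assert rho == pytest.approx(1025.76, abs=0.01)

    def test_clutch_exceeding_chamber_rejected(self):
        with pytest.raises(ValueError):
            nest_sand_density(1282.2, 0.012, 0.010, 0.012)


class TestEggProperties:
    def test_published_defaults(self):
        props = egg_properties()
        assert (props.density, props.conductivity, props.heat_capacity) == (
            1000.0,
            0.6,
            4177.6,
        )

    def test_override_passthrough(self):
        props = egg_properties(conductivity=0.65)
        assert props.conductivity == 0.65
        assert props.density == 1000.0
        assert props.heat_capacity == 4177.6

    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            egg_properties(density=-1.0)


class TestMixtureSpec:
    def test_oversaturation_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(2700.0, 0.04)

    def test_canonical_specs_valid(self):
        for spec in (BEACH_SAND, NEST_SAND):
            f = spec.fractions()
            assert sum(f) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in f)


def test_properties_table_matches_published_layout():
    table = properties_table()
    assert list(table.index) == ["beach_sand", "nest_sand", "eggs"]
    assert table.loc["beach_sand", "density_kg_m3"] == pytest.approx(1282.2)
    assert table.loc["nest_sand", "density_kg_m3"] == pytest.approx(1026.6)
    assert table.loc["eggs", "conductivity_w_m_c"] == pytest.approx(0.6)


def test_sand_core_reader_round_trip(tmp_path):
    import pandas as pd

    # three cores: 310 cm3 each, known wet/dry masses
    df = pd.DataFrame(
        {
            "depth_cm": [33, 53, 3],
            "wet_mass_g": [413.4, 413.4, 300.0],
            "dry_mass_g": [397.5, 397.5, 295.0],
            "core_volume_cm3": [310.0, 310.0, 310.0],
        }
    )
    path = tmp_path / "cores.csv"
    df.to_csv(path, index=False)
    from nestherm.materials import read_sand_cores

    cores = read_sand_cores(path)
    assert cores["dry_bulk_density"].iloc[0] == pytest.approx(397.5 / 310 * 1000)
    spec = mixture_from_cores(cores)  # shallow core excluded by default
    assert spec.dry_bulk_density == pytest.approx(397.5 / 310 * 1000)
    assert spec.gravimetric_moisture == pytest.approx((413.4 - 397.5) / 397.5)
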