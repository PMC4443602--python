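"""Volumetric translation: Morrow threshold, NOAEC, adjustment factors, HEC."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dustdose.model_b import (ModelBScenario, af_clearance, af_lungburden,
                              hec_simple_rule, hec_volumetric, morrow_threshold,
                              noaec_eq7, threshold_per_gram_lung)
from dustdose.physiology import load_physiology
from dustdose.quantities import Q


def _scenario(f_rat=0.075, f_human=0.164, threshold=1.0, t_half_rat=60.0,
              t_half_human=400.0, density=1.0, pool_rat=None, pool_human=None):
    rat = load_physiology("rat_reference_1kg")
    human = load_physiology("human_MAK_Brown")
    rat = dataclasses.replace(rat, clearance_half_time=Q(t_half_rat, "day"),
                              **({"macrophage_pool_volume_per_kg": Q(pool_rat, "ul/kg"),
                                  "macrophage_count_per_kg": None,
                                  "macrophage_cell_volume": None}
                                 if pool_rat else {}))
    human = dataclasses.replace(
        human, clearance_half_time=Q(t_half_human, "day"),
        **({"macrophage_pool_volume_per_kg": Q(pool_human, "ul/kg")}
           if pool_human else {}))
    return ModelBScenario(rat=rat, human=human,
                          rat_alveolar_fraction=f_rat,
                          human_alveolar_fraction=f_human,
                          threshold_volume_per_kg=Q(threshold, "ul/kg"),
                          particle_density=Q(density, "g/cm^3"))


class TestThresholds:
    @pytest.mark.parametrize("pool,frac,expected", [
        (70, 0.06, 4.2), (70, 0.0, 0.0), (500, 0.06, 30.0),
    ])
    def test_morrow_threshold(self, pool, frac, expected):
        t = morrow_threshold(Q(pool, "ul/kg"), frac)
        assert t.magnitude_in("ul/kg") == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("per_kg,lung,expected", [
        (4.2, 4.5, 0.9333), (4.2, 4.2, 1.0), (1.0, 4.5, 0.2222),
    ])
    def test_threshold_per_gram_lung(self, per_kg, lung, expected):
        t = threshold_per_gram_lung(Q(per_kg, "ul/kg"), Q(lung, "g/kg"))
        assert t.magnitude_in("ul/g") == pytest.approx(expected, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            morrow_threshold(Q(-1, "ul/kg"))
        with pytest.raises(ValueError):
            threshold_per_gram_lung(Q(0, "ul/kg"), Q(4.5, "g/kg"))


class TestNoaec:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(f_rat=0.075, threshold=1.0), 0.5311),
        (dict(f_rat=0.033, threshold=1.0), 1.2071),
        (dict(f_rat=0.063, threshold=4.2), 2.6557),
    ])
    def test_values(self, kwargs, expected):
        assert noaec_eq7(_scenario(**kwargs)).magnitude_in(
            "mg/m^3") == pytest.approx(expected, abs=1e-4)

    def test_undocumented_divisor_defaults_to_one(self):
        base = noaec_eq7(_scenario())
        halved = noaec_eq7(dataclasses.replace(_scenario(), fvi=2.0))
        assert halved.magnitude_in("mg/m^3") == pytest.approx(
            base.magnitude_in("mg/m^3") / 2, rel=1e-12)


class TestAdjustmentFactors:
    def test_af_lungburden_values(self):
        assert af_lungburden(_scenario(f_rat=0.075, f_human=0.164)) == \
            pytest.approx(0.9284, abs=1e-4)
        assert af_lungburden(_scenario(f_rat=0.063, f_human=0.084)) == \
            pytest.approx(1.5225, abs=1e-4)

    def test_af_lungburden_identity(self):
        rat = load_physiology("rat_reference_1kg")
        human = dataclasses.replace(
            load_physiology("human_MAK_Brown"),
            ventilation_rate_per_kg=rat.ventilation_rate_per_kg)
        s = ModelBScenario(rat=rat, human=human, rat_alveolar_fraction=0.1,
                           human_alveolar_fraction=0.1,
                           threshold_volume_per_kg=Q(1, "ul/kg"),
                           particle_density=Q(1, "g/cm^3"))
        assert af_lungburden(s) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("t_half_human,pools,expected", [
        (400, (None, None), 0.9333),
        (250, (None, None), 0.5833),
        (60, (70, 70), 1.0),
    ])
    def test_af_clearance_values(self, t_half_human, pools, expected):
        s = _scenario(t_half_human=t_half_human, pool_rat=pools[0],
                      pool_human=pools[1])
        assert af_clearance(s) == pytest.approx(expected, abs=1e-4)


class TestHecVolumetric:
    @pytest.mark.parametrize("kwargs,expected_hec", [
        (dict(f_rat=0.075, f_human=0.164, threshold=1.0, t_half_human=400), 0.528),
        (dict(f_rat=0.063, f_human=0.084, threshold=1.0, t_half_human=400), 1.031),
        (dict(f_rat=0.063, f_human=0.084, threshold=4.2, t_half_human=250), 6.931),
    ])
    def test_grid_rows(self, kwargs, expected_hec):
        res = hec_volumetric(_scenario(**kwargs))
        assert res.hec.magnitude_in("mg/m^3") == pytest.approx(expected_hec,
                                                               abs=1e-3)
        assert res.dimension_audit_clean

    def test_rat_fraction_cancels(self):
        """F_rat appears in the NOAEC and in AF_lungburden and cancels in the
        HEC — translation outcomes only depend on the human fraction."""
        hecs = {f: hec_volumetric(_scenario(f_rat=f)).hec.magnitude_in("mg/m^3")
                for f in (0.02, 0.075, 0.15)}
        vals = list(hecs.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=0.5, max_value=10),
           st.floats(min_value=1, max_value=5))
    def test_linear_in_threshold_and_density(self, thresh, rho):
        base = hec_volumetric(_scenario()).hec.magnitude_in("mg/m^3")
        scaled = hec_volumetric(
            _scenario(threshold=thresh, density=rho)).hec.magnitude_in("mg/m^3")
        assert scaled == pytest.approx(base * thresh * rho, rel=1e-10)

    def test_monotone_decreasing_in_human_half_time(self):
        fast = hec_volumetric(_scenario(t_half_human=250)).hec
        slow = hec_volumetric(_scenario(t_half_human=400)).hec
        assert fast > slow

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=0.03, max_value=0.2),
           st.floats(min_value=0.03, max_value=0.2),
           st.floats(min_value=30, max_value=120),
           st.floats(min_value=200, max_value=500),
           st.floats(min_value=20, max_value=200),
           st.floats(min_value=100, max_value=1000))
    def test_af_decomposition_equals_full_burden_per_pool_ratio(
            self, f_r, f_h, t_r, t_h, pool_r, pool_h):
        """AF_lungburden/AF_clearance is exactly the steady-state
        burden-per-pool ratio between species for all positive parameters."""
        s = _scenario(f_rat=f_r, f_human=f_h, t_half_rat=t_r, t_half_human=t_h,
                      pool_rat=pool_r, pool_human=pool_h)
        k_r = 1.0 / t_r
        k_h = 1.0 / t_h  # ln2 cancels in the ratio
        rat_side = 0.29 * f_r / (k_r * pool_r)
        human_side = (10 / 70) * f_h / (k_h * pool_h)
        assert af_lungburden(s) / af_clearance(s) == pytest.approx(
            rat_side / human_side, rel=1e-10)
        # and hec_volumetric's internal consistency check must pass
        hec_volumetric(s)


class TestSimpleRule:
    @pytest.mark.parametrize("rho,expected", [(1, 0.5), (2, 1.0), (4.3, 2.15)])
    def test_density_proportional(self, rho, expected):
        assert hec_simple_rule(Q(rho, "g/cm^3")).magnitude_in(
            "mg/m^3") == pytest.approx(expected, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            hec_simple_rule(Q(0, "g/cm^3"))
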