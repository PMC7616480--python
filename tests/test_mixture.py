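"""Mixture-theory body-water prediction under the six coefficient schemes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bisffm.cole import ColeParameters
from bisffm.mixture import (
    COEFFICIENT_REGISTRY,
    MIXTURE_METHODS,
    ConfigurationError,
    HydrationTable,
    default_config,
    ecw_hanai,
    ecw_icw_moissl,
    ffm_from_tbw,
    icw_hanai,
    predict_mixture,
)
from bisffm.records import ChildRecord
from bisffm.simulate import SynthConfig, generate_cohort


@pytest.fixture(scope="module")
def cfg():
    return default_config("sfb7_default")


def child(**kw):
    base = dict(
        child_id="x", sex=1, ethnicity_asian=0, age_days=1232.0,
        weight_scale_kg=15.7, height_cm=100.3, r50_ohm=721.0, kb=4.3,
    )
    base.update(kw)
    return ChildRecord(**base)


class TestEcwHanai:
    def test_matches_highprecision_oracle_at_cohort_means(self, cfg):
        # frozen from a 40-digit evaluation of the Hanai wire-conductor form
        assert ecw_hanai(100.3, 15.7, 786.0, cfg) == pytest.approx(
            4.20376713262, rel=1e-9
        )

    def test_power_law_scaling_in_r0(self, cfg):
        e1 = ecw_hanai(100.3, 15.7, 786.0, cfg)
        e2 = ecw_hanai(100.3, 15.7, 2 * 786.0, cfg)
        assert e2 == pytest.approx(e1 * 2 ** (-2 / 3), rel=1e-12)

    def test_kb_scaling_is_two_thirds_power(self, cfg):
        # kb enters the wire-conductor constant squared, so volume ~ kb^(2/3)
        cfg4 = dataclasses.replace(cfg, kb=4 * cfg.kb)
        assert ecw_hanai(100.3, 15.7, 786.0, cfg4) == pytest.approx(
            4 ** (2 / 3) * ecw_hanai(100.3, 15.7, 786.0, cfg), rel=1e-12
        )

    def test_monotone_in_height_weight_and_r0(self, cfg):
        base = ecw_hanai(100.3, 15.7, 786.0, cfg)
        assert ecw_hanai(105.0, 15.7, 786.0, cfg) > base
        assert ecw_hanai(100.3, 17.0, 786.0, cfg) > base
        assert ecw_hanai(100.3, 15.7, 850.0, cfg) < base

    def test_rejects_nonpositive_inputs(self, cfg):
        with pytest.raises(ValueError):
            ecw_hanai(100.3, 15.7, 0.0, cfg)
        with pytest.raises(ValueError):
            ecw_hanai(-1.0, 15.7, 786.0, cfg)


class TestIcwHanai:
    def test_matches_bisection_oracle(self, cfg):
        # frozen root from an exhaustive fine-grid bisection of the implicit
        # equation at (ecw from the oracle above, r0=786, rinf=597); the
        # scan confirms the root is unique on (0, 10*ecw)
        ecw = 4.20376713262
        assert icw_hanai(ecw, 786.0, 597.0, cfg) == pytest.approx(
            0.523237806007, rel=1e-8
        )

    @given(
        ecw=st.floats(1.0, 8.0),
        r0=st.floats(500.0, 1100.0),
        frac=st.floats(0.55, 0.95),
    )
    def test_root_satisfies_implicit_equation(self, cfg, ecw, r0, frac):
        rinf = frac * r0
        icw = icw_hanai(ecw, r0, rinf, cfg)
        assert icw > 0
        ri = r0 * rinf / (r0 - rinf)
        x = icw / ecw
        lhs = (1 + x) ** 2.5
        rhs = (r0 + ri) / ri * (1 + cfg.rho_ecw / cfg.rho_icw * x)
        assert abs(lhs - rhs) / rhs < 1e-10

    def test_no_intracellular_path_gives_vanishing_icw(self, cfg):
        # rinf -> r0 means R_I -> infinity: no current crosses membranes
        icw = icw_hanai(4.2, 786.0, 786.0 - 1e-6, cfg)
        assert icw == pytest.approx(0.0, abs=1e-6)

    def test_rejects_rinf_not_below_r0(self, cfg):
        with pytest.raises(ValueError):
            icw_hanai(4.2, 786.0, 786.0, cfg)
        with pytest.raises(ValueError):
            icw_hanai(0.0, 786.0, 597.0, cfg)


class TestMoissl:
    def test_matches_arithmetic_oracle_at_cohort_means(self):
        cfg = default_config("moissl")
        ecw, icw = ecw_icw_moissl(100.3, 15.7, 786.0, 597.0, cfg)
        assert ecw == pytest.approx(4.11505180096, rel=1e-9)
        assert icw == pytest.approx(5.06529708553, rel=1e-9)

    def test_k_ecw_is_exact_affine_in_inverse_bmi(self):
        cfg = default_config("moissl")
        h, bmi = 100.0, 15.5
        w = bmi * (h / 100) ** 2
        ecw, _ = ecw_icw_moissl(h, w, 786.0, 597.0, cfg)
        k = ecw / (h**2 * np.sqrt(w) / 786.0) ** (2 / 3)
        assert k == pytest.approx(cfg.moissl_a / 15.5 + cfg.moissl_b, rel=1e-12)

    def test_higher_bmi_shrinks_the_ecw_coefficient(self):
        cfg = default_config("moissl")
        h = 100.0
        e_low, _ = ecw_icw_moissl(h, 14.0 * (h / 100) ** 2, 786.0, 597.0, cfg)
        e_high, _ = ecw_icw_moissl(h, 18.0 * (h / 100) ** 2, 786.0, 597.0, cfg)
        k_low = e_low / (h**2 * np.sqrt(14.0) / 786.0) ** (2 / 3)
        k_high = e_high / (h**2 * np.sqrt(18.0) / 786.0) ** (2 / 3)
        assert k_high < k_low

    def test_volumes_decrease_in_their_resistances(self):
        cfg = default_config("moissl")
        e1, i1 = ecw_icw_moissl(100.3, 15.7, 786.0, 597.0, cfg)
        e2, _ = ecw_icw_moissl(100.3, 15.7, 850.0, 597.0, cfg)
        _, i3 = ecw_icw_moissl(100.3, 15.7, 786.0, 650.0, cfg)
        assert e2 < e1
        assert i3 < i1


class TestHydration:
    def test_exact_division(self, cfg):
        table = HydrationTable(entries=((1, 0.0, 4000.0, 0.75),))
        c = dataclasses.replace(cfg, hydration_table=table)
        assert ffm_from_tbw(9.0, 1232.0, 1, c) == pytest.approx(12.0, rel=1e-12)

    def test_cohort_typical_value(self, cfg):
        table = HydrationTable(entries=((0, 0.0, 4000.0, 0.765),))
        c = dataclasses.replace(cfg, hydration_table=table)
        assert ffm_from_tbw(8.74, 1232.0, 0, c) == pytest.approx(11.42, abs=0.005)

    def test_missing_entry_is_configuration_error(self, cfg):
        with pytest.raises(ConfigurationError):
            ffm_from_tbw(9.0, 5000.0, 1, cfg)

    def test_fraction_outside_physiological_band_rejected(self):
        with pytest.raises(ValueError):
            HydrationTable(entries=((1, 0.0, 4000.0, 1.0),))


class TestPredictMixture:
    def test_personal_kb_equal_to_default_reproduces_default(self):
        c = child(kb=4.3)
        params = ColeParameters(786.0, 597.0, 40.0, 0.1)
        out_default = predict_mixture(c, params, default_config("sfb7_default"))
        out_personal = predict_mixture(c, params, default_config("sfb7_personal_kb"))
        assert out_personal.ffm_kg == pytest.approx(out_default.ffm_kg, rel=1e-12)

    @pytest.mark.parametrize("method", MIXTURE_METHODS)
    def test_tbw_is_exactly_ecw_plus_icw(self, method):
        params = ColeParameters(786.0, 597.0, 40.0, 0.1)
        out = predict_mixture(child(), params, default_config(method))
        assert out.tbw_l == out.ecw_l + out.icw_l
        assert out.method_label == method

    @pytest.mark.parametrize("method", MIXTURE_METHODS)
    def test_more_resistive_body_has_less_ffm(self, method):
        """Scaling the whole Cole locus up (a uniformly more resistive body)
        must reduce predicted water and FFM for every scheme.  Varying R0
        alone is deliberately not asserted: with Rinf held fixed it shrinks
        the intracellular resistance and legitimately raises ICW."""
        cfgm = default_config(method)
        lo = predict_mixture(child(), ColeParameters(786.0, 597.0, 40.0, 0.1), cfgm)
        hi = predict_mixture(
            child(), ColeParameters(1.08 * 786.0, 1.08 * 597.0, 40.0, 0.1), cfgm
        )
        assert hi.ffm_kg < lo.ffm_kg
        assert hi.ecw_l < lo.ecw_l

    def test_matches_hand_chained_component_oracle(self, cfg):
        c = child()
        params = ColeParameters(786.0, 597.0, 40.0, 0.1)
        ecw = ecw_hanai(c.height_cm, c.weight_scale_kg, params.r0, cfg)
        icw = icw_hanai(ecw, params.r0, params.rinf, cfg)
        ffm = ffm_from_tbw(ecw + icw, c.age_days, c.sex, cfg)
        out = predict_mixture(c, params, cfg)
        assert out.ffm_kg == pytest.approx(ffm, rel=1e-12)

    def test_registry_covers_all_six_schemes(self):
        assert set(MIXTURE_METHODS) == {
            "sfb7_default", "sfb7_personal_kb", "moissl",
            "xitron_hydra", "xitron_4000b", "xitron_4000b_ellis",
        }
        for entry in COEFFICIENT_REGISTRY.values():
            assert "source" in entry

    def test_scheme_bias_ranking_stable_across_seeds(self):
        """The ordering of mean-bias magnitudes across schemes is a property
        of the coefficient sets, not of the particular cohort draw."""
        methods = [m for m in MIXTURE_METHODS if m != "sfb7_personal_kb"]
        rankings = []
        for seed in (5, 6, 7):
            cohort = generate_cohort(
                SynthConfig(seed=seed, n_children=300, generate_spectra=False)
            )
            dxa = np.array([r.ffm_dxa_kg for r in cohort.references])
            biases = {}
            for m in methods:
                cfgm = default_config(m)
                preds = np.array(
                    [
                        predict_mixture(
                            rec,
                            ColeParameters(
                                1.090 * rec.r50_ohm, 0.828 * rec.r50_ohm, 75.9, 0.1
                            ),
                            cfgm,
                        ).ffm_kg
                        for rec in cohort.records
                    ]
                )
                biases[m] = abs(float(np.mean(preds - dxa)))
            rankings.append(tuple(sorted(methods, key=biases.get)))
        assert rankings[0] == rankings[1] == rankings[2]
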