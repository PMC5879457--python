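"""Unit and property tests for the synthetic study generator."""

import math

import numpy as np
import pandas as pd
import pytest

from fotmech.synthetic_data import (
    CELL_TYPES,
    DEFAULT_BASE_PARAMS,
    DEFAULT_FREQUENCIES,
    GENES,
    EffectTemplate,
    MechParams,
    build_design,
    default_effect_template,
    fundamental_frequency,
    sample_animal_params,
    simulate_ct_table,
    simulate_differentials,
    simulate_fit_table,
    synthesize_waveform,
)


class TestMechParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MechParams(a=-1, b=0.2, c=5, e0=20, de=10, beta=0.5)
        with pytest.raises(ValueError):
            MechParams(a=2, b=-0.1, c=5, e0=20, de=10, beta=0.5)
        with pytest.raises(ValueError):
            MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.0)
        # negative dE is allowed (elastance may fall with frequency)
        MechParams(a=2, b=0.2, c=5, e0=20, de=-3.0, beta=0.5)

    def test_low_frequency_resistance(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        assert p.a_over_c == 0.4


class TestBuildDesign:
    def test_roster_size_is_product_of_factors(self):
        d = build_design(
            treatments=("HBSS", "CB", "AgNP"), doses=(("high", 0.5),),
            days=(1, 3, 7), n_per_group=5,
        )
        assert len(d.roster) == 3 * 1 * 3 * 5
        assert d.roster["animal_id"].is_unique

    def test_default_group_sizes_in_reported_range(self):
        d = build_design()
        sizes = d.roster.groupby(["treatment", "dose_label", "day"]).size()
        assert ((sizes >= 4) & (sizes <= 6)).all()

    def test_deterministic_given_seed(self):
        d1 = build_design(seed=3)
        d2 = build_design(seed=3)
        pd.testing.assert_frame_equal(d1.roster, d2.roster)

    @pytest.mark.parametrize("bad", [0, 1001])
    def test_rejects_out_of_range_group_size(self, bad):
        with pytest.raises(ValueError):
            build_design(n_per_group=bad)

    def test_rejects_empty_factor_sets(self):
        with pytest.raises(ValueError):
            build_design(treatments=())
        with pytest.raises(ValueError):
            build_design(days=())

    def test_rejects_decreasing_dose_order(self):
        with pytest.raises(ValueError):
            build_design(doses=(("high", 0.5), ("low", 0.05)))


class TestEffectTemplate:
    def test_control_shifts_must_be_unity(self):
        with pytest.raises(ValueError):
            EffectTemplate(mech_shifts={("HBSS", "high", 1): {"e0": 1.2}})

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            EffectTemplate(cell_props={("CB", "high", 1): {ct: 0.3 for ct in CELL_TYPES}})

    def test_default_template_control_is_neutral(self, template):
        key = ("HBSS", "high", 7)
        assert all(v == 1.0 for v in template.mech_shift(key).values())
        assert template.fold(key, "IL10") == 1.0
        assert math.isclose(sum(template.proportions(key).values()), 1.0)


class TestSampleAnimalParams:
    def test_zero_cv_collapses_to_base_times_shift(self, small_design, template):
        params = sample_animal_params(small_design, template, cv=0.0)
        base = DEFAULT_BASE_PARAMS
        for row in small_design.roster.itertuples(index=False):
            got = params[row.animal_id]
            shift = template.mech_shift((row.treatment, row.dose_label, row.day))
            for name in ("a", "b", "c", "e0", "de", "beta"):
                assert got.as_dict()[name] == pytest.approx(getattr(base, name) * shift[name])

    def test_control_zero_cv_equals_base(self, small_design, template):
        params = sample_animal_params(small_design, template, cv=0.0)
        ctrl = [p for aid, p in params.items() if aid.startswith("HBSS")]
        for p in ctrl:
            assert p.as_dict() == DEFAULT_BASE_PARAMS.as_dict()

    def test_geometric_mean_matches_base_at_large_n(self, template):
        # law of large numbers: geometric mean within 2% of base x shift
        design = build_design(
            treatments=("HBSS", "AgNP"), doses=(("high", 0.5),), days=(7,),
            n_per_group=1000, seed=5,
        )
        params = sample_animal_params(design, template, cv=0.2, rng=np.random.default_rng(5))
        shift = template.mech_shift(("AgNP", "high", 7))
        vals = np.array([
            [p.as_dict()[n] for n in ("a", "b", "c", "e0", "de", "beta")]
            for aid, p in params.items() if aid.startswith("AgNP")
        ])
        geo = np.exp(np.log(vals).mean(axis=0))
        expected = np.array([
            getattr(DEFAULT_BASE_PARAMS, n) * shift[n]
            for n in ("a", "b", "c", "e0", "de", "beta")
        ])
        assert np.all(np.abs(geo / expected - 1) < 0.02)

    def test_rejects_cv_out_of_range(self, small_design, template):
        with pytest.raises(ValueError):
            sample_animal_params(small_design, template, cv=0.7)


class TestSynthesizeWaveform:
    def test_single_tone_gain_is_impedance_magnitude(self):
        # RL(f)=0.5, EL(f)=25 at f=2.5 Hz -> |Z| = sqrt(0.25 + (25/(2 pi 2.5))^2)
        f = 2.5
        # choose params giving exactly RL=0.5, EL=25 at this f: constant spectra
        p = MechParams(a=0.5 * 5.0, b=0.5, c=5.0, e0=25.0, de=1e-12, beta=0.5)
        rec = synthesize_waveform(
            p, peep=0.0, freqs=[f], duration=8.0, noise_sd=0.0,
            rng=np.random.default_rng(0), phases=[0.0],
        )
        expected_gain = math.sqrt(0.5**2 + (25.0 / (2 * math.pi * f)) ** 2)
        assert expected_gain == pytest.approx(1.668, abs=5e-4)
        gain = (rec.pressure.max() - rec.pressure.min()) / (rec.flow.max() - rec.flow.min())
        assert gain == pytest.approx(expected_gain, rel=1e-3)

    def test_pure_resistance_gives_proportional_pressure(self):
        # EL ~ 0: pressure = peep + RL(f) * flow with zero phase shift
        p = MechParams(a=1.5, b=0.3, c=5.0, e0=1e-9, de=1e-12, beta=0.5)
        f = 2.0
        rec = synthesize_waveform(
            p, peep=3.0, freqs=[f], duration=4.0, noise_sd=0.0,
            rng=np.random.default_rng(0),
        )
        rl = (p.a + p.b * f) / (p.c + f)
        assert np.allclose(rec.pressure, 3.0 + rl * rec.flow, atol=1e-8)

    def test_zero_flow_leaves_peep_plus_noise(self, base_params):
        rec = synthesize_waveform(
            base_params, peep=2.0, freqs=[1.0], duration=2.0, noise_sd=0.0,
            rng=np.random.default_rng(0), amplitudes=[0.0],
        )
        assert np.allclose(rec.flow, 0.0)
        assert np.allclose(rec.pressure, 2.0)

    def test_rejects_duplicate_and_aliased_frequencies(self, base_params):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            synthesize_waveform(base_params, 0.0, freqs=[1.0, 1.0], rng=rng)
        with pytest.raises(ValueError):
            synthesize_waveform(base_params, 0.0, freqs=[200.0], sample_rate=256.0, rng=rng)
        with pytest.raises(ValueError):
            synthesize_waveform(base_params, 0.0, freqs=[1.0], duration=-1.0, rng=rng)

    def test_rejects_fractional_cycles(self, base_params):
        with pytest.raises(ValueError):
            synthesize_waveform(
                base_params, 0.0, freqs=[0.3], duration=8.0, rng=np.random.default_rng(0)
            )

    def test_deterministic_given_seed(self, base_params):
        a = synthesize_waveform(base_params, 3.0, noise_sd=0.05, rng=np.random.default_rng(9))
        b = synthesize_waveform(base_params, 3.0, noise_sd=0.05, rng=np.random.default_rng(9))
        assert np.array_equal(a.pressure, b.pressure)
        assert np.array_equal(a.flow, b.flow)


class TestCtTable:
    def test_unity_fold_and_zero_noise_reproduces_base_ct(self, small_design, template):
        table = simulate_ct_table(small_design, template, base_ct=26.0, ct_noise_sd=0.0)
        hbss = table[table["treatment"] == "HBSS"]
        assert np.allclose(hbss["ct_target"], 26.0)

    def test_sixty_fold_shifts_ct_by_log2_60(self, small_design):
        t = EffectTemplate(gene_folds={("AgNP", "high", 7): {"IL10": 60.0}})
        table = simulate_ct_table(small_design, t, ct_noise_sd=0.0)
        il10 = table[table["gene"] == "IL10"].set_index("treatment")["ct_target"]
        shift = il10["HBSS"] - il10["AgNP"]
        assert shift == pytest.approx(math.log2(60.0), abs=1e-12)
        assert shift == pytest.approx(5.907, abs=1e-3)

    def test_fourfold_is_two_cycles(self, small_design):
        t = EffectTemplate(gene_folds={("AgNP", "high", 7): {"IL6": 4.0}})
        table = simulate_ct_table(small_design, t, ct_noise_sd=0.0)
        il6 = table[table["gene"] == "IL6"].set_index("treatment")["ct_target"]
        assert il6["HBSS"] - il6["AgNP"] == pytest.approx(2.0)

    def test_one_row_per_group_and_gene(self, small_design, template):
        table = simulate_ct_table(small_design, template)
        assert len(table) == len(small_design.groups) * len(GENES)
        assert not table.duplicated(["group", "gene"]).any()

    def test_rejects_missing_required_genes(self, small_design, template):
        with pytest.raises(ValueError):
            simulate_ct_table(small_design, template, genes=("IL6",))


class TestDifferentials:
    def test_degenerate_proportions_put_all_cells_in_one_type(self, small_design):
        t = EffectTemplate(
            cell_props={
                k: {"macrophage": 1.0, "neutrophil": 0.0, "lymphocyte": 0.0, "eosinophil": 0.0}
                for k in small_design.groups
            }
        )
        counts = simulate_differentials(small_design, t, total_cells=200)
        assert (counts["macrophage"] == 200).all()
        assert (counts[["neutrophil", "lymphocyte", "eosinophil"]] == 0).all().all()

    def test_counts_sum_to_total(self, small_design, template):
        counts = simulate_differentials(small_design, template, total_cells=200)
        assert (counts[list(CELL_TYPES)].sum(axis=1) == 200).all()

    def test_multinomial_mean_matches_template(self):
        design = build_design(
            treatments=("CB",), doses=(("high", 0.5),), days=(1,), n_per_group=500, seed=2,
        )
        t = EffectTemplate(
            cell_props={("CB", "high", 1): {"macrophage": 0.95, "neutrophil": 0.05,
                                            "lymphocyte": 0.0, "eosinophil": 0.0}},
            control_treatment="CB_none",
        )
        counts = simulate_differentials(design, t, total_cells=200, rng=np.random.default_rng(3))
        mean_neut = counts["neutrophil"].mean()
        se = math.sqrt(200 * 0.05 * 0.95 / 500)
        assert abs(mean_neut - 10.0) < 4 * se

    def test_rejects_bad_total(self, small_design, template):
        with pytest.raises(ValueError):
            simulate_differentials(small_design, template, total_cells=0)


class TestFitTableSimulation:
    def test_null_shifts_keep_groups_exchangeable(self):
        t = simulate_fit_table(rng=np.random.default_rng(0), cv=0.0, cv_meas=0.0)
        assert np.allclose(t.groupby("treatment")["e0"].mean(), 20.0)

    def test_shift_applies_to_named_treatment_only(self):
        t = simulate_fit_table(
            shifts={"AgNP": {"e0": 0.7, "a": 0.7}}, cv=0.0, cv_meas=0.0,
            rng=np.random.default_rng(0),
        )
        means = t.groupby("treatment")[["e0", "a_over_c"]].mean()
        assert means.loc["AgNP", "e0"] == pytest.approx(14.0)
        assert means.loc["AgNP", "a_over_c"] == pytest.approx(0.28)
        assert means.loc["HBSS", "e0"] == pytest.approx(20.0)


def test_default_frequency_set_shape():
    f = np.asarray(DEFAULT_FREQUENCIES)
    assert f.size == 13
    assert f[0] == 0.5 and f[-1] == 20.5
    assert fundamental_frequency(f) == 0.5
    # mutually prime multiples of the fundamental
    mult = (f / 0.5).astype(int)
    for i in range(len(mult)):
        for j in range(i + 1, len(mult)):
            assert math.gcd(mult[i], mult[j]) == 1
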