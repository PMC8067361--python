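"""Injury model tests: damage filters, allocation, and the FAS<->ablation
correspondence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from manduca import (
    DamageLabel,
    InjuryDomainError,
    InjurySpec,
    ablation_to_fas,
    apply_injury_pn_qn,
    apply_injury_rn,
    assign_damage,
    expected_retained_fraction,
    fas_ablation_ratio,
    fas_filter,
    fas_to_ablation,
    generate_instance,
)
from manduca.errors import ConfigurationError
from manduca.injury import DEFAULT_FRACTIONS


class TestFasFilter:
    @pytest.mark.parametrize(
        "rate,label,expected",
        [
            (10.0, DamageLabel.REFLECT, 5.0),
            (10.0, DamageLabel.ABLATE, 0.0),
            (10.0, DamageLabel.TRANSMIT, 10.0),
            (0.0, DamageLabel.LOWPASS, 0.0),
            (0.0, DamageLabel.REFLECT, 0.0),
        ],
    )
    def test_damage_type_arithmetic(self, rate, label, expected):
        assert fas_filter(np.asarray(rate), label) == pytest.approx(expected)

    def test_lowpass_at_unit_rate_hits_nominal_bottom(self):
        # with the normalized [0, 1] reference range a unit rate gets 0.7
        assert fas_filter(np.asarray(1.0), DamageLabel.LOWPASS) == pytest.approx(0.7)

    def test_lowpass_band_and_monotone_harm(self):
        rates = np.linspace(0, 1, 11)
        out = fas_filter(rates, DamageLabel.LOWPASS)
        factors = out[1:] / rates[1:]
        assert np.all(factors >= 0.7 - 1e-12)
        assert np.all(factors <= 0.9 + 1e-12)
        assert np.all(np.diff(factors) <= 1e-12)  # high rates hit harder

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            fas_filter(np.asarray(-1.0), DamageLabel.TRANSMIT)

    @given(st.floats(min_value=0, max_value=1e3), st.sampled_from(list(DamageLabel)))
    def test_never_increases_rate(self, rate, label):
        out = float(fas_filter(np.asarray(rate), label))
        assert 0.0 <= out <= rate + 1e-9


class TestAssignDamage:
    def test_worked_example_300_neurons_half_injured(self):
        labels = assign_damage(300, 0.5, seed=7)
        injured = labels[labels >= 0]
        assert injured.size == 150
        counts = np.bincount(injured, minlength=4)
        # largest-remainder split of (0.15, 0.35, 0.35, 0.15) * 150
        for c, quota in zip(counts, np.array(DEFAULT_FRACTIONS) * 150):
            assert abs(c - quota) <= 1.0
        assert counts.sum() == 150

    def test_full_injury_has_exact_proportions(self):
        labels = assign_damage(100, 1.0, seed=3)
        assert np.bincount(labels, minlength=4).tolist() == [15, 35, 35, 15]

    def test_zero_level_injures_nobody(self):
        assert np.all(assign_damage(1000, 0.0, seed=0) == -1)

    def test_deterministic_given_seed(self):
        a = assign_damage(500, 0.3, seed=11)
        b = assign_damage(500, 0.3, seed=11)
        assert np.array_equal(a, b)

    @given(st.integers(min_value=1, max_value=400), st.floats(min_value=0, max_value=1))
    def test_counts_are_exact_not_binomial(self, n, level):
        labels = assign_damage(n, level, seed=1)
        assert (labels >= 0).sum() == int(round(level * n))


class TestCorrespondence:
    def test_expected_retained_default_fractions(self):
        # 0.15*1 + 0.35*0.5 + 0.35*0 + 0.15*0.7
        assert expected_retained_fraction() == pytest.approx(0.43, abs=1e-12)

    def test_all_transmit_retains_everything(self):
        assert expected_retained_fraction((1, 0, 0, 0)) == pytest.approx(1.0)

    def test_nominal_ratio_and_exact_ratio(self):
        assert fas_ablation_ratio() == pytest.approx(1.75, abs=1e-12)
        assert fas_ablation_ratio(ndigits=None) == pytest.approx(1 / 0.57, rel=1e-9)

    @pytest.mark.parametrize(
        "m,n", [(0.35, 0.20), (0.0, 0.0), (0.0175, 0.01), (0.175, 0.10)]
    )
    def test_fas_to_ablation_worked_conversions(self, m, n):
        assert fas_to_ablation(m) == pytest.approx(n, abs=1e-12)

    @given(st.floats(min_value=0, max_value=0.9))
    def test_conversion_roundtrip_is_identity(self, m):
        assert ablation_to_fas(fas_to_ablation(m)) == pytest.approx(m, rel=1e-9, abs=1e-12)

    def test_iid_monte_carlo_agrees_with_closed_form(self, rng):
        # i.i.d. damage types at unit firing rate, modest n (the acceptance
        # suite repeats this at >= 1e5 neurons)
        n = 20000
        labels = rng.choice(4, size=n, p=DEFAULT_FRACTIONS)
        mult = np.array([1.0, 0.5, 0.0, 0.7])[labels]
        se = np.sqrt(0.126 / n)  # var of the multiplier distribution
        assert abs(mult.mean() - 0.43) < 3 * se + 1e-9


class TestApplyInjuryRn:
    def test_zero_level_is_identity_scaling(self, small_template):
        inst = generate_instance(small_template, 1)
        injured = apply_injury_rn(inst, InjurySpec(site="rn_channel", level=0.0))
        assert injured.injury.rn_ablation_level == 0.0
        assert injured.injury.rn_noise_scale == 1.0

    def test_worked_scaling_at_35_percent(self, small_template):
        inst = generate_instance(small_template, 1)
        injured = apply_injury_rn(inst, InjurySpec(site="rn_channel", level=0.35))
        assert injured.injury.rn_ablation_level == pytest.approx(0.20)
        assert injured.injury.rn_noise_scale == pytest.approx(1.25)

    def test_conversion_at_17_5_percent(self, small_template):
        inst = generate_instance(small_template, 1)
        injured = apply_injury_rn(inst, InjurySpec(site="rn_channel", level=0.175))
        assert injured.injury.rn_ablation_level == pytest.approx(0.10)

    def test_total_destruction_rejected(self, small_template):
        inst = generate_instance(small_template, 1)
        with pytest.raises(InjuryDomainError):
            apply_injury_rn(inst, InjurySpec(site="rn_channel", kind="ablation", level=1.0))

    def test_site_mismatch_rejected(self, small_template):
        inst = generate_instance(small_template, 1)
        with pytest.raises(ConfigurationError):
            apply_injury_rn(inst, InjurySpec(site="pn_qn_channel", level=0.2))


class TestApplyInjuryPnQn:
    def test_fas_keeps_non_ablated_neurons_alive(self, small_template):
        inst = generate_instance(small_template, 2)
        injured = apply_injury_pn_qn(
            inst, InjurySpec(site="pn_qn_channel", kind="fas", level=0.5, seed=4)
        )
        labels = injured.injury.labels
        mult = injured.injury.static_multiplier
        non_ablate = (labels >= 0) & (labels != DamageLabel.ABLATE.value)
        assert np.all(mult[non_ablate] > 0)
        assert np.all(mult[labels == DamageLabel.ABLATE.value] == 0)

    def test_ablation_kind_zeroes_selected_neurons_only(self, small_template):
        inst = generate_instance(small_template, 2)
        injured = apply_injury_pn_qn(
            inst, InjurySpec(site="pn_qn_channel", kind="ablation", level=0.4, seed=4)
        )
        mult = injured.injury.static_multiplier
        n_al = inst.n_pn_total + inst.n_qn_total
        assert (mult == 0).sum() == int(round(0.4 * n_al))
        assert np.all((mult == 0) | (mult == 1))

    def test_pooled_population_includes_qns(self):
        from manduca import MothTemplate

        tpl = MothTemplate(n_glomeruli=20, n_kc=100, n_odor_targets=8, n_qn_per_glom=4)
        inst = generate_instance(tpl, 5)
        injured = apply_injury_pn_qn(
            inst, InjurySpec(site="pn_qn_channel", level=0.5, seed=1)
        )
        labels = injured.injury.labels
        n_pn = inst.n_pn_total
        # both PN and QN segments of the pooled population get injured
        assert (labels[:n_pn] >= 0).any()
        assert (labels[n_pn:] >= 0).any()

    def test_pooled_rn_treatment_matches_explicit_neuron_average(self, rng):
        # pooled attenuation (1 - m * (1 - retained)) vs an explicit large
        # population of unit-rate neurons passed through per-neuron filters
        m = 0.42
        n = 40000
        labels = assign_damage(n, m, seed=9)
        mult = np.ones(n)
        for label in DamageLabel:
            mask = labels == label.value
            mult[mask] = fas_filter(np.ones(mask.sum()), label)
        pooled = 1.0 - m * (1.0 - expected_retained_fraction())
        assert mult.mean() == pytest.approx(pooled, abs=3 * np.sqrt(0.126 / n) + 1e-3)
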