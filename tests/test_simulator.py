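"""Equilibrium occupancy model: weights, recruitment, activation, curves."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixsynergy.exceptions import CapacityError, InputError
from helixsynergy.helix_geometry import BindingSite, HelixParameters, SiteArrangement
from helixsynergy.simulator import (
    DEFAULT_MODEL_PARAMS,
    ZEBRA_MODEL_PARAMS,
    SynergyModelParams,
    activation,
    expected_recruitment,
    hindrance_fraction,
    occupancy_distribution,
    sample_occupancy_metropolis,
    simulate_curve,
    simulate_template,
    state_weight,
)
from helixsynergy.templates import (
    TEMPLATE_CATALOG,
    build_arrangement,
    single_site_template,
    two_site_template,
)


def arrangement_at_c2c(c2c: int, n: int = 2) -> SiteArrangement:
    """n single-bp activator sites spaced c2c apart (no TATA)."""
    sites = tuple(
        BindingSite(f"S{i}", start=1 + i * c2c, length=1, factor="GAL4")
        for i in range(n)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SiteArrangement(sites=sites, params=HelixParameters())


SAME_FACE = arrangement_at_c2c(20)  # folded phase 0
OPPOSITE = arrangement_at_c2c(25)  # folded phase 180


class TestStateWeight:
    def test_empty_state_is_unity(self):
        assert state_weight(0, SAME_FACE, DEFAULT_MODEL_PARAMS) == 1.0

    def test_single_bound_is_K(self):
        p = SynergyModelParams(K=0.37)
        assert state_weight(1, SAME_FACE, p) == pytest.approx(0.37)

    def test_opposite_pair_has_no_penalty(self):
        """At folded phase 180 the angular kernel is exactly zero."""
        p = SynergyModelParams(K=0.5, w=50.0)
        assert state_weight(3, OPPOSITE, p) == pytest.approx(0.25)

    def test_kernel_endpoints(self):
        assert hindrance_fraction(0.0) == 1.0
        assert hindrance_fraction(180.0) == pytest.approx(0.0, abs=1e-30)
        assert hindrance_fraction(180.0, sharpness=2.5) == pytest.approx(0.0, abs=1e-30)


class TestOccupancyDistribution:
    def test_single_site_closed_form(self):
        arr = arrangement_at_c2c(20, n=1)
        p = SynergyModelParams(K=0.8, w=0.0)
        probs = occupancy_distribution(arr, p)
        assert probs[1] == pytest.approx(0.8 / 1.8)

    def test_no_hindrance_sites_independent(self):
        """w=0: the joint distribution is the product of marginals."""
        arr = arrangement_at_c2c(20, n=3)
        p = SynergyModelParams(K=0.6, w=0.0)
        probs = occupancy_distribution(arr, p)
        marginal = 0.6 / 1.6
        for state in range(8):
            k = bin(state).count("1")
            assert probs[state] == pytest.approx(
                marginal**k * (1 - marginal) ** (3 - k)
            )

    def test_extreme_hindrance_forbids_same_face_double(self):
        p = SynergyModelParams(K=1.0, w=1e6, xi=1e9, sharpness=1.0)
        probs = occupancy_distribution(SAME_FACE, p)
        assert probs[3] < 1e-12

    def test_capacity_limit(self):
        arr = arrangement_at_c2c(11, n=13)
        with pytest.raises(CapacityError):
            occupancy_distribution(arr, DEFAULT_MODEL_PARAMS)

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(0, 10_000),
        st.integers(2, 6),
    )
    def test_normalization(self, seed, n_sites):
        rng = np.random.default_rng(seed)
        p = SynergyModelParams(
            K=float(rng.uniform(0.1, 5)),
            w=float(rng.uniform(0, 10)),
            xi=float(rng.uniform(5, 300)),
            sharpness=float(rng.uniform(1, 3)),
        )
        arr = arrangement_at_c2c(int(rng.integers(3, 30)), n=n_sites)
        probs = occupancy_distribution(arr, p)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_matches_metropolis(self):
        """Stochastic oracle: 1e5-step sampler agrees within 3 MC SE."""
        arr = arrangement_at_c2c(13, n=4)
        p = SynergyModelParams(K=1.2, w=3.0, xi=100.0, sharpness=1.5)
        exact = occupancy_distribution(arr, p)
        n_steps = 100_000
        sampled = sample_occupancy_metropolis(arr, p, n_steps=n_steps, seed=42)
        # conservative SE: iid binomial scaled by an autocorrelation margin
        se = 3 * np.sqrt(exact * (1 - exact) / n_steps) * 5 + 1e-3
        assert np.all(np.abs(sampled - exact) < 3 * se)


class TestExpectedRecruitment:
    def test_single_site_closed_form(self):
        arr = arrangement_at_c2c(20, n=1)
        p = SynergyModelParams(K=0.8, r=0.4)
        assert expected_recruitment(arr, p) == pytest.approx(0.4 * 0.8 / 1.8)

    def test_opposite_pair_doubles_single_site_rate(self):
        """Phase 180: no hindrance, no interference; sites act independently."""
        p = SynergyModelParams(K=0.8, r=0.4, w=7.0, rho=1.0)
        single = expected_recruitment(arrangement_at_c2c(25, n=1), p)
        double = expected_recruitment(OPPOSITE, p)
        assert double == pytest.approx(2 * single)

    def test_full_interference_at_zero_distance(self):
        """rho=1 at phase 0 and distance 0: bound pairs recruit nothing."""
        sites = (
            BindingSite("A", start=1, length=1, factor="GAL4"),
            BindingSite("B", start=1, length=1, factor="GAL4"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = SiteArrangement(sites=sites, params=HelixParameters())
        p = SynergyModelParams(K=1.0, w=0.0, rho=1.0, r=0.5)
        probs = occupancy_distribution(arr, p)
        expected = (probs[1] + probs[2]) * 0.5  # only singly-bound states recruit
        assert expected_recruitment(arr, p) == pytest.approx(expected)


class TestActivation:
    def test_zero_recruitment_gives_basal(self):
        assert activation(0.0, DEFAULT_MODEL_PARAMS) == DEFAULT_MODEL_PARAMS.A_basal

    def test_half_saturation(self):
        p = DEFAULT_MODEL_PARAMS
        assert activation(p.R50, p) == pytest.approx(p.A_basal + p.A_max / 2)

    def test_hill_superadditivity_of_weak_activators(self):
        """m=2: doubling a weak recruitment more than doubles the response."""
        p = SynergyModelParams(m=2.0, R50=1.0, A_basal=0.0, A_max=100.0)
        R = 0.05
        assert activation(2 * R, p) > 2 * activation(R, p)


class TestSimulateCurve:
    def test_no_hindrance_no_interference_no_peaks(self):
        from helixsynergy.activity_analysis import detect_peaks

        p = SynergyModelParams(w=0.0, rho=0.0)
        c = simulate_curve(range(0, 49, 2), params=p)
        assert detect_peaks(c) == []

    def test_default_argmax_at_first_antipodal_spacer(self):
        c = simulate_curve(range(0, 49, 2))
        assert c.spacers[int(np.argmax(c.mean))] == 8.0

    def test_monotone_in_dose(self):
        base = simulate_curve(range(0, 49, 2))
        doubled = simulate_curve(range(0, 49, 2), dose=2.0)
        assert np.all(doubled.mean > base.mean)

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            simulate_curve([])


class TestPhaseProperties:
    def test_all_opposite_activation_independent_of_w(self):
        """g(180) = 0 removes every hindrance term."""
        design = two_site_template(8)  # c2c 25, folded phase 180
        values = {
            w: simulate_template(design, SynergyModelParams(w=w))
            for w in (0.0, 1.0, 10.0, 1e4)
        }
        ref = values[0.0]
        assert all(v == pytest.approx(ref, rel=1e-12) for v in values.values())

    def test_same_face_activation_non_increasing_in_w(self):
        design = two_site_template(3)  # c2c 20, folded phase 0
        ws = [0.0, 0.5, 1.0, 2.0, 5.0, 20.0]
        vals = [simulate_template(design, SynergyModelParams(w=w)) for w in ws]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestCalibrationContract:
    def test_min_synergy_ratio_exceeds_two(self):
        c = simulate_curve(range(0, 49, 2))
        one = simulate_template(single_site_template("GAL4"))
        assert (c.mean / one).min() > 2.0

    def test_template_panel_ordering(self):
        v = {k: simulate_template(TEMPLATE_CATALOG[k]) for k in TEMPLATE_CATALOG}
        assert v["145"] > v["142"]
        assert v["196"] / v["193"] >= 2.0
        assert v["191"] > v["190"] and v["192"] > v["190"]
        assert 0.5 < v["191"] / v["192"] < 2.0
        assert v["189"] > v["187"]
        assert v["Z8Z"] > v["Z4Z"]

    def test_zebra_noise_free_single_peak(self):
        from helixsynergy.activity_analysis import detect_peaks

        c = simulate_curve(
            range(0, 21, 2), factor="ZIIIB", params=ZEBRA_MODEL_PARAMS
        )
        assert detect_peaks(c) == [8.0]


def test_template_arrangement_face_structure(helix):
    """Template 142's GAL4 pair is same-face; 145's is opposite-face."""
    from helixsynergy.helix_geometry import Face, classify_arrangement

    for key, expected in (("142", Face.SAME), ("145", Face.OPPOSITE)):
        arr = build_arrangement(TEMPLATE_CATALOG[key], helix, include_tata=False)
        result = classify_arrangement(arr)
        assert result.pair_classes[(0, 1)].value is expected
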