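"""Normalization, peak detection, periodic fit, synergy and comparisons."""

import numpy as np
import pandas as pd
import pytest

from helixsynergy.activity_analysis import (
    ActivationCurve,
    ActivityTable,
    _periodic_model,
    compare_templates,
    curve_from_table,
    detect_peaks,
    fit_periodic_attenuation,
    normalize,
    synergy_ratio,
    titration_summary,
)
from helixsynergy.emsa_analysis import DetrendedSeries, find_local_minima
from helixsynergy.exceptions import InputError
from helixsynergy.simulator import simulate_curve
from helixsynergy.synthetic import NoiseSpec, generate_activity_dataset
from helixsynergy.templates import TEMPLATE_CATALOG


def table(rows):
    return ActivityTable(rows=pd.DataFrame(rows))


def curve(values, start=0, step=2):
    values = np.asarray(values, dtype=float)
    return ActivationCurve(
        spacers=np.arange(start, start + step * len(values), step, dtype=float),
        mean=values,
        sd=np.zeros_like(values),
        n=np.ones(len(values), dtype=int),
    )


class TestNormalize:
    def test_ratio(self):
        t = table(
            [{"template_id": "x", "replicate": 1, "firefly": 1000.0, "renilla": 100.0}]
        )
        assert normalize(t)["activity"].iloc[0] == 10.0

    def test_identical_replicates_zero_sd(self):
        t = table(
            [
                {"template_id": "x", "spacer_bp": 0, "replicate": i, "firefly": 500.0,
                 "renilla": 50.0}
                for i in range(1, 4)
            ]
        )
        c = curve_from_table(t)
        assert c.sd[0] == 0.0 and c.n[0] == 3

    def test_nonpositive_renilla_rejected_with_warning(self):
        t = table(
            [
                {"template_id": "x", "replicate": 1, "firefly": 10.0, "renilla": 1.0},
                {"template_id": "x", "replicate": 2, "firefly": 10.0, "renilla": 0.0},
            ]
        )
        with pytest.warns(UserWarning, match="renilla"):
            out = normalize(t)
        assert len(out) == 1

    def test_triplicate_mean_unbiased(self):
        """Lognormal CV-10% triplicates: grand mean within 3 SE of truth."""
        truth = {}
        means = []
        for seed in range(100):
            tab = generate_activity_dataset(
                spacers=[8], noise=NoiseSpec(cv=0.10, n_replicates=3, seed=seed)
            )
            df = normalize(tab)
            means.append(df["activity"].mean())
            if not truth:
                noise_free = generate_activity_dataset(
                    spacers=[8], noise=NoiseSpec(cv=0.0, seed=0)
                )
                truth["value"] = normalize(noise_free)["activity"].iloc[0]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - truth["value"]) < 3 * se


class TestDetectPeaks:
    def test_noise_free_generator_peaks_at_opposite_spacers(self):
        c = simulate_curve(range(0, 49, 2))
        assert detect_peaks(c) == [8.0, 18.0, 28.0, 38.0]

    def test_monotone_decreasing_has_no_peaks(self):
        assert detect_peaks(curve(np.linspace(5, 1, 12))) == []

    def test_single_interior_bump(self):
        vals = [1, 1, 1, 4, 1, 1, 1]
        assert detect_peaks(curve(vals), tie_epsilon=0.0) == [6.0]

    def test_mirror_of_minimum_finder(self, rng):
        """Shared contract: peaks of x are minima of -x, identically."""
        for _ in range(25):
            vals = rng.normal(size=16)
            c = curve(vals)
            mirrored = DetrendedSeries(spacers=c.spacers, residuals=-vals)
            assert detect_peaks(c, tie_epsilon=0.1) == find_local_minima(
                mirrored, tie_epsilon=0.1
            )


class TestPeriodicFit:
    def test_noise_free_period_recovery(self):
        s = np.arange(0, 49, 2.0)
        y = _periodic_model(s, 10.0, 2.0, 0.01, 0.5, 3.0)
        fit = fit_periodic_attenuation(curve(y))
        assert fit.converged
        assert fit.period == pytest.approx(10.0, abs=0.05)

    def test_noisy_period_within_half_bp(self):
        rng = np.random.default_rng(77)
        s = np.arange(0, 49, 2.0)
        y = _periodic_model(s, 10.0, 2.0, 0.01, 0.5, 3.0)
        noisy = y * rng.lognormal(0, 0.10 * np.sqrt(2 / 3), size=y.size)
        fit = fit_periodic_attenuation(curve(noisy))
        assert abs(fit.period - 10.0) < 0.5

    def test_flat_curve_flagged_not_raised(self):
        fit = fit_periodic_attenuation(curve(np.full(25, 3.0)))
        assert not fit.converged
        assert fit.amplitude == 0.0

    def test_short_grid_rejected(self):
        with pytest.raises(InputError):
            fit_periodic_attenuation(curve([1.0, 2.0, 1.0]))


class TestSynergyRatio:
    def test_exact_double_is_not_synergy(self):
        c = curve([2.0, 2.0, 2.0, 2.0])
        result = synergy_ratio(c, 1.0)
        assert result.min_ratio == 2.0
        assert not result.synergy

    def test_one_site_greater_gives_subunit_ratio(self):
        result = synergy_ratio(curve([0.5, 0.6]), 1.0)
        assert result.min_ratio < 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(InputError):
            synergy_ratio(curve([1.0]), 0.0)

    def test_default_generator_exceeds_additivity(self):
        """Calibration contract: simulated two-site always beats 2x one-site."""
        from helixsynergy.simulator import simulate_template
        from helixsynergy.templates import single_site_template

        c = simulate_curve(range(0, 49, 2))
        one = simulate_template(single_site_template("GAL4"))
        assert synergy_ratio(c, one).synergy


class TestCompareTemplates:
    def test_identical_samples(self):
        result = compare_templates([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert result.fold_change == 1.0
        assert result.p_value == pytest.approx(1.0)

    def test_exact_doubling_zero_variance(self):
        result = compare_templates([1.0, 1.0], [2.0, 2.0])
        assert result.fold_change == 2.0

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(InputError):
            compare_templates([1.0], [2.0, 2.0])

    def test_196_vs_193_fold_at_least_two_in_most_seeds(self):
        """Simulated triplicates recover the ~two-fold 196/193 difference."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            tab = generate_activity_dataset(
                designs=[TEMPLATE_CATALOG["193"], TEMPLATE_CATALOG["196"]],
                noise=NoiseSpec(cv=0.10, n_replicates=3, seed=seed),
            )
            df = normalize(tab)
            result = compare_templates(
                df[df["template_id"] == "193"]["activity"],
                df[df["template_id"] == "196"]["activity"],
            )
            hits += result.fold_change >= 2.0
        assert hits >= 0.95 * n_seeds


class TestTitration:
    def test_generator_dominance_at_all_doses(self):
        tab = generate_activity_dataset(
            designs=[TEMPLATE_CATALOG["142"], TEMPLATE_CATALOG["145"]],
            doses=[0.25, 0.5, 1.0, 2.0, 4.0],
            noise=NoiseSpec(cv=0.10, n_replicates=3, seed=5),
        )
        summary = titration_summary(tab, dominant_template="145", other_template="142")
        assert summary.dominant_at_all_doses

    def test_identical_templates_not_dominant(self):
        rows = []
        for dose in (1.0, 2.0):
            for t in ("a", "b"):
                rows.append(
                    {"template_id": t, "dose": dose, "replicate": 1,
                     "firefly": 100.0, "renilla": 10.0}
                )
        assert not titration_summary(table(rows), "a", "b").dominant_at_all_doses

    def test_single_dose_rejected(self):
        rows = [
            {"template_id": t, "dose": 1.0, "replicate": 1, "firefly": 100.0,
             "renilla": 10.0}
            for t in ("a", "b")
        ]
        with pytest.raises(InputError):
            titration_summary(table(rows), "a", "b")


class TestScalingInvariance:
    def test_firefly_rescaling_changes_no_conclusion(self):
        tab = generate_activity_dataset(
            spacers=range(0, 49, 2), noise=NoiseSpec(cv=0.05, seed=9)
        )
        scaled_rows = tab.rows.copy()
        scaled_rows["firefly"] *= 37.5
        base = curve_from_table(tab)
        scaled = curve_from_table(ActivityTable(rows=scaled_rows))
        assert detect_peaks(base) == detect_peaks(scaled)
        f1 = fit_periodic_attenuation(base)
        f2 = fit_periodic_attenuation(scaled)
        assert f1.period == pytest.approx(f2.period, abs=1e-6)
        assert np.allclose(scaled.mean, 37.5 * base.mean, rtol=1e-12)
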