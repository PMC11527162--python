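import numpy as np
import pandas as pd
import pytest

import mutscan as ms


class TestCountsToRate:
    def test_worked_conversion(self):
        # 19.5 Ci/mmol x 2.22e12 dpm/Ci = 4.329e13 dpm/mmol = 43290 dpm/pmol
        rate = ms.counts_to_rate(43290.0, time_min=1.0, spores=1e8)
        assert rate == pytest.approx(1e-12, rel=1e-12)

    def test_zero_counts_zero_rate(self):
        assert ms.counts_to_rate(0.0) == 0.0

    @pytest.mark.parametrize("cpm", [10.0, 1234.5, 9e5])
    def test_linear_in_cpm_inverse_in_efficiency(self, cpm):
        base = ms.counts_to_rate(cpm)
        assert ms.counts_to_rate(2 * cpm) == pytest.approx(2 * base)
        assert ms.counts_to_rate(cpm, counting_efficiency=0.5) == pytest.approx(
            2 * base
        )

    def test_round_trip_with_inverse(self):
        for rate in (1e-13, 3.7e-12, 5e-11):
            cpm = ms.rate_to_counts(rate, time_min=2.0, spores=5e7)
            back = ms.counts_to_rate(cpm, time_min=2.0, spores=5e7)
            assert back == pytest.approx(rate, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms.counts_to_rate(10.0, specific_activity=0)
        with pytest.raises(ValueError):
            ms.counts_to_rate(10.0, counting_efficiency=1.5)


def rate_table(rows):
    df = pd.DataFrame(
        rows, columns=["strain", "labelled_conc_uM", "competitor",
                       "competitor_conc_uM", "rate"]
    )
    return df


class TestBackgroundCorrection:
    def test_subtraction_and_self_zero(self):
        df = rate_table(
            [
                ("wt", 0.2, "none", 0.0, 5.0),
                ("mut", 0.2, "none", 0.0, 1.0),
                ("null", 0.2, "none", 0.0, 2.0),
            ]
        )
        out = ms.correct_background(df, "null")
        by = out.set_index("strain")
        assert by.loc["wt", "rate_corrected"] == pytest.approx(3.0)
        assert by.loc["null", "rate_corrected"] == pytest.approx(0.0)
        # negatives retained and flagged, not clamped
        assert by.loc["mut", "rate_corrected"] == pytest.approx(-1.0)
        assert bool(by.loc["mut", "negative_flag"])

    def test_background_matched_per_condition(self):
        df = rate_table(
            [
                ("wt", 0.2, "none", 0.0, 5.0),
                ("wt", 0.2, "hx", 1000.0, 2.0),
                ("null", 0.2, "none", 0.0, 1.0),
                ("null", 0.2, "hx", 1000.0, 0.5),
            ]
        )
        out = ms.correct_background(df, "null").set_index(
            ["strain", "competitor"]
        )
        assert out.loc[("wt", "hx"), "rate_corrected"] == pytest.approx(1.5)

    def test_missing_background_condition(self):
        df = rate_table(
            [
                ("wt", 0.2, "hx", 1000.0, 2.0),
                ("null", 0.2, "none", 0.0, 1.0),
            ]
        )
        with pytest.raises(ValueError, match="condition"):
            ms.correct_background(df, "null")

    def test_absent_background_strain(self):
        with pytest.raises(ValueError, match="background"):
            ms.correct_background(
                rate_table([("wt", 0.2, "none", 0.0, 5.0)]), "null"
            )


class TestNormalizeRates:
    def rates(self, scale=1.0):
        rows = []
        for strain, vals in [
            ("PhZwt", [0.9, 1.0, 1.1]),
            ("fast", [1.5, 1.55, 1.6]),
            ("dead", [0.0, 0.0, 0.0]),
        ]:
            rows += [
                {"strain": strain, "rate_corrected": v * scale} for v in vals
            ]
        return pd.DataFrame(rows)

    def test_reference_is_exactly_100(self):
        v = ms.normalize_rates(self.rates()).set_index("strain")
        assert v.loc["PhZwt", "v_percent"] == pytest.approx(100.0)

    def test_relative_rates(self):
        v = ms.normalize_rates(self.rates()).set_index("strain")
        assert v.loc["fast", "v_percent"] == pytest.approx(155.0)
        assert v.loc["dead", "v_percent"] == pytest.approx(0.0)

    def test_scale_invariance(self):
        a = ms.normalize_rates(self.rates(1.0)).set_index("strain")
        b = ms.normalize_rates(self.rates(7.3e-13)).set_index("strain")
        for s in a.index:
            assert a.loc[s, "v_percent"] == pytest.approx(
                b.loc[s, "v_percent"]
            )
            assert a.loc[s, "v_sd"] == pytest.approx(b.loc[s, "v_sd"])

    def test_nonpositive_reference_rejected(self):
        df = pd.DataFrame(
            {"strain": ["PhZwt", "PhZwt"], "rate_corrected": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="non-positive"):
            ms.normalize_rates(df)


GRID = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)


def exact_curve(top=100.0, bottom=0.0, ic50=10.0, hill=-1.0, n_zero=3):
    pts = [(0.0, top)] * n_zero
    for x in GRID:
        y = bottom + (top - bottom) / (1 + 10 ** ((np.log10(ic50) - np.log10(x)) * hill))
        pts.append((x, y))
    return pts


class TestDoseResponseFit:
    @pytest.mark.parametrize(
        "true",
        [
            {"top": 100.0, "bottom": 0.0, "ic50": 10.0, "hill": -1.0},
            {"top": 80.0, "bottom": 5.0, "ic50": 2.5, "hill": -1.3},
            {"top": 1.2e-12, "bottom": 0.0, "ic50": 5.2, "hill": -1.0},
        ],
    )
    def test_exact_model_recovery(self, true):
        """Noise-free model data: all four parameters to <= 1e-4 relative."""
        fit = ms.fit_dose_response(exact_curve(**true))
        assert fit.converged
        assert fit.ic50 == pytest.approx(true["ic50"], rel=1e-4)
        assert fit.hill == pytest.approx(true["hill"], rel=1e-4)
        assert fit.top == pytest.approx(true["top"], rel=1e-4)
        assert fit.bottom == pytest.approx(true["bottom"], abs=1e-4 * true["top"])

    def test_flat_data_not_converged(self):
        pts = [(0.0, 5.0)] + [(x, 5.0) for x in GRID]
        fit = ms.fit_dose_response(pts)
        assert not fit.converged and fit.ki is None

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            ms.fit_dose_response([(0.0, 10.0), (1.0, 8.0), (10.0, 5.0), (100.0, 2.0)])

    def test_hill_near_minus_one_on_noisy_triplicates(self):
        """Simulated homologous competition at 10% CV keeps the fitted Hill
        coefficient within +/-0.15 of -1 (single binding site)."""
        cfg = ms.UptakeConfig(strains={"PhZwt": 1.0}, noise_cv=0.1, seed=42)
        df, _ = ms.generate_uptake(cfg)
        corr = ms.correct_background(ms.rates_from_counts(df), "ΔZAC")
        wt = corr[corr.strain == "PhZwt"]
        fit = ms.fit_dose_response(
            list(zip(wt.competitor_conc_uM, wt.rate_corrected))
        )
        assert fit.converged
        assert abs(fit.hill - (-1.0)) <= 0.15

    def test_ic50_recovery_rate_over_simulations(self):
        """IC50 within +/-15% of truth in >= 90% of 200 seeded simulations
        at 10% CV with n=6 per level."""
        ok = 0
        for seed in range(200):
            cfg = ms.UptakeConfig(strains={"PhZwt": 1.0}, noise_cv=0.1, seed=seed)
            df, truth = ms.generate_uptake(cfg)
            corr = ms.correct_background(ms.rates_from_counts(df), "ΔZAC")
            wt = corr[corr.strain == "PhZwt"]
            fit = ms.fit_dose_response(
                list(zip(wt.competitor_conc_uM, wt.rate_corrected))
            )
            true_ic50 = truth.ic50_uM["hypoxanthine"]
            if fit.converged and abs(fit.ic50 - true_ic50) / true_ic50 <= 0.15:
                ok += 1
        assert ok >= 180


class TestChengPrusoff:
    def test_zero_substrate_identity(self):
        ki, approx = ms.ic50_to_ki(10.0, 0.0, 2.0)
        assert ki == pytest.approx(10.0) and not approx

    def test_direct_formula(self):
        ki, _ = ms.ic50_to_ki(10.0, 0.2, 2.0)
        assert ki == pytest.approx(10.0 / 1.1)

    def test_bound_in_tracer_regime(self):
        """[S] <= Km/10 keeps |Ki - IC50|/IC50 <= 1/11 (closed form)."""
        for km in (1.0, 2.0, 5.0, 10.0):
            for frac in (0.01, 0.05, 0.1):
                S = km * frac
                ki, _ = ms.ic50_to_ki(7.0, S, km)
                assert abs(ki - 7.0) / 7.0 <= 1 / 11 + 1e-12

    def test_unknown_km_flags_approximation(self):
        ki, approx = ms.ic50_to_ki(7.0, 0.2, None)
        assert ki == 7.0 and approx

    def test_invalid_km(self):
        with pytest.raises(ValueError):
            ms.ic50_to_ki(7.0, 0.2, -1.0)


class TestCompetitionProfile:
    def profiles(self, km=5.0):
        cfg = ms.UptakeConfig(
            strains={"PhZwt": 1.0},
            km_uM=km,
            competitors={"hypoxanthine": km, "inert": None},
            competitor_grid_uM=(1000.0,),
            noise_cv=0.0,
            seed=0,
        )
        df, _ = ms.generate_uptake(cfg)
        corr = ms.correct_background(ms.rates_from_counts(df), "ΔZAC")
        # the null strain has no transport left after correction
        return ms.competition_profile(corr[corr.strain != "ΔZAC"])

    @pytest.mark.parametrize("km", [2.0, 5.0, 10.0])
    def test_self_competition_near_total(self, km):
        """1 mM unlabelled substrate vs 0.2 µM tracer with Km in the
        10-50x window inhibits >= 95% (single-site model)."""
        p = [x for x in self.profiles(km) if x.strain == "PhZwt"][0]
        assert p.percent_inhibition("hypoxanthine") >= 95.0

    def test_non_substrate_no_inhibition(self):
        p = [x for x in self.profiles() if x.strain == "PhZwt"][0]
        assert p.percent_inhibition("inert") == pytest.approx(0.0, abs=1e-9)

    def test_missing_baseline_rejected(self):
        df = pd.DataFrame(
            {
                "strain": ["wt"],
                "competitor": ["hx"],
                "rate_corrected": [1.0],
            }
        )
        with pytest.raises(ValueError, match="baseline"):
            ms.competition_profile(df)
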