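import numpy as np
import pandas as pd
import pytest

import mutscan as ms
from mutscan.synthetic import PlantedMotif


class TestFamilyGenerator:
    def test_reported_composition(self, paper_family):
        fam, _ = paper_family
        assert len(fam) == 155
        sizes = {g: sum(1 for r in fam.records if r.group == g)
                 for g in fam.groups_present()}
        assert sizes == {
            "known": 11, "prokaryote": 29, "plant": 35,
            "ascomycete": 54, "basidiomycete": 26,
        }

    def test_seed_determinism(self):
        cfg = ms.paper_family_config(seed=7)
        fam1, t1 = ms.generate_family(cfg)
        fam2, t2 = ms.generate_family(ms.paper_family_config(seed=7))
        assert [r.aligned_seq for r in fam1.records] == [
            r.aligned_seq for r in fam2.records
        ]
        assert t1.invariant_columns == t2.invariant_columns

    def test_different_seeds_differ(self):
        fam1, _ = ms.generate_family(ms.paper_family_config(seed=1))
        fam2, _ = ms.generate_family(ms.paper_family_config(seed=2))
        assert any(
            a.aligned_seq != b.aligned_seq
            for a, b in zip(fam1.records, fam2.records)
        )

    def test_thirty_five_invariants_planted(self, paper_family):
        _, truth = paper_family
        assert len(truth.invariant_columns) == 35

    def test_planted_columns_gap_free_single_residue(self, paper_family):
        fam, truth = paper_family
        for col in truth.invariant_columns:
            chars = {r.aligned_seq[col - 1] for r in fam.records}
            assert len(chars) == 1 and "-" not in chars

    def test_motif_columns_respect_constraint_sets(self, paper_family):
        fam, truth = paper_family
        cfg = ms.paper_family_config(seed=20)
        for m in cfg.planted_motifs:
            for off, pset in enumerate(m.position_sets):
                if pset is None:
                    continue
                col = m.column_start + off
                chars = {r.aligned_seq[col - 1] for r in fam.records}
                assert chars <= set(pset)

    def test_non_planted_columns_have_two_residues(self, paper_family):
        fam, truth = paper_family
        planted = set(truth.invariant_columns)
        prof = ms.compute_profile(fam)
        for col in range(1, fam.n_columns + 1):
            if col not in planted:
                assert prof[col].n_distinct >= 2

    def test_overlapping_planted_features_rejected(self):
        cfg = ms.FamilyConfig(
            group_sizes={"other": 3},
            n_columns=30,
            planted_invariant_columns=[5],
            planted_motifs=[PlantedMotif("m", 4, ["AG", "CT", "AG"])],
            seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            ms.generate_family(cfg)


class TestUptakeGenerator:
    def test_seed_determinism(self):
        cfg = ms.UptakeConfig(strains={"wt": 1.0}, seed=5)
        df1, _ = ms.generate_uptake(cfg)
        df2, _ = ms.generate_uptake(ms.UptakeConfig(strains={"wt": 1.0}, seed=5))
        pd.testing.assert_frame_equal(df1, df2)

    def test_noiseless_round_trip(self):
        """At zero noise, cpm -> rate returns the model values exactly
        (background included)."""
        cfg = ms.UptakeConfig(strains={"wt": 1.0}, noise_cv=0.0, seed=0)
        df, truth = ms.generate_uptake(cfg)
        rates = ms.rates_from_counts(df)
        base = rates[(rates.strain == "wt") & (rates.competitor == "none")]
        expect = truth.v0["wt"] + truth.background_rate
        assert np.allclose(base["rate"], expect, rtol=1e-12)

    def test_competition_follows_single_site_model(self):
        cfg = ms.UptakeConfig(strains={"wt": 1.0}, noise_cv=0.0, seed=0)
        df, truth = ms.generate_uptake(cfg)
        rates = ms.rates_from_counts(df)
        ic50 = truth.ic50_uM["hypoxanthine"]
        assert ic50 == pytest.approx(cfg.km_uM + cfg.labelled_conc_uM)
        for conc in cfg.competitor_grid_uM:
            sub = rates[
                (rates.strain == "wt") & (rates.competitor_conc_uM == conc)
            ]
            expect = truth.v0["wt"] / (1 + conc / ic50) + truth.background_rate
            assert np.allclose(sub["rate"], expect, rtol=1e-12)

    def test_replicate_layout(self):
        cfg = ms.UptakeConfig(
            strains={"wt": 1.0}, replicates=3, experiments=2, seed=0
        )
        df, _ = ms.generate_uptake(cfg)
        base = df[(df.strain == "wt") & (df.competitor == "none")]
        assert len(base) == 6  # triplicates x two experiments
        assert set(base.replicate) == {"r1", "r2", "r3"}
        assert set(base.experiment) == {"e1", "e2"}

    def test_noise_scale_matches_cv(self):
        cfg = ms.UptakeConfig(
            strains={"wt": 1.0}, competitors={}, replicates=400,
            experiments=1, noise_cv=0.1, seed=8,
        )
        df, truth = ms.generate_uptake(cfg)
        base = df[(df.strain == "wt") & (df.competitor == "none")]["cpm"]
        assert base.std() / base.mean() == pytest.approx(0.1, rel=0.25)
        expect = ms.rate_to_counts(truth.v0["wt"] + truth.background_rate)
        assert base.mean() == pytest.approx(expect, rel=0.02)

    def test_table_profile_recovers_v_percent(self):
        """Simulated at the summary table's relative rates, the V%
        pipeline lands within noise of the configured percentages."""
        cfg = ms.UptakeConfig(
            strains=ms.table1_rate_profile(), competitors={},
            noise_cv=0.1, seed=17,
        )
        df, _ = ms.generate_uptake(cfg)
        corr = ms.correct_background(ms.rates_from_counts(df), "ΔZAC")
        v = ms.normalize_rates(corr).set_index("strain")
        assert v.loc["PhZwt", "v_percent"] == pytest.approx(100.0)
        for strain, rel in ms.table1_rate_profile().items():
            assert v.loc[strain, "v_percent"] == pytest.approx(
                100 * rel, abs=max(0.2 * 100 * rel, 3.0)
            )

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            ms.generate_uptake(
                ms.UptakeConfig(strains={"wt": 1.0}, replicates=0, seed=0)
            )


class TestFixtures:
    def test_table_fixture_shape(self, table1):
        assert len(table1) == 16
        assert sum(s.is_control for s in table1) == 3
        wild = [s for s in table1 if s.strain == "PhZwt"][0]
        assert wild.v_percent == 100.0 and wild.v_sd == 17.0

    def test_fig3_groups(self):
        assert set(ms.FIG3_GROUP_MEMBERS.values()) == set(ms.FIG3_GROUPS)
        assert len(ms.FIG3_GROUPS) == 4

    def test_family_config_sums_to_155(self):
        cfg = ms.paper_family_config()
        assert sum(cfg.group_sizes.values()) == 155
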