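"""Ground-truth generators: arrays, fragments, domains, reporters, counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from nucspacing.core import GenomicInterval
from nucspacing import synthetic as syn


class TestDyadPositions:
    def test_zero_noise_arithmetic(self):
        spec = syn.ArraySpec(GenomicInterval("c", 100, 1100), nrl=200)
        dyads = syn.simulate_dyad_positions(spec, seed=0)
        assert dyads.tolist() == [100, 300, 500, 700, 900]

    def test_mean_spacing_matches_planted_nrl(self):
        spec = syn.ArraySpec(
            GenomicInterval("c", 0, 1_900_000), nrl=190, jitter_sd=5
        )
        dyads = syn.simulate_dyad_positions(spec, seed=1)
        assert len(dyads) == 10_000
        spacing = np.diff(dyads).mean()
        assert spacing == pytest.approx(190, abs=0.5)

    def test_interval_shorter_than_repeat_is_rejected(self):
        spec = syn.ArraySpec(GenomicInterval("c", 0, 150), nrl=200)
        with pytest.raises(ValueError, match="interval too short"):
            syn.simulate_dyad_positions(spec, seed=0)

    def test_occupancy_thins_the_array(self):
        spec = syn.ArraySpec(
            GenomicInterval("c", 0, 2_000_000), nrl=200, occupancy=0.5
        )
        dyads = syn.simulate_dyad_positions(spec, seed=2)
        assert 4500 < len(dyads) < 5500

    def test_positions_stay_inside_interval_and_sorted(self):
        spec = syn.ArraySpec(
            GenomicInterval("c", 500, 5000), nrl=180, jitter_sd=40
        )
        dyads = syn.simulate_dyad_positions(spec, seed=3)
        assert dyads.min() >= 500 and dyads.max() < 5000
        assert np.all(np.diff(dyads) >= 0)

    def test_seed_reproducibility(self):
        spec = syn.ArraySpec(
            GenomicInterval("c", 0, 100_000), nrl=188.4, jitter_sd=10,
            occupancy=0.8,
        )
        a = syn.simulate_dyad_positions(spec, seed=9)
        b = syn.simulate_dyad_positions(spec, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_spec_fields_rejected(self):
        iv = GenomicInterval("c", 0, 10_000)
        with pytest.raises(ValueError):
            syn.ArraySpec(iv, nrl=140)
        with pytest.raises(ValueError):
            syn.ArraySpec(iv, nrl=190, jitter_sd=-1)
        with pytest.raises(ValueError):
            syn.ArraySpec(iv, nrl=190, occupancy=1.5)


class TestFragments:
    def test_fixed_length_midpoint_arithmetic(self):
        model = syn.FragmentLengthModel(mean=150, sd=0, min=100, max=220)
        frags = syn.simulate_fragments(np.array([1000]), model, depth=1,
                                       seed=0)
        assert frags.iloc[0][["start", "end"]].tolist() == [925, 1075]

    def test_centers_equal_source_dyads(self):
        model = syn.FragmentLengthModel(mean=165, sd=20, min=121, max=199)
        dyads = np.arange(1000, 20_000, 188)
        frags = syn.simulate_fragments(dyads, model, depth=3, seed=1)
        centers = (frags["start"] + frags["end"]) // 2
        assert set(centers) <= set(dyads)
        assert len(frags) == 3 * len(dyads)

    def test_truncated_normal_moment(self):
        model = syn.FragmentLengthModel(mean=150, sd=15, min=100, max=220)
        frags = syn.simulate_fragments(np.array([10_000]), model,
                                       depth=100_000, seed=2)
        lengths = frags["end"] - frags["start"]
        a, b = (100 - 150) / 15, (220 - 150) / 15
        expected = truncnorm.mean(a, b, loc=150, scale=15)
        assert lengths.mean() == pytest.approx(expected, abs=1.0)
        assert lengths.min() >= 100 and lengths.max() <= 220

    def test_zero_depth_rejected(self):
        model = syn.FragmentLengthModel()
        with pytest.raises(ValueError, match="depth"):
            syn.simulate_fragments(np.array([1000]), model, depth=0, seed=0)

    def test_empty_dyads_give_empty_set(self):
        model = syn.FragmentLengthModel()
        frags = syn.simulate_fragments(np.array([], dtype=int), model,
                                       depth=5, seed=0)
        assert len(frags) == 0

    def test_invalid_length_model_rejected(self):
        with pytest.raises(ValueError):
            syn.FragmentLengthModel(mean=150, sd=10, min=200, max=100)


class TestDomainAnnotation:
    def test_single_state_covers_chromosome(self):
        domains = syn.simulate_domain_annotation(
            {"c": 100_000}, {"BLACK": 1.0}, mean_domain_len=10_000, seed=0
        )
        assert len(domains) == 1
        assert domains.iloc[0].tolist() == ["c", 0, 100_000, "BLACK"]

    def test_gray_fills_residual_fraction(self):
        domains = syn.simulate_domain_annotation(
            {"c": 10_000_000},
            {"BLACK": 0.4, "BLUE": 0.2, "YELLOW": 0.2},
            mean_domain_len=100_000, seed=1,
        )
        lengths = (domains["end"] - domains["start"]).groupby(
            domains["state"]).sum()
        assert lengths["GRAY"] == pytest.approx(2_000_000, rel=0.1)

    def test_fraction_recovery_at_scale(self):
        fractions = {"BLACK": 0.4, "BLUE": 0.2, "YELLOW": 0.2}
        domains = syn.simulate_domain_annotation(
            {"c": 10_000_000}, fractions, mean_domain_len=100_000, seed=2
        )
        lengths = (domains["end"] - domains["start"]).groupby(
            domains["state"]).sum()
        for state, frac in fractions.items():
            assert lengths[state] == pytest.approx(
                frac * 10_000_000, rel=0.1)

    def test_tiling_is_complete_and_disjoint(self):
        domains = syn.simulate_domain_annotation(
            {"c": 1_000_000, "d": 500_000},
            {"BLACK": 0.5, "YELLOW": 0.3}, mean_domain_len=50_000, seed=3,
        )
        for chrom, size in (("c", 1_000_000), ("d", 500_000)):
            grp = domains[domains["chrom"] == chrom]
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == size
            assert (grp["start"].iloc[1:].to_numpy()
                    == grp["end"].iloc[:-1].to_numpy()).all()

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            syn.simulate_domain_annotation(
                {"c": 1000}, {"BLACK": 0.7, "BLUE": 0.7}, 100, seed=0
            )


class TestReporterLibrary:
    def test_zero_effects_give_zero_medians(self):
        from nucspacing import tethering as trip

        model = syn.ReporterEffectModel(
            effects={s: 0.0 for s in syn.REPORTER_STATE_EFFECTS},
            expression_slope=0.0,
        )
        df = syn.simulate_reporter_library(n=3000, effects=model, seed=4)
        kept = trip.filter_reporters(trip.normalize_reporter_counts(df))
        fc = trip.reporter_log2fc(kept, "tethered", "control")
        med = trip.median_fc_by_state(fc, kept["state"])
        # the rare GREEN/GRAY states hold only tens of reporters here,
        # so their medians carry most of the sampling noise
        assert np.abs(med["median"]).max() < 0.1

    def test_planted_black_effect_recovered(self):
        from nucspacing import tethering as trip

        effects = dict(syn.REPORTER_STATE_EFFECTS, BLACK=-1.8)
        model = syn.ReporterEffectModel(effects=effects)
        df = syn.simulate_reporter_library(n=5000, effects=model, seed=5)
        kept = trip.filter_reporters(trip.normalize_reporter_counts(df))
        fc = trip.reporter_log2fc(kept, "tethered", "control")
        med = trip.median_fc_by_state(fc, kept["state"])
        assert med.loc["BLACK", "median"] == pytest.approx(-1.8, abs=0.1)

    def test_zero_fraction_plants_filterable_reporters(self):
        df = syn.simulate_reporter_library(n=1000, seed=6,
                                           zero_fraction=0.1)
        zeroed = df.groupby("barcode")["cdna_count"].min() == 0
        assert zeroed.sum() >= 100

    def test_default_library_size_and_composition(self):
        df = syn.simulate_reporter_library(seed=7)
        assert df["barcode"].nunique() == 492
        states = df.groupby("barcode")["state"].first()
        # BLACK is the plurality state in the library
        assert states.value_counts().idxmax() == "BLACK"

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            syn.simulate_reporter_library(
                n=10, state_proportions={"BLACK": 0.5, "BLUE": 0.2}, seed=0
            )

    def test_seed_reproducibility(self):
        a = syn.simulate_reporter_library(n=200, seed=8)
        b = syn.simulate_reporter_library(n=200, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestExpressionCounts:
    def test_counts_are_nonnegative_integers_with_metadata(self):
        sim = syn.simulate_expression_counts(n_genes=500, seed=9)
        assert (sim.counts.to_numpy() >= 0).all()
        assert np.issubdtype(sim.counts.to_numpy().dtype, np.integer)
        assert sim.counts.shape == (500, 12)
        assert set(sim.meta["genotype"]) == {"wt", "mutant"}
        assert (sim.meta.groupby("genotype").size() == 6).all()

    def test_null_effects_give_zero_median_fold_change(self):
        from nucspacing import stratification as st

        sim = syn.simulate_expression_counts(
            n_genes=2000, derepression={}, seed=10
        )
        counts = st.filter_genes_by_zero_counts(sim.counts)
        fc = st.log2fc_by_genotype(
            st.normalize_counts(counts), sim.meta, "post-ZGA"
        )
        assert fc["log2fc"].median() == pytest.approx(0, abs=0.05)

    def test_planted_low_expression_derepression_recovered(self):
        from nucspacing import stratification as st

        sim = syn.simulate_expression_counts(
            n_genes=5000, derepression={"BLACK": 0.5}, seed=11
        )
        counts = st.filter_genes_by_zero_counts(sim.counts)
        fc = st.log2fc_by_genotype(
            st.normalize_counts(counts), sim.meta, "post-ZGA"
        )
        info = sim.gene_info.loc[fc.index]
        affected = (info["state"] == "BLACK") & info["low_expression"]
        assert fc.loc[affected, "log2fc"].median() == pytest.approx(
            0.5, abs=0.1)

    def test_non_positive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            syn.simulate_expression_counts(n_genes=10, dispersion=0, seed=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            syn.simulate_expression_counts(n_genes=10, n_replicates=1,
                                           seed=0)

    def test_seed_reproducibility(self):
        a = syn.simulate_expression_counts(n_genes=100, seed=12)
        b = syn.simulate_expression_counts(n_genes=100, seed=12)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.gene_info, b.gene_info)
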