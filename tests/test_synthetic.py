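"""Synthetic-data generators: determinism, planted truth, calibration."""

import numpy as np
import pandas as pd
import pytest

from chemnet import io, synthetic
from chemnet.screen import call_hits
from chemnet.synthetic import (GeneSetTruth, NetworkTruth, ScreenTruth,
                               gen_genesets, gen_growth_screen, gen_interactome,
                               gen_microscopy_table, gen_screen_scores,
                               logistic_od, planted_partition_truth)


class TestGrowthScreen:
    def test_noise_free_curves_match_logistic_closed_form(self):
        truth = ScreenTruth(("a", "b"), {}, noise_sd=0.0, replicates=2, seed=3)
        times = np.arange(0, 10, 1.0)
        df = gen_growth_screen(truth, times, r=0.4, carrying_k=2.0, od0=0.05)
        expected = logistic_od(times, 0.4, 2.0, 0.05)
        for (_, _, _), g in df.groupby(["strain", "condition", "replicate"]):
            np.testing.assert_allclose(g["od600"].to_numpy(), expected, rtol=1e-12)

    def test_planted_sensitive_strains_end_below_control(self):
        strains = tuple(f"s{i:02d}" for i in range(50))
        truth = ScreenTruth(strains, {s: 0.5 for s in strains[:5]},
                            noise_sd=0.0, replicates=1)
        df = gen_growth_screen(truth, np.arange(0, 12, 1.0))
        final = df[df["time_h"] == df["time_h"].max()]
        treated = final[final["condition"] == "treated"].set_index("strain")["od600"]
        vehicle = final[final["condition"] == "vehicle"].set_index("strain")["od600"]
        below = set(treated.index[treated < vehicle - 1e-12])
        assert below == set(strains[:5])

    def test_same_seed_gives_identical_tables(self):
        truth = ScreenTruth(("a", "b", "c"), {"a": 0.5}, seed=7)
        t = np.arange(0, 8, 1.0)
        pd.testing.assert_frame_equal(gen_growth_screen(truth, t),
                                      gen_growth_screen(truth, t))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ScreenTruth((), {})
        with pytest.raises(ValueError):
            ScreenTruth(("a",), {"b": 0.5})  # planted id not among strains
        with pytest.raises(ValueError):
            ScreenTruth(("a",), {"a": -1.0})
        truth = ScreenTruth(("a",), {})
        with pytest.raises(ValueError):
            gen_growth_screen(truth, [0, 1, 2], r=-0.1)
        with pytest.raises(ValueError):
            gen_growth_screen(truth, [2, 1, 0])

    def test_adding_a_strain_does_not_reshuffle_existing_draws(self):
        t = np.arange(0, 6, 1.0)
        small = gen_growth_screen(ScreenTruth(("a", "b"), {}, seed=1), t)
        big = gen_growth_screen(ScreenTruth(("a", "b", "c"), {}, seed=1), t)
        a_small = small[small["strain"] == "a"].reset_index(drop=True)
        a_big = big[big["strain"] == "a"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a_small, a_big)


class TestScreenScores:
    def test_true_score_is_100_times_multiplier(self):
        truth = ScreenTruth(("neutral", "sens", "res"),
                            {"sens": 0.5, "res": 1.5}, noise_sd=0.0)
        df = gen_screen_scores(truth, n_screens=2)
        means = df.groupby("strain")["score"].mean()
        assert means["neutral"] == pytest.approx(100)
        assert means["sens"] == pytest.approx(50)
        assert means["res"] == pytest.approx(150)

    def test_null_hit_calling_is_calibrated(self):
        """With no planted effects, p<0.05 calls occur at 5% +/- 2%."""
        strains = tuple(f"s{i:02d}" for i in range(50))
        called = total = 0
        for seed in range(200):
            truth = ScreenTruth(strains, {}, noise_sd=0.05, replicates=3, seed=seed)
            scores = gen_screen_scores(truth, n_screens=1)
            calls = call_hits(scores, stage="validation",
                              use_effect_thresholds=False, alpha=0.05)
            called += (calls["call"] != "none").sum()
            total += len(calls)
        assert abs(called / total - 0.05) < 0.02


class TestInteractome:
    def test_zero_edge_probability_gives_no_edges(self):
        edges, _ = gen_interactome(20, "erdos_renyi", edge_p=0.0, seed=0)
        assert len(edges) == 0

    def test_planted_partition_truth_records_blocks(self):
        truth = planted_partition_truth(4, 25, p_in=0.3, p_out=0.02, seed=1)
        edges, tdict = gen_interactome(100, "planted_partition", truth=truth, seed=1)
        assert tdict["blocks"] == dict(truth.blocks)
        nodes = set(edges["protein1"]) | set(edges["protein2"])
        assert nodes <= set(truth.blocks)
        # no duplicates and no self-loops
        pairs = list(zip(edges["protein1"], edges["protein2"]))
        assert len(pairs) == len({tuple(sorted(p)) for p in pairs})
        assert all(a != b for a, b in pairs)

    def test_scores_within_string_like_ranges(self):
        edges, _ = gen_interactome(40, "erdos_renyi", edge_p=0.2, seed=2)
        assert edges["combined_score"].between(150, 1000).all()
        assert edges["experimental"].between(0, 1000).all()

    def test_seeds_vary_edges_but_preserve_marginal_edge_count(self):
        """Edge counts across seeds stay within 3 s.d. of the binomial mean."""
        n, p = 30, 0.1
        n_pairs = n * (n - 1) // 2
        tables = [gen_interactome(n, "erdos_renyi", edge_p=p, seed=s)[0]
                  for s in range(30)]
        counts = [len(t) for t in tables]
        edge_sets = [set(zip(t["protein1"], t["protein2"])) for t in tables[:2]]
        assert edge_sets[0] != edge_sets[1]
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(np.mean(counts) - n_pairs * p) < 3 * sd / np.sqrt(len(counts))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            gen_interactome(10, "small_world")

    def test_invalid_block_probabilities_rejected(self):
        with pytest.raises(ValueError):
            NetworkTruth({"a": 0}, p_in=0.1, p_out=0.2)


class TestGeneSets:
    def test_full_overlap_set_equals_query(self):
        truth = GeneSetTruth(universe_size=100, n_sets=1, set_size=5,
                             n_planted=1, planted_fraction=1.0, seed=0)
        collection, universe, query, tdict = gen_genesets(truth, query=None)
        # query drawn from universe; planted set of size 5 with fraction 1.0
        planted = collection[tdict["planted_enriched"][0]]
        assert planted <= set(query)
        assert len(planted) == 5

    def test_gmt_round_trip(self, tmp_path):
        truth = GeneSetTruth(universe_size=200, n_sets=10, seed=3)
        collection, *_ = gen_genesets(truth)
        path = tmp_path / "sets.gmt"
        io.write_gmt(collection, path)
        assert io.read_gmt(path) == collection

    def test_set_size_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            GeneSetTruth(universe_size=5, set_size=10)


class TestMicroscopyTable:
    def test_planted_shifts_listed_in_truth(self):
        shifts = {"s000": 50.0, "s005": 50.0, "s017": -40.0}
        cells, truth = gen_microscopy_table(30, 50, abundance_shifts=shifts, seed=1)
        assert truth["abundance_shifts"] == shifts

    def test_zero_shift_measured_change_stays_under_flag_threshold(self):
        """Analytic s.e. of a log-normal median at n=200, sd=0.1 is ~1%,
        so an unshifted strain's measured change sits far below 20%."""
        cells, _ = gen_microscopy_table(5, 200, noise_sd=0.1, seed=2)
        from chemnet.microscopy import abundance_change
        for strain, g in cells.groupby("strain"):
            call = abundance_change(g[g["condition"] == "control"],
                                    g[g["condition"] == "treated"], strain=strain)
            assert abs(call.pct_change) < 20
            assert not call.flagged

    def test_identical_seed_identical_table(self):
        a, _ = gen_microscopy_table(3, 20, seed=9)
        b, _ = gen_microscopy_table(3, 20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_total_knockdown_rejected(self):
        with pytest.raises(ValueError):
            gen_microscopy_table(3, 20, abundance_shifts={"s000": -100.0})

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            gen_microscopy_table(3, 5)
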