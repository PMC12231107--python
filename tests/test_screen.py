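"""Plate normalization, epistasis scoring, chemical-genomic hit calling."""

import numpy as np
import pandas as pd
import pytest

from chemnet.phenotype import GrowthRecord
from chemnet.screen import (EpistasisInputs, call_hits, chemgen_score,
                            epistasis_score, normalize_plate)
from chemnet.synthetic import ScreenTruth, gen_screen_scores, logistic_od


class TestNormalizePlate:
    def test_uniform_plate_maps_to_ones(self):
        out = normalize_plate(np.full((8, 12), 100.0))
        np.testing.assert_allclose(out, 1.0)

    def test_row_artefact_flattened(self):
        plate = np.full((8, 12), 100.0)
        plate[3, :] *= 2
        out = normalize_plate(plate)
        row_medians = np.median(out[1:-1, 1:-1], axis=1)
        np.testing.assert_allclose(row_medians, row_medians[0], atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        plate = rng.lognormal(4, 0.3, size=(8, 12))
        once = normalize_plate(plate)
        twice = normalize_plate(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_planted_small_colonies_are_bottom_k_after_gradient_removal(self):
        rng = np.random.default_rng(11)
        rows, cols = 8, 12
        row_gain = np.linspace(0.6, 1.4, rows)[:, None]
        col_gain = np.linspace(0.7, 1.3, cols)[None, :]
        plate = 100.0 * row_gain * col_gain * rng.lognormal(0, 0.02, (rows, cols))
        planted = [(2, 3), (4, 7), (6, 10)]
        for r, c in planted:
            plate[r, c] *= 0.5
        out = normalize_plate(plate)
        # ranking over interior positions: border cells receive only the
        # coarse border/interior rescale, not per-row/column polishing
        interior = out[1:-1, 1:-1]
        order = np.dstack(np.unravel_index(np.argsort(interior, axis=None),
                                           interior.shape))[0]
        bottom = {(r + 1, c + 1) for r, c in order[:len(planted)]}
        assert bottom == set(planted)

    def test_missing_positions_preserved_and_all_missing_rejected(self):
        plate = np.full((6, 6), 50.0)
        plate[0, 0] = np.nan
        out = normalize_plate(plate)
        assert np.isnan(out[0, 0]) and np.isfinite(out[1:, 1:]).all()
        with pytest.raises(ValueError):
            normalize_plate(np.full((6, 6), np.nan))

    def test_mostly_missing_plate_rejected(self):
        plate = np.full((6, 6), np.nan)
        plate[:2, :] = 50.0
        with pytest.raises(ValueError):
            normalize_plate(plate)


class TestEpistasis:
    def test_multiplicative_neutrality_scores_100(self):
        e = EpistasisInputs(g_double=0.32, g_query=0.8, g_array=0.4, g_wt=1.0)
        assert epistasis_score(e) == pytest.approx(100.0)

    def test_dead_double_scores_zero(self):
        e = EpistasisInputs(0.0, 0.8, 0.4, 1.0)
        assert epistasis_score(e) == 0.0

    def test_reference_double_forced_to_exactly_100(self):
        ref = EpistasisInputs(g_double=0.7, g_query=0.8, g_array=0.95, g_wt=1.0)
        assert epistasis_score(ref, reference=ref) == pytest.approx(100.0)

    def test_reference_rescaling_is_multiplicative(self):
        ref = EpistasisInputs(0.7, 0.8, 0.95, 1.0)
        e = EpistasisInputs(0.3, 0.8, 0.9, 1.0)
        raw_ref = epistasis_score(ref)
        assert epistasis_score(e, reference=ref) == pytest.approx(
            epistasis_score(e) * 100.0 / raw_ref)

    def test_planted_score_recovered_within_3_se(self):
        rng = np.random.default_rng(21)
        noise = 0.05
        scores = []
        for _ in range(3):  # replicates
            e = EpistasisInputs(
                g_double=0.5 * 0.32 * rng.lognormal(0, noise),
                g_query=0.8 * rng.lognormal(0, noise),
                g_array=0.4 * rng.lognormal(0, noise),
                g_wt=1.0 * rng.lognormal(0, noise))
            scores.append(epistasis_score(e))
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores) - 50.0) < 3 * max(se, 2.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            EpistasisInputs(0.3, 0.0, 0.4, 1.0)
        with pytest.raises(ValueError):
            EpistasisInputs(-0.1, 0.8, 0.4, 1.0)


def _records(strains, conditions=("vehicle", "treated"), multipliers=None,
             replicates=2, times=None):
    times = times if times is not None else tuple(np.arange(0, 15, 1.0))
    recs = []
    for s in strains:
        m = (multipliers or {}).get(s, 1.0)
        for cond in conditions:
            rate = 0.5 * (m if cond == "treated" else 1.0)
            od = tuple(logistic_od(np.asarray(times), rate, 2.0, 0.05))
            for rep in range(1, replicates + 1):
                recs.append(GrowthRecord(s, cond, rep, times, od))
    return recs


class TestChemgenScore:
    def test_treated_equals_vehicle_scores_100(self):
        table, unscored = chemgen_score(_records(["a", "b"]))
        assert unscored == []
        assert table["score"].tolist() == pytest.approx([100.0, 100.0])

    def test_planted_multiplier_matches_logistic_closed_form(self):
        times = np.arange(0, 15, 1.0)
        table, _ = chemgen_score(_records(["a"], multipliers={"a": 0.5}))
        control = logistic_od(times, 0.5, 2.0, 0.05)
        idx = int(np.nonzero((control >= 0.3) & (control <= 0.5))[0][0])
        expected = logistic_od(times[idx], 0.25, 2.0, 0.05) / control[idx] * 100
        assert table.loc[0, "score"] == pytest.approx(expected, rel=1e-9)

    def test_strain_missing_vehicle_reported_unscored(self):
        recs = _records(["a"]) + _records(["b"], conditions=("treated",))
        table, unscored = chemgen_score(recs)
        assert unscored == ["b"]
        assert table["strain"].tolist() == ["a"]


class TestCallHits:
    def make_scores(self, seed=11, n_strains=50, n_sens=5, n_res=5,
                    noise=0.05, n_screens=3):
        strains = tuple(f"s{i:02d}" for i in range(n_strains))
        mult = {s: 0.5 for s in strains[:n_sens]}
        mult.update({s: 1.5 for s in strains[n_sens:n_sens + n_res]})
        truth = ScreenTruth(strains, mult, noise_sd=noise, replicates=3, seed=seed)
        return gen_screen_scores(truth, n_screens=n_screens), truth

    def test_zero_variance_neutral_scores_make_no_calls(self):
        scores = pd.DataFrame({
            "strain": ["a"] * 3, "screen": [1] * 3,
            "replicate": [1, 2, 3], "score": [100.0] * 3})
        calls = call_hits(scores, stage="validation")
        assert calls["call"].tolist() == ["none"]

    def test_planted_screen_perfect_precision_and_recall(self):
        scores, truth = self.make_scores(seed=11)
        calls = call_hits(scores, stage="screen", thresholds=(75, 130),
                          alpha=0.05, min_screens=2)
        sens = set(calls.loc[calls["call"] == "sensitive", "strain"])
        res = set(calls.loc[calls["call"] == "resistant", "strain"])
        assert sens == truth.sensitive
        assert res == truth.resistant

    def test_single_screen_support_is_not_called(self):
        rows = []
        for screen_i in (1, 2, 3):
            score = 60.0 if screen_i == 1 else 100.0
            for rep, eps in enumerate((-1.0, 0.0, 1.0), start=1):
                rows.append(("s1", screen_i, rep, score + eps))
        scores = pd.DataFrame(rows, columns=["strain", "screen", "replicate", "score"])
        calls = call_hits(scores, stage="screen", thresholds=(75, 130),
                          min_screens=2)
        assert calls["call"].tolist() == ["none"]
        assert calls["screens_supporting"].tolist() == [1]

    def test_permutation_invariance_to_strain_order(self):
        scores, _ = self.make_scores(seed=5)
        shuffled = scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = call_hits(scores, stage="screen")
        b = call_hits(shuffled, stage="screen")
        pd.testing.assert_frame_equal(a, b)

    def test_inviable_strains_reported_separately(self):
        scores = pd.DataFrame({
            "strain": ["dead"] * 3 + ["ok"] * 3, "screen": [1] * 6,
            "replicate": [1, 2, 3] * 2,
            "score": [50.0, 51.0, 49.0, 100.0, 101.0, 99.0]})
        vehicle = pd.DataFrame({
            "strain": ["dead"] * 3 + ["ok"] * 3, "screen": [1] * 6,
            "replicate": [1, 2, 3] * 2,
            "score": [5.0, 6.0, 4.0, 100.0, 101.0, 99.0]})
        calls = call_hits(scores, stage="validation", vehicle_scores=vehicle)
        assert calls.set_index("strain")["call"]["dead"] == "inviable"
        assert calls.set_index("strain")["call"]["ok"] == "none"

    def test_bad_thresholds_rejected(self):
        scores, _ = self.make_scores(seed=1, n_strains=2, n_sens=0, n_res=0)
        with pytest.raises(ValueError):
            call_hits(scores, thresholds=(130, 75))
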