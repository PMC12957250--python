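import numpy as np
import pandas as pd
import pytest

import matscore as m


def wells_from(scores_by_tf, condition="T3", controls=(), replicate=1):
    rows = [{"tf_id": tf, "condition": condition, "replicate": replicate,
             "maturation_score": s, "rfp_percent": 0.0, "is_control": False}
            for tf, s in scores_by_tf.items()]
    rows += [{"tf_id": f"ctl{i}", "condition": condition, "replicate": 1,
              "maturation_score": s, "rfp_percent": 0.0, "is_control": True}
             for i, s in enumerate(controls)]
    return pd.DataFrame(rows)


def both_conditions(scores_t3, scores_no_t3):
    return pd.concat([wells_from(scores_t3, "T3"),
                      wells_from(scores_no_t3, "no_T3")], ignore_index=True)


class TestCallHits:
    def test_single_outlier_is_only_hit(self):
        scores = {f"tf{i}": 50.0 for i in range(9)}
        scores["star"] = 60.0
        # mean 51; the outlier clears mean + SD under either SD convention
        hits = m.call_hits(both_conditions(scores, scores))
        hit_set = set(hits.loc[hits.category == "both_conditions", "tf_id"])
        assert hit_set == {"star"}
        assert (hits.loc[hits.tf_id != "star", "category"] == "none").all()

    def test_identical_metrics_zero_hits(self):
        scores = {f"tf{i}": 50.0 for i in range(5)}
        hits = m.call_hits(both_conditions(scores, scores))
        assert (hits.category == "none").all()  # SD 0, strict > excludes all

    def test_one_condition_category(self):
        base = {f"tf{i}": 50.0 + (i % 3) for i in range(9)}
        t3 = dict(base, star=70.0)
        no_t3 = dict(base, star=50.0)
        hits = m.call_hits(both_conditions(t3, no_t3)).set_index("tf_id")
        assert hits.loc["star", "category"] == "one_condition"
        assert hits.loc["star", "exceeds_T3"]
        assert not hits.loc["star", "exceeds_no_T3"]

    def test_controls_excluded_from_threshold(self):
        scores = {f"tf{i}": 50.0 for i in range(9)}
        scores["star"] = 60.0
        table = pd.concat(
            [wells_from(scores, "T3", controls=[200.0, 220.0, 240.0]),
             wells_from(scores, "no_T3", controls=[200.0, 220.0, 240.0])],
            ignore_index=True)
        hits = m.call_hits(table).set_index("tf_id")
        assert hits.loc["star", "category"] == "both_conditions"

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        scores = {f"tf{i}": float(v)
                  for i, v in enumerate(rng.normal(50, 3, size=12))}
        shifted = {k: v + 17.5 for k, v in scores.items()}
        h1 = m.call_hits(both_conditions(scores, scores))
        h2 = m.call_hits(both_conditions(shifted, shifted))
        pd.testing.assert_frame_equal(h1, h2)
        t1 = h1.attrs["thresholds"]
        t2 = h2.attrs["thresholds"]
        for cond in t1:
            assert t2[cond] - t1[cond] == pytest.approx(17.5)

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError, match="no_T3"):
            m.call_hits(wells_from({"a": 1.0, "b": 2.0, "c": 3.0}))

    def test_rfp_channel_uses_reporter_column(self):
        table = both_conditions({f"tf{i}": 50.0 for i in range(5)},
                                {f"tf{i}": 50.0 for i in range(5)})
        table.loc[table.tf_id == "tf0", "rfp_percent"] = 40.0
        hits = m.call_hits(table, channel="rfp").set_index("tf_id")
        assert hits.loc["tf0", "category"] == "both_conditions"


class TestConfirmHits:
    def _replicates(self, tf_scores, control_scores):
        rows = [{"tf_id": "TFX", "condition": "T3", "replicate": i + 1,
                 "maturation_score": s, "rfp_percent": 0.0,
                 "is_control": False} for i, s in enumerate(tf_scores)]
        rows += [{"tf_id": f"ctl{i}", "condition": "T3", "replicate": 1,
                  "maturation_score": s, "rfp_percent": 0.0,
                  "is_control": True} for i, s in enumerate(control_scores)]
        return pd.DataFrame(rows)

    def test_exact_p_for_separated_triples(self):
        out = m.confirm_hits(self._replicates([56, 57, 58], [49, 50, 51]))
        assert out.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)
        assert not out.loc[0, "significant_05"]

    def test_identical_replicates_p_one(self):
        out = m.confirm_hits(self._replicates([50, 51, 52], [50, 51, 52]))
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_two_replicates_give_na(self):
        with pytest.warns(UserWarning, match="no statistics"):
            out = m.confirm_hits(self._replicates([56, 57], [49, 50, 51]))
        assert np.isnan(out.loc[0, "p_value"])

    def test_monotone_transform_invariance(self):
        a = self._replicates([56, 57, 58, 59], [49, 50, 51, 52])
        b = a.copy()
        b["maturation_score"] = np.exp(b["maturation_score"] / 10)
        pa = m.confirm_hits(a).loc[0, "p_value"]
        pb = m.confirm_hits(b).loc[0, "p_value"]
        assert pa == pytest.approx(pb, abs=1e-12)

    def test_significance_reached_with_pooled_controls(self):
        out = m.confirm_hits(self._replicates(
            [60, 61, 62], [49, 50, 51, 52, 48, 50.5, 49.5]))
        assert out.loc[0, "p_value"] < 0.05
        assert out.loc[0, "significant_05"]


class TestMarkerFlags:
    def _matrix(self, gene_tpm_by_sample):
        df = pd.DataFrame(gene_tpm_by_sample)
        return m.ExpressionMatrix(df, "tpm")

    def _run(self, treated, control):
        mat = self._matrix({**{f"t{i}": [v] for i, v in enumerate(treated)},
                            **{f"c{i}": [v] for i, v in enumerate(control)}})
        mat.values.index = ["Ckmt2"]
        groups = {**{f"t{i}": "TF" for i in range(len(treated))},
                  **{f"c{i}": "control" for i in range(len(control))}}
        return m.marker_flags(mat, groups, "control")

    def test_fold_change_and_p_both_pass(self):
        out = self._run([21.0, 22.0, 20.0, 21.5], [10.0, 10.2, 9.8, 10.1])
        assert out.loc[0, "flagged"] and out.loc[0, "direction"] == "up"
        assert out.loc[0, "fold_change"] > 2.0

    def test_small_fold_change_not_flagged(self):
        out = self._run([15.0, 15.2, 14.8, 15.1], [10.0, 10.2, 9.8, 10.1])
        assert out.loc[0, "p_value"] < 0.05
        assert not out.loc[0, "flagged"]  # 1.5-fold fails the FC arm

    def test_high_p_not_flagged(self):
        out = self._run([30.0, 2.0, 40.0, 1.0], [10.0, 11.0, 9.0, 10.5])
        assert out.loc[0, "fold_change"] > 1.5
        assert not out.loc[0, "flagged"]  # fails the p arm

    def test_downregulation_flagged(self):
        out = self._run([4.0, 4.1, 3.9, 4.05], [10.0, 10.2, 9.8, 10.1])
        assert out.loc[0, "flagged"] and out.loc[0, "direction"] == "down"

    def test_zero_control_mean_gives_na(self):
        with pytest.warns(UserWarning, match="fold change undefined"):
            out = self._run([5.0, 5.1, 4.9], [0.0, 0.0, 0.0])
        assert np.isnan(out.loc[0, "fold_change"])
        assert not out.loc[0, "flagged"]

    def test_log_input_backtransformed(self):
        tpm = self._matrix({"t0": [21.0], "t1": [22.0], "t2": [20.0],
                            "c0": [10.0], "c1": [10.2], "c2": [9.8]})
        tpm.values.index = ["Mb"]
        log = m.log_transform(tpm)
        groups = {"t0": "TF", "t1": "TF", "t2": "TF",
                  "c0": "control", "c1": "control", "c2": "control"}
        out = m.marker_flags(log, groups, "control")
        assert out.loc[0, "fold_change"] == pytest.approx(21.0 / 10.0, rel=1e-9)


class TestScreenSimulator:
    def test_same_seed_reproducible(self):
        a = m.simulate_screen(planted=["TF005"], effect_sizes=[1.5], seed=3)
        b = m.simulate_screen(planted=["TF005"], effect_sizes=[1.5], seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_extreme_effect_always_both_conditions(self):
        for seed in range(5):
            wells = m.simulate_screen(planted=["TF010"], effect_sizes=[10.0],
                                      seed=seed)
            hits = m.call_hits(wells).set_index("tf_id")
            assert hits.loc["TF010", "category"] == "both_conditions"

    def test_planted_must_exist(self):
        with pytest.raises(ValueError, match="not in the screen"):
            m.simulate_screen(planted=["TF999"], effect_sizes=[1.0])

    def test_effect_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            m.simulate_screen(planted=["TF001"], effect_sizes=[1.0, 2.0])

    def test_null_hit_rate_matches_gaussian_tail(self):
        """With no planted effects the per-condition exceedance frequency
        sits at the self-normalized Gaussian tail P(X > x̄ + s) ≈ 0.159."""
        exceed = total = 0
        for seed in range(50):
            wells = m.simulate_screen(seed=seed)
            tf_wells = wells[~wells.is_control]
            for cond in ("T3", "no_T3"):
                v = tf_wells.loc[tf_wells.condition == cond,
                                 "maturation_score"].to_numpy()
                thr = v.mean() + v.std(ddof=1)
                exceed += (v > thr).sum()
                total += len(v)
        assert abs(exceed / total - 0.1587) < 0.03

    def test_planted_recovery_under_default_conditions(self):
        planted = [f"TF{i:03d}" for i in (3, 17, 40, 66, 90)]
        good = 0
        fps = []
        for seed in range(20):
            wells = m.simulate_screen(planted=planted,
                                      effect_sizes=[1.5] * 5, seed=seed)
            hits = m.call_hits(wells)
            both = set(hits.loc[hits.category == "both_conditions", "tf_id"])
            good += len(both & set(planted)) >= 4
            fps.append(len(both - set(planted)))
        assert good >= 16          # >= 80% of seeds recover >= 4/5
        assert np.mean(fps) <= 2.0
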