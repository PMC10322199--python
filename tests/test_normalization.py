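import numpy as np
import pandas as pd
import pytest

import swevowel as sv
from swevowel.errors import ConfigError, DegenerateStatsError, FitError, SwevowelError

from conftest import make_dataset


def two_token_talker(f1_values, f0_values=(200.0, 200.0), f2_values=None, talker="T1"):
    f2_values = f2_values or tuple(10 * v for v in f1_values)
    rows = [
        {"talker": talker, "token_id": f"t{i}", "F1": f1, "F2": f2, "F3": 2 * f2, "F0": f0}
        for i, (f1, f2, f0) in enumerate(zip(f1_values, f2_values, f0_values))
    ]
    return make_dataset(rows)


class TestFitTalkerStats:
    def test_log_mean_and_mean(self):
        data = two_token_talker((100.0, 1000.0))
        stats = sv.fit_talker_stats(data, cues=("F1",))
        assert stats.get("T1", "F1", "log_mean") == pytest.approx((np.log(100) + np.log(1000)) / 2, abs=1e-10)
        assert stats.get("T1", "F1", "log_mean") == pytest.approx(5.75646, abs=1e-5)
        assert stats.get("T1", "F1", "mean") == pytest.approx(550.0)

    def test_constant_cue_degenerate_spread(self):
        data = two_token_talker((500.0, 500.0))
        stats = sv.fit_talker_stats(data, cues=("F1",))
        assert stats.get("T1", "F1", "sd") == 0.0
        assert stats.get("T1", "F1", "min") == stats.get("T1", "F1", "max") == 500.0

    def test_geometric_mean_f0(self):
        data = two_token_talker((300.0, 400.0), f0_values=(100.0, 400.0))
        stats = sv.fit_talker_stats(data, cues=("F0",))
        assert stats.gm_f0["T1"] == pytest.approx(200.0, rel=1e-12)

    def test_single_token_talker_rejected(self):
        data = make_dataset([{"talker": "T1"}])
        with pytest.raises(FitError, match="fewer than 2"):
            sv.fit_talker_stats(data, cues=("F1",))

    def test_pooled_across_categories(self):
        rows = [
            {"talker": "T1", "vowel": "hid", "token_id": "a", "F1": 300.0},
            {"talker": "T1", "vowel": "had", "token_id": "b", "F1": 700.0},
        ]
        stats = sv.fit_talker_stats(make_dataset(rows), cues=("F1",))
        assert stats.get("T1", "F1", "mean") == pytest.approx(500.0)


class TestCCuRE:
    def test_token_at_training_mean_maps_to_zero(self):
        train = two_token_talker((400.0, 600.0))
        stats = sv.fit_talker_stats(train, cues=("F1", "F2", "duration"))
        out = sv.apply_ccure(two_token_talker((500.0, 500.0)), stats)
        assert np.allclose(out.df["F1"], 0.0)

    def test_simple_subtraction(self):
        train = two_token_talker((400.0, 600.0))
        stats = sv.fit_talker_stats(train, cues=("F1",))
        out = sv.apply_ccure(two_token_talker((600.0, 600.0)), stats, cues=("F1",), include_duration=False)
        assert np.allclose(out.df["F1"], 100.0)

    def test_bark_variant_composes_transform_then_center(self, small_synth):
        data, _ = small_synth
        cues = ("F1", "F2")
        model = sv.fit_normalization(data, "CCuRE-Bark", cues)
        auto = sv.normalize(data, model)
        bark = sv.transform_dataset(data, sv.Scale("Bark"), cues=cues)
        stats = sv.fit_talker_stats(bark, cues=cues)
        manual = sv.apply_ccure(bark, stats, cues=cues, include_duration=False)
        assert np.allclose(auto.df["F1"], manual.df["F1"], atol=1e-12)
        assert np.allclose(auto.df["F2"], manual.df["F2"], atol=1e-12)

    def test_unseen_talker_is_an_error_not_a_refit(self):
        stats = sv.fit_talker_stats(two_token_talker((400.0, 600.0)), cues=("F1",))
        other = two_token_talker((400.0, 600.0), talker="T9")
        with pytest.raises(SwevowelError, match="T9"):
            sv.apply_ccure(other, stats, cues=("F1",), include_duration=False)


class TestNearey:
    def test_nearey1_hand_value(self):
        train = two_token_talker((100.0, 1000.0))
        stats = sv.fit_talker_stats(train, cues=("F1",))
        out = sv.apply_nearey1(two_token_talker((100.0, 100.0)), stats, cues=("F1",))
        assert np.allclose(out.df["F1"], np.log(100) - 5.756462732485114, atol=1e-9)
        assert out.df["F1"].iloc[0] == pytest.approx(-1.15129, abs=1e-5)

    def test_nearey1_zero_at_geometric_mean(self):
        train = two_token_talker((100.0, 1000.0))
        stats = sv.fit_talker_stats(train, cues=("F1",))
        gm = float(np.sqrt(100 * 1000))
        out = sv.apply_nearey1(two_token_talker((gm, gm)), stats, cues=("F1",))
        assert np.allclose(out.df["F1"], 0.0, atol=1e-12)

    def test_nearey2_grand_log_mean_symmetry(self):
        train = two_token_talker((500.0, 500.0), f2_values=(1500.0, 1500.0))
        stats = sv.fit_talker_stats(train, cues=("F1", "F2"), nearey2_formants=("F1", "F2"))
        assert stats.grand_log_mean["T1"] == pytest.approx((np.log(500) + np.log(1500)) / 2, abs=1e-12)
        assert stats.grand_log_mean["T1"] == pytest.approx(6.76391, abs=1e-5)
        out = sv.apply_nearey2(train, stats)
        assert out.df["F1"].iloc[0] == pytest.approx(-np.log(3) / 2, abs=1e-12)
        assert out.df["F2"].iloc[0] == pytest.approx(+np.log(3) / 2, abs=1e-12)

    def test_nearey2_zero_vector_at_grand_mean(self):
        train = two_token_talker((500.0, 500.0), f2_values=(1500.0, 1500.0))
        stats = sv.fit_talker_stats(train, cues=("F1", "F2"))
        g = float(np.exp(stats.grand_log_mean["T1"]))
        probe = two_token_talker((g, g), f2_values=(g, g))
        out = sv.apply_nearey2(probe, stats)
        assert np.allclose(out.df[["F1", "F2"]], 0.0, atol=1e-12)

    @pytest.mark.parametrize("account", ["Nearey1", "Nearey2"])
    def test_multiplicative_talker_invariance_with_refit(self, small_synth, account):
        data, _ = small_synth
        cues = ("F1", "F2", "F3")
        scale_by = {t: 1.0 + 0.2 * i for i, t in enumerate(data.talkers)}
        df = data.df.copy()
        factor = df["talker"].map(scale_by)
        for cue in cues:
            df[cue] = df[cue] * factor
        perturbed = data.with_frame(df)
        out_a = sv.normalize(data, sv.fit_normalization(data, account, cues))
        out_b = sv.normalize(perturbed, sv.fit_normalization(perturbed, account, cues))
        assert np.allclose(out_a.df[list(cues)], out_b.df[list(cues)], atol=1e-10)


class TestGerstman:
    def fitted(self):
        train = two_token_talker((400.0, 600.0))
        return train, sv.fit_talker_stats(train, cues=("F1",))

    def test_range_endpoints_and_midpoint(self):
        train, stats = self.fitted()
        out = sv.apply_gerstman(
            two_token_talker((400.0, 600.0), f2_values=(4000.0, 6000.0)), stats, cues=("F1",)
        )
        assert out.df["F1"].tolist() == [0.0, 999.0]
        mid = sv.apply_gerstman(two_token_talker((500.0, 500.0)), stats, cues=("F1",))
        assert np.allclose(mid.df["F1"], 499.5)

    def test_out_of_range_values_pass_through_unclipped(self):
        _, stats = self.fitted()
        out = sv.apply_gerstman(two_token_talker((700.0, 700.0)), stats, cues=("F1",))
        assert np.allclose(out.df["F1"], 999.0 * (700 - 400) / 200)

    def test_degenerate_range_names_talker_and_cue(self):
        stats = sv.fit_talker_stats(two_token_talker((500.0, 500.0)), cues=("F1",))
        with pytest.raises(DegenerateStatsError, match="F1.*T1"):
            sv.apply_gerstman(two_token_talker((500.0, 500.0)), stats, cues=("F1",))


class TestLobanov:
    def test_training_triple_maps_to_unit_z_scores(self):
        rows = [{"talker": "T1", "token_id": f"t{i}", "F1": v} for i, v in enumerate((1.0, 2.0, 3.0))]
        # bypass formant-order constraints by keeping other cues fixed and valid
        train = make_dataset([{**r, "F2": 2000.0, "F3": 3000.0} for r in rows])
        stats = sv.fit_talker_stats(train, cues=("F1",))
        out = sv.apply_lobanov(train, stats, cues=("F1",))
        assert np.allclose(out.df["F1"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_maps_to_zero(self):
        train = two_token_talker((400.0, 600.0))
        stats = sv.fit_talker_stats(train, cues=("F1",))
        out = sv.apply_lobanov(two_token_talker((500.0, 500.0)), stats, cues=("F1",))
        assert np.allclose(out.df["F1"], 0.0)

    def test_zero_variance_is_an_error(self):
        stats = sv.fit_talker_stats(two_token_talker((500.0, 500.0)), cues=("F1",))
        with pytest.raises(DegenerateStatsError):
            sv.apply_lobanov(two_token_talker((500.0, 500.0)), stats, cues=("F1",))

    def test_affine_talker_invariance_with_refit(self, small_synth):
        data, _ = small_synth
        cues = ("F1", "F2")
        df = data.df.copy()
        a = df["talker"].map({t: 1.0 + 0.1 * i for i, t in enumerate(data.talkers)})
        b = df["talker"].map({t: 50.0 * i for i, t in enumerate(data.talkers)})
        for cue in cues:
            df[cue] = a * df[cue] + b
        perturbed = data.with_frame(df)
        out_a = sv.normalize(data, sv.fit_normalization(data, "Lobanov", cues))
        out_b = sv.normalize(perturbed, sv.fit_normalization(perturbed, "Lobanov", cues))
        assert np.allclose(out_a.df[list(cues)], out_b.df[list(cues)], atol=1e-10)


class TestSyrdalGopal:
    def test_self_difference_is_zero(self):
        data = make_dataset([{"F0": 300.0, "F1": 300.0, "F2": 2000.0}])
        out = sv.apply_syrdal_gopal(data)
        assert out.df["F1"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_bark_differences(self):
        data = make_dataset([{"F0": 200.0, "F1": 500.0, "F2": 1500.0}])
        out = sv.apply_syrdal_gopal(data)
        b = sv.hz_to_bark
        assert out.df["F1"].iloc[0] == pytest.approx(b(500) - b(200), abs=1e-12)
        assert out.df["F2"].iloc[0] == pytest.approx(b(1500) - b(500), abs=1e-12)
        assert out.df["F1"].iloc[0] == pytest.approx(2.9668, abs=1e-4)
        assert out.df["F2"].iloc[0] == pytest.approx(6.1736, abs=1e-4)

    def test_f0_column_required(self):
        data = make_dataset([{}])
        broken = data.with_frame(data.df.drop(columns=["F0"]))
        with pytest.raises(ConfigError, match="F0"):
            sv.apply_syrdal_gopal(broken)


class TestMiller:
    def fitted(self, f0=(216.0, 216.0)):
        train = two_token_talker((400.0, 600.0), f0_values=f0)
        return sv.fit_talker_stats(train, cues=("F0",))

    def test_sr_fixed_point(self):
        stats = self.fitted(f0=(168.0, 168.0))
        data = make_dataset([{"F1": 168.0, "F2": 1000.0, "F3": 2000.0}])
        out = sv.apply_miller(data, stats)
        assert out.df["F1"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_formants_give_zero_ratio_dimension(self):
        stats = self.fitted()
        data = make_dataset([{"F1": 500.0, "F2": 500.00000001, "F3": 2000.0}])
        out = sv.apply_miller(data, stats)
        assert out.df["F2"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_sensory_reference_value(self):
        stats = self.fitted(f0=(216.0, 216.0))
        sr = 168.0 * (216.0 / 168.0) ** (1.0 / 3.0)
        data = make_dataset([{"F1": sr, "F2": 1000.0, "F3": 2000.0}])
        out = sv.apply_miller(data, stats)
        assert out.df["F1"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert sr == pytest.approx(182.68, abs=0.01)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigError):
            sv.apply_miller(make_dataset([{}]), self.fitted(), k=0.0)

    def test_coupled_multiplicative_invariance_with_refit(self, small_synth):
        """Miller's cube-root reference compensates exactly when formants
        scale by c and F0 by c**3 (the account's stated physiological
        coupling); the canonical three ratio dimensions are then invariant."""
        data, _ = small_synth
        cues = ("F1", "F2", "F3")
        c = {t: 1.0 + 0.1 * i for i, t in enumerate(data.talkers)}
        df = data.df.copy()
        factor = df["talker"].map(c)
        for cue in cues:
            df[cue] = df[cue] * factor
        df["F0"] = df["F0"] * factor**3
        perturbed = data.with_frame(df)
        out_a = sv.normalize(data, sv.fit_normalization(data, "Miller", cues))
        out_b = sv.normalize(perturbed, sv.fit_normalization(perturbed, "Miller", cues))
        assert np.allclose(out_a.df[list(cues)], out_b.df[list(cues)], atol=1e-10)


class TestNormalizeDispatch:
    def test_raw_hz_is_identity_on_cue_columns(self, small_synth):
        data, _ = small_synth
        model = sv.fit_normalization(data, "raw-Hz", ("F1", "F2"))
        out = sv.normalize(data, model)
        assert np.allclose(out.df[["F1", "F2"]], data.df[["F1", "F2"]])

    def test_roster_is_exactly_the_fifteen_accounts(self):
        assert len(sv.ACCOUNT_ROSTER) == 15
        assert set(sv.ACCOUNT_ROSTER) == {
            "raw-Hz", "Bark", "ERB", "Mel", "ST", "SyrdalGopal", "Miller",
            "CCuRE-Hz", "CCuRE-Bark", "CCuRE-ERB", "CCuRE-Mel",
            "Nearey1", "Nearey2", "Gerstman", "Lobanov",
        }

    def test_syrdal_gopal_restricted_to_f1_f2_comparison(self, small_synth):
        data, _ = small_synth
        with pytest.raises(ConfigError):
            sv.fit_normalization(data, "SyrdalGopal", ("F1", "F2", "F3"))

    @pytest.mark.parametrize("account", sv.ACCOUNT_ROSTER)
    def test_every_account_runs_on_every_compatible_cue_set(self, small_synth, account):
        data, _ = small_synth
        for cues in sv.CUE_SETS.values():
            try:
                sv.check_compatibility(account, cues)
            except ConfigError:
                continue
            model = sv.fit_normalization(data, account, cues)
            out = sv.normalize(data, model)
            assert len(out) == len(data)
            for cue in model.observer_cues:
                assert np.isfinite(out.df[cue]).all()

    @pytest.mark.parametrize("account", ["Lobanov", "CCuRE-Hz", "Nearey1"])
    def test_refit_on_self_centering_invariants(self, small_synth, account):
        data, _ = small_synth
        cues = ("F1", "F2", "F3")
        model = sv.fit_normalization(data, account, cues)
        out = sv.normalize(data, model)
        for cue in cues:
            per_talker = out.df.groupby("talker")[cue]
            assert np.all(np.abs(per_talker.mean()) < 1e-10)
            if account == "Lobanov":
                assert np.all(np.abs(per_talker.std(ddof=1) - 1.0) < 1e-10)

    def test_gerstman_training_span_is_exactly_0_to_999(self, small_synth):
        data, _ = small_synth
        model = sv.fit_normalization(data, "Gerstman", ("F1", "F2"))
        out = sv.normalize(data, model)
        for cue in ("F1", "F2"):
            per_talker = out.df.groupby("talker")[cue]
            assert np.allclose(per_talker.min(), 0.0, atol=1e-9)
            assert np.allclose(per_talker.max(), 999.0, atol=1e-9)

    def test_train_apply_separation(self, small_synth):
        """Perturbing held-out data must leave fitted parameters unchanged."""
        data, _ = small_synth
        folds = sv.make_folds(data, k=5, seed=3)
        train, test = folds.train_test(data, 1)
        model = sv.fit_normalization(train, "Lobanov", ("F1", "F2"))
        mutated = test.with_frame(test.df.assign(F1=test.df["F1"] * 3.0))
        model_after = sv.fit_normalization(train, "Lobanov", ("F1", "F2"))
        pd.testing.assert_frame_equal(model.stats.table, model_after.stats.table)
        out_ref = sv.normalize(test, model)
        out_mut = sv.normalize(mutated, model)
        assert np.allclose(out_mut.df["F2"], out_ref.df["F2"])
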