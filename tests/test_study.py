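import itertools
import json

import numpy as np
import pytest

from cardiodki.phantom import PhantomSpec, build_ground_truth, synthesize_series
from cardiodki.preprocessing import phase_correct_real
from cardiodki.study import (StudyConfig, bland_altman, one_dim_fit_curves,
                             run_dti_dki_subset_comparison, run_full_study,
                             snr_gain, wilcoxon_signed_rank)


class TestBlandAltman:
    def test_constant_difference(self):
        out = bland_altman([1.1, 2.1, 3.1], [1.0, 2.0, 3.0])
        assert out["mean_diff"] == pytest.approx(0.1)
        assert out["loa_high"] - out["loa_low"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_inputs(self):
        out = bland_altman([1.0, 2.0], [1.0, 2.0])
        assert out["mean_diff"] == 0.0

    def test_hand_computed_example(self):
        # differences {0.1, 0.2, 0.3}: mean 0.2, sample SD 0.1
        out = bland_altman([1.1, 2.2, 3.3], [1.0, 2.0, 3.0])
        assert out["mean_diff"] == pytest.approx(0.2)
        assert out["sd_diff"] == pytest.approx(0.1)
        assert out["loa_high"] == pytest.approx(0.2 + 1.96 * 0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


def wilcoxon_brute_force(d):
    """Independent oracle: enumerate all sign assignments of the ranked
    |differences| and count statistics at least as extreme (two-sided)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    import pandas as pd
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2.0 ** n


class TestWilcoxon:
    def test_ten_one_signed_differences_exact_p(self):
        out = wilcoxon_signed_rank(np.arange(1, 11, dtype=float))
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(2.0 / 2 ** 10, rel=1e-12)

    def test_symmetric_pairs_give_p_one(self):
        out = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert out["p"] == pytest.approx(1.0)

    def test_all_zero_differences(self):
        out = wilcoxon_signed_rank(np.zeros(10))
        assert out["p"] == 1.0

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.standard_normal(8), 3)
        d[d == 0] = 0.5
        out = wilcoxon_signed_rank(d)
        assert out["p"] == pytest.approx(wilcoxon_brute_force(d), rel=1e-9)

    def test_matches_scipy_exact_when_no_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(10)
        d = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(d)["p"]
        theirs = scipy_wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestSnrGain:
    def test_reported_echo_time_gain(self):
        assert snr_gain(61.0, 90.0, 46.0) == pytest.approx(1.88, abs=5e-3)

    def test_equal_echo_times_unity(self):
        assert snr_gain(75.0, 75.0, 46.0) == 1.0

    def test_longer_comparison_echo_time(self):
        assert snr_gain(61.0, 118.0, 46.0) == \
            pytest.approx(np.exp(57.0 / 46.0), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            snr_gain(-1.0, 90.0, 46.0)


class TestOneDimFits:
    BVALS = np.array([100.0, 450.0, 900.0, 1200.0, 1350.0])

    def signal(self, d, k, b=None):
        b = self.BVALS if b is None else b
        return np.exp(-b * d + b ** 2 * d ** 2 * k / 6.0)

    def test_zero_kurtosis_curves_coincide(self):
        out = one_dim_fit_curves(self.signal(1.66e-3, 0.0), self.BVALS)
        assert np.allclose(out["mono_curve"], out["dki_curve"], rtol=1e-10)

    def test_three_exact_points_recover_parameters(self):
        b = np.array([100.0, 900.0, 1350.0])
        out = one_dim_fit_curves(self.signal(1.66e-3, 0.32, b), b,
                                 mono_bmax=900.0)
        assert out["dki"]["d"] == pytest.approx(1.66e-3, rel=1e-10)
        assert out["dki"]["k"] == pytest.approx(0.32, rel=1e-10)

    def test_mono_fit_underpredicts_decay_deficit(self):
        d, k = 1.66e-3, 0.32
        s = self.signal(d, k)
        out = one_dim_fit_curves(s, self.BVALS)
        resid = np.log(s) - np.log(out["mono_curve"])
        # oracle: only b = 100 and 450 enter the mono fit, so the fitted line
        # is exactly the chord through those two log-signal points
        b1, b2 = 100.0, 450.0
        slope = (np.log(s[1]) - np.log(s[0])) / (b2 - b1)
        line_1350 = np.log(s[0]) + slope * (self.BVALS[-1] - b1)
        assert resid[-1] == pytest.approx(np.log(s[-1]) - line_1350, rel=1e-10)
        assert np.all(np.diff(resid[1:]) > 0)   # deficit grows beyond 450
        assert resid[-1] > 0                    # measured decays slower

    def test_too_few_low_bvals_rejected(self):
        with pytest.raises(ValueError):
            one_dim_fit_curves(self.signal(1.6e-3, 0.3), self.BVALS,
                               mono_bmax=50.0)


class TestSubsetComparison:
    def test_noiseless_dki_md_invariant_dti_md_decreasing(self,
                                                          noiseless_real):
        tab = run_dti_dki_subset_comparison(noiseless_real, n_dirs_mk=500)
        dki = tab[tab["model"] == "dki"].set_index("subset")
        dti = tab[tab["model"] == "dti"].set_index("subset")
        order = ["subset1", "subset2", "fullset"]
        dki_md = dki.loc[order, "md_mean_e3"].to_numpy()
        dti_md = dti.loc[order, "md_mean_e3"].to_numpy()
        assert np.ptp(dki_md) < 1e-6
        assert np.all(np.diff(dti_md) < 0)

    def test_noisy_dki_md_more_stable_than_dti_md(self, protocol):
        spec = PhantomSpec(seed=21)
        truth = build_ground_truth(spec)
        real = phase_correct_real(synthesize_series(truth, protocol, spec))
        tab = run_dti_dki_subset_comparison(real, n_dirs_mk=500)
        dki_md = tab[tab["model"] == "dki"]["md_mean_e3"].to_numpy()
        dti_md = tab[tab["model"] == "dti"]["md_mean_e3"].to_numpy()
        assert np.ptp(dki_md) < np.ptp(dti_md)

    def test_reduced_protocol_kurtosis_close_to_full(self, protocol):
        spec = PhantomSpec(seed=22)
        truth = build_ground_truth(spec)
        real = phase_correct_real(synthesize_series(truth, protocol, spec))
        tab = run_dti_dki_subset_comparison(real, n_dirs_mk=500)
        dki = tab[tab["model"] == "dki"].set_index("subset")
        for metric in ("mk_mean", "ak_mean", "rk_mean", "md_mean_e3"):
            scale = 1.0 if metric != "md_mean_e3" else 1.0
            assert abs(dki.loc["subset1", metric]
                       - dki.loc["fullset", metric]) <= 0.03 * scale


class TestFullStudy:
    def test_deterministic_report(self, tmp_path):
        cfg = StudyConfig(
            base_spec=PhantomSpec(grid_size=24, inner_radius_mm=7,
                                  outer_radius_mm=13),
            n_subjects=2, seed=5, noiseless=True, n_dirs_mk=500,
            directions_per_shell=15, repeats=2)
        a = run_full_study(cfg, outdir=tmp_path / "a")
        b = run_full_study(cfg, outdir=tmp_path / "b")
        assert a["subjects"].equals(b["subjects"])
        assert (tmp_path / "a" / "group_report.json").read_text() == \
               (tmp_path / "b" / "group_report.json").read_text()

    def test_noiseless_group_recovers_targets(self):
        cfg = StudyConfig(
            base_spec=PhantomSpec(grid_size=24, inner_radius_mm=7,
                                  outer_radius_mm=13),
            n_subjects=2, jitter_rel=0.0, seed=6, noiseless=True,
            n_dirs_mk=4000, directions_per_shell=15, repeats=2)
        rep = run_full_study(cfg)
        assert rep["group"]["mk_mean"]["mean"] == pytest.approx(0.32, abs=5e-3)
        assert rep["group"]["ak_mean"]["mean"] == pytest.approx(0.27, abs=5e-3)
        assert rep["group"]["rk_mean"]["mean"] == pytest.approx(0.35, abs=5e-3)
        assert rep["group"]["md_mean_e3"]["mean"] == pytest.approx(1.66,
                                                                   abs=5e-3)
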