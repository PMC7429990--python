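"""Shell averaging, S(0) extrapolation, dot fraction and high-b fits."""

import math

import numpy as np
import pandas as pd
import pytest

import stedot as st
from tests.conftest import noiseless_signals


def _shells_from_model(model, protocol):
    return st.shell_average(noiseless_signals(model, protocol), protocol)


class TestShellAverage:
    def test_identical_repeats_have_zero_std(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        assert len(shells) == 11
        assert np.all(shells["std"].to_numpy() < 1e-14)
        np.testing.assert_array_equal(shells["n"], st.STE_REPETITIONS)

    def test_b0_excluded_from_shell_list(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        assert np.all(shells["b"] > 0.0)

    def test_standard_error_follows_sqrt_n(self, single_te_protocol):
        # 36 repeats at the top shell: SE of the mean = sigma / 6
        sigma, reps = 0.01, 1000
        rng = np.random.default_rng(0)
        means = []
        top = single_te_protocol.b == 15.0
        base = np.zeros(len(single_te_protocol))
        for _ in range(reps):
            v = base + rng.normal(0.0, sigma, size=base.shape)
            means.append(v[top].mean())
        assert np.std(means) == pytest.approx(sigma / 6.0, rel=0.1)

    def test_length_mismatch_rejected(self, single_te_protocol):
        with pytest.raises(ValueError, match="does not match"):
            st.shell_average(np.zeros(5), single_te_protocol)


class TestS0Estimate:
    def test_monoexponential_recovered_exactly(self):
        d = 0.7
        shells = pd.DataFrame(
            {"b": [0.25, 1.5], "te": [88.0, 88.0],
             "mean": [math.exp(-0.25 * d), math.exp(-1.5 * d)]}
        )
        assert st.estimate_s0_lowb(shells) == pytest.approx(1.0, rel=1e-12)

    def test_printed_example(self):
        shells = pd.DataFrame(
            {"b": [0.25, 1.5], "te": [88.0, 88.0], "mean": [0.8, 0.3]}
        )
        want = math.exp(math.log(0.8) + 0.25 * (math.log(0.8) - math.log(0.3)) / 1.25)
        got = st.estimate_s0_lowb(shells)
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(0.9734, abs=5e-4)

    def test_csf_contamination_pulls_estimate_down(self, cgm_model):
        # adding a fast CSF pool makes ln S convex between the two lowest
        # shells, so the extrapolated S(0) under-shoots the true S(0)
        csf = st.TissueModel(
            (
                st.Compartment("ball", 0.097, d_par=0.12, d_perp=0.12),
                st.Compartment("ball", 0.703, d_par=1.0, d_perp=1.0),
                st.Compartment("ball", 0.2, d_par=3.0, d_perp=3.0),
            )
        )
        shells = pd.DataFrame(
            {
                "b": [0.25, 1.5],
                "te": [88.0, 88.0],
                "mean": [st.signal_ste_mixture(b, csf) for b in (0.25, 1.5)],
            }
        )
        assert st.estimate_s0_lowb(shells) < 1.0

    def test_nonpositive_mean_falls_back_with_warning(self):
        shells = pd.DataFrame(
            {"b": [0.25, 1.5], "te": [88.0, 88.0], "mean": [0.8, -0.1]}
        )
        with pytest.warns(UserWarning, match="lowest-shell"):
            assert st.estimate_s0_lowb(shells) == 0.8


class TestFdotUpperLimit:
    def test_definition(self):
        shells = pd.DataFrame({"b": [10.5, 15.0], "te": [88.0] * 2, "mean": [0.03, 0.018]})
        assert st.fdot_upper_limit(shells, 1.0) == pytest.approx(0.018)

    def test_pure_dot_is_exact_at_any_bmax(self, single_te_protocol):
        model = st.TissueModel(
            (st.Compartment("dot", 0.02), st.Compartment("ball", 0.98, d_par=1.0, d_perp=1.0))
        )
        shells = _shells_from_model(model, single_te_protocol)
        s0 = 1.0
        got = st.fdot_upper_limit(shells, s0)
        assert got == pytest.approx(0.02, abs=1e-6)

    def test_two_pool_value(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        got = st.fdot_upper_limit(shells, 1.0)
        assert got == pytest.approx(0.01603, abs=1e-4)

    def test_rejects_nonpositive_s0(self):
        shells = pd.DataFrame({"b": [15.0], "te": [88.0], "mean": [0.01]})
        with pytest.raises(ValueError, match="positive"):
            st.fdot_upper_limit(shells, 0.0)


class TestMonoexpFit:
    HIGH_B = np.array([10.5, 12.0, 13.5, 15.0])

    def _shells(self, a, d, extra_b=(0.25, 1.5)):
        b = np.concatenate([np.array(extra_b), self.HIGH_B])
        return pd.DataFrame(
            {"b": b, "te": np.full(b.size, 88.0), "mean": a * np.exp(-b * d)}
        )

    def test_exact_recovery_on_noiseless_monoexponential(self):
        shells = self._shells(0.097, 0.12)
        fit = st.fit_highb_monoexp(shells, s0_tilde=1.0, seed=0)
        assert fit.amplitude == pytest.approx(0.097, abs=1e-6)
        assert fit.d1_tilde == pytest.approx(0.12, abs=1e-6)
        assert fit.n_starts_converged == 10

    def test_two_pool_contamination_within_5_percent(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        fit = st.fit_highb_monoexp(shells, s0_tilde=1.0, seed=1)
        assert fit.d1_tilde == pytest.approx(0.12, rel=0.05)
        assert fit.f1_tilde == pytest.approx(0.097, rel=0.05)

    def test_scale_equivariance(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        fit1 = st.fit_highb_monoexp(shells, s0_tilde=1.0, seed=3)
        c = 1234.5
        scaled = shells.copy()
        scaled["mean"] *= c
        fit2 = st.fit_highb_monoexp(scaled, s0_tilde=c, seed=3)
        assert fit2.amplitude / c == pytest.approx(fit1.amplitude, rel=1e-9)
        assert fit2.d1_tilde == pytest.approx(fit1.d1_tilde, rel=1e-9, abs=1e-12)

    def test_seeded_multistart_is_reproducible(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        fits = [st.fit_highb_monoexp(shells, s0_tilde=1.0, seed=7) for _ in range(2)]
        assert fits[0].amplitude == fits[1].amplitude
        assert fits[0].d1_tilde == fits[1].d1_tilde

    def test_all_zero_signal_is_flagged_unidentifiable(self):
        shells = self._shells(0.0, 0.0)
        fit = st.fit_highb_monoexp(shells, s0_tilde=1.0, seed=0)
        # any (A, D1) with A exp(-b D1) ~ 0 fits; the fit must say so
        assert fit.amplitude * math.exp(-10.5 * fit.d1_tilde) < 1e-6
        assert "unidentifiable_highb" in fit.flags

    def test_requires_two_high_shells(self):
        shells = pd.DataFrame({"b": [0.25, 15.0], "te": [88.0] * 2, "mean": [0.9, 0.02]})
        with pytest.raises(ValueError, match=">= 2 shells"):
            st.fit_highb_monoexp(shells, s0_tilde=1.0)

    def test_dropping_top_shell_keeps_noiseless_recovery(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        no_top = shells[shells["b"] < 15.0]
        fit = st.fit_highb_monoexp(no_top, s0_tilde=1.0, seed=2)
        assert fit.d1_tilde == pytest.approx(0.12, rel=0.05)

    def test_dropping_top_shell_increases_noise_variance(self):
        rng = np.random.default_rng(0)
        d1s_full, d1s_drop = [], []
        for rep in range(40):
            noise = rng.normal(0.0, 0.002, size=self.HIGH_B.size)
            shells = self._shells(0.097, 0.12)
            hi = shells["b"].isin(self.HIGH_B)
            shells.loc[hi, "mean"] += noise
            d1s_full.append(st.fit_highb_monoexp(shells, 1.0, seed=rep).d1_tilde)
            drop = shells[shells["b"] < 15.0]
            d1s_drop.append(st.fit_highb_monoexp(drop, 1.0, seed=rep).d1_tilde)
        assert np.var(d1s_drop) > np.var(d1s_full)


class TestT2Fit:
    def test_exact_recovery(self, multi_te_protocol):
        c, t2, d1 = 0.1, 61.0, 0.12
        model = st.TissueModel(
            (st.Compartment("ball", 1.0, d_par=d1, d_perp=d1, t2=t2),)
        )
        # unnormalised multi-TE signal: C exp(-TE/T2) exp(-b D1)
        vals = np.array(
            [
                c * math.exp(-te / t2) * math.exp(-b * d1)
                for b, te in zip(multi_te_protocol.b, multi_te_protocol.te)
            ]
        )
        shells = st.shell_average(vals, multi_te_protocol)
        fit = st.fit_highb_t2(shells, s0_tilde=c, seed=0)
        assert fit.amplitude == pytest.approx(c, abs=1e-6)
        assert fit.t2_1 == pytest.approx(t2, abs=1e-3)
        assert fit.d1_tilde == pytest.approx(d1, abs=1e-6)

    def test_te_independent_data_hits_t2_bound(self, multi_te_protocol):
        vals = np.array(
            [0.1 * math.exp(-b * 0.12) for b in multi_te_protocol.b]
        )
        shells = st.shell_average(vals, multi_te_protocol)
        fit = st.fit_highb_t2(shells, s0_tilde=0.1, seed=0)
        assert "t2_at_upper_bound" in fit.flags

    def test_single_te_directs_to_monoexp(self, single_te_protocol, cgm_model):
        shells = _shells_from_model(cgm_model, single_te_protocol)
        with pytest.raises(ValueError, match="monoexp"):
            st.fit_highb_t2(shells, s0_tilde=1.0)

    def test_per_te_apparent_fraction_decreases(self, multi_te_protocol):
        model = st.TissueModel(
            (
                st.Compartment("ball", 0.1, d_par=0.12, d_perp=0.12, t2=61.0),
                st.Compartment("ball", 0.9, d_par=1.0, d_perp=1.0, t2=120.0),
            )
        )
        vals = noiseless_signals(model, multi_te_protocol)
        shells = st.shell_average(vals, multi_te_protocol)
        f1s = []
        for te, group in shells.groupby("te"):
            s0 = st.estimate_s0_lowb(group.reset_index(drop=True))
            fit = st.fit_highb_monoexp(group.reset_index(drop=True), s0, seed=0)
            f1s.append(fit.f1_tilde)
        assert all(a > b for a, b in zip(f1s, f1s[1:]))


@pytest.fixture(scope="module")
def sphere_waveform():
    # single-axis PGSE carrying b = 15 ms/um^2 (sphere signal is
    # orientation-independent, so one axis suffices)
    g6 = 267.513e-6
    delta, separation = 5.0, 25.0
    G = math.sqrt(15.0 / (separation - delta / 3.0)) / (g6 * delta)
    return st.make_pgse_waveform(G, delta, separation, dt=0.02)


class TestSphereRadiusFit:
    @staticmethod
    def _sphere_shells(waveform, rs, ds, amp=0.1):
        b_wave = st.btensor_from_waveform(waveform).b
        high_b = np.array([10.5, 12.0, 13.5, 15.0])
        ln_s = math.log(st.signal_sphere_waveform(waveform, rs, ds))
        means = amp * np.exp(high_b / b_wave * ln_s)
        b = np.concatenate([[0.25, 1.5], high_b])
        mean = np.concatenate([[amp, amp], means])
        return pd.DataFrame({"b": b, "te": np.full(b.size, 88.0), "mean": mean})

    def test_recovers_radius_within_2_percent(self, sphere_waveform):
        shells = self._sphere_shells(sphere_waveform, rs=4.5, ds=3.0)
        fit = st.fit_sphere_radius(shells, sphere_waveform, s0_tilde=1.0, d_s=3.0, seed=0)
        assert fit.r_s == pytest.approx(4.5, rel=0.02)

    def test_dot_data_gives_small_radius(self, sphere_waveform):
        # flat (dot-like) data: the fitted sphere must be small enough to
        # attenuate by less than 1% at the top shell
        shells = self._sphere_shells(sphere_waveform, rs=1e-3, ds=3.0)
        fit = st.fit_sphere_radius(shells, sphere_waveform, s0_tilde=1.0, d_s=3.0, seed=0)
        assert st.signal_sphere_waveform(sphere_waveform, fit.r_s, 3.0) > 0.99

    def test_missing_waveform_rejected(self, sphere_waveform):
        shells = self._sphere_shells(sphere_waveform, rs=4.5, ds=3.0)
        with pytest.raises(ValueError, match="waveform"):
            st.fit_sphere_radius(shells, None, s0_tilde=1.0)


class TestRoiSummary:
    def _table(self, n, roi="cGM", f1=9.7):
        return pd.DataFrame(
            {
                "roi": [roi] * n,
                "f1_pct": np.full(n, f1),
                "d1": np.full(n, 0.12),
                "fdot_pct": np.full(n, 1.8),
            }
        )

    def test_identical_voxels_collapse(self):
        out = st.roi_summary(self._table(20))
        row = out.iloc[0]
        assert row["f1_pct_median"] == pytest.approx(9.7)
        assert row["f1_pct_p10"] == row["f1_pct_p90"] == pytest.approx(9.7)

    def test_small_roi_suppresses_percentiles(self):
        out = st.roi_summary(self._table(5))
        row = out.iloc[0]
        assert row["f1_pct_median"] == pytest.approx(9.7)
        assert math.isnan(row["f1_pct_p10"]) and math.isnan(row["f1_pct_p90"])

    def test_percentiles_on_spread_data(self):
        rng = np.random.default_rng(5)
        tab = self._table(200)
        tab["f1_pct"] = rng.normal(9.7, 1.0, size=200)
        row = st.roi_summary(tab).iloc[0]
        assert row["f1_pct_p10"] < row["f1_pct_median"] < row["f1_pct_p90"]
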