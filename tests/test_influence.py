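"""Directional correlation, delay extraction (vs brute-force oracle),
influential-neighbor gates, counts, eta and chain removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schoolnet.errors import TooShortError
from schoolnet.influence import (AnalysisConfig, count_influential,
                                 directional_correlation, eta,
                                 extract_delays, global_delay,
                                 identify_influential,
                                 remove_influence_chains,
                                 windowed_correlation)


def unit(angles):
    a = np.asarray(angles, dtype=float)
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


def brute_force_delays(e_i, e_j, w, tau0):
    """Independent oracle: naive loops, np.mean over explicit windows,
    following the documented search rule (full-initial-range start, then
    range [0, tau_prev + 1], smallest delay on ties)."""
    t_total = len(e_i)
    tau0_eff = min(tau0, t_total - 2 * w - 1)
    first = max(w, tau0_eff + w)
    out_tau = np.full(t_total, -1, dtype=int)
    out_gam = np.full(t_total, np.nan)
    prev = tau0_eff - 1
    for t in range(first, t_total - w):
        hi = min(prev + 1, t - w)
        best_tau, best = None, None
        for tau in range(hi + 1):
            if t - tau - w < 0:
                continue
            vals = [float(np.dot(e_i[t + k], e_j[t + k - tau]))
                    for k in range(-w, w + 1)]
            c = float(np.mean(vals))
            if np.isnan(c):
                continue
            if best is None or c > best:
                best, best_tau = c, tau
        if best_tau is None:
            continue
        out_tau[t] = best_tau
        out_gam[t] = best
        prev = best_tau
    return out_tau, out_gam


class TestDirectionalCorrelation:
    @pytest.mark.parametrize("a,b,expect", [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (-1, 0), -1.0),
        ((1, 0), (0, 1), 0.0),
    ])
    def test_reference_values(self, a, b, expect):
        assert directional_correlation(a, b) == pytest.approx(expect)


class TestWindowedCorrelation:
    def test_degenerate_window_equals_h(self):
        e_i = unit([0.1, 0.2, 0.3, 0.4])
        e_j = unit([0.0, 0.1, 0.2, 0.3])
        c = windowed_correlation(e_i, e_j, 2, 1, 0)
        assert c == pytest.approx(float(np.dot(e_i[2], e_j[1])))

    def test_mean_of_constant(self):
        ang = np.arccos(0.9)
        e_i = unit(np.full(9, ang))
        e_j = unit(np.zeros(9))
        assert windowed_correlation(e_i, e_j, 4, 0, 2) == pytest.approx(0.9)

    def test_arithmetic_mean(self):
        # H over the window takes values (1, 0.5, 0, -0.5, -1) -> mean 0
        angles_i = [0.0, np.arccos(0.5), np.pi / 2, np.arccos(-0.5), np.pi]
        e_i = unit(angles_i)
        e_j = unit(np.zeros(5))
        assert windowed_correlation(e_i, e_j, 2, 0, 2) == pytest.approx(0.0, abs=1e-12)

    def test_masked_when_history_missing(self):
        e = unit(np.zeros(10))
        assert np.isnan(windowed_correlation(e, e, 3, 5, 2))  # needs t-tau-w >= 0
        assert np.isnan(windowed_correlation(e, e, 9, 0, 2))  # window past the end


class TestExtractDelays:
    def test_exact_lag_recovered_everywhere(self, pair_noiseless):
        ts, gt, kin, event, an = pair_noiseless
        cfg = AnalysisConfig(dt=ts.dt)
        track = extract_delays(kin.e[1], kin.e[0], cfg)
        tau = track.tau_frames[60:]
        tau = tau[tau >= 0]
        assert np.mean(tau == 20) >= 0.95

    def test_identical_series_zero_delay(self):
        rng = np.random.default_rng(3)
        e = unit(np.cumsum(rng.normal(0, 0.2, size=120)))
        cfg = AnalysisConfig(tau0=30)
        track = extract_delays(e, e, cfg)
        defined = track.tau_frames >= 0
        assert defined.any()
        assert np.all(track.tau_frames[defined] == 0)  # smallest-tau tie-break
        assert np.allclose(track.gamma[defined], 1.0)

    def test_search_range_follows_previous_delay(self):
        # when tau*_{k-1} = 10 the next frame may search [0, 11] only:
        # the recursion can never jump upward by more than one frame
        rng = np.random.default_rng(5)
        e_i = unit(np.cumsum(rng.normal(0, 0.3, 300)))
        e_j = unit(np.cumsum(rng.normal(0, 0.3, 300)))
        track = extract_delays(e_i, e_j, AnalysisConfig(tau0=40))
        t = track.tau_frames
        defined = np.where(t >= 0)[0]
        diffs = np.diff(t[defined])
        assert np.all(diffs <= 1)

    def test_too_short_series(self):
        with pytest.raises(TooShortError):
            extract_delays(unit([0.0, 0.1]), unit([0.0, 0.1]), AnalysisConfig(w=2))

    @pytest.mark.parametrize("tau0", [15, 50, 500])
    def test_oracle_equivalence_bit_exact(self, tau0):
        # random-walk headings, 200 frames: recursion must equal the naive
        # constrained-argmax oracle exactly, including the delay bookkeeping
        rng = np.random.default_rng(11)
        e_i = unit(np.cumsum(rng.normal(0, 0.25, 200)))
        e_j = unit(np.roll(np.cumsum(rng.normal(0, 0.25, 200)), 7))
        cfg = AnalysisConfig(tau0=tau0)
        track = extract_delays(e_i, e_j, cfg)
        o_tau, o_gam = brute_force_delays(e_i, e_j, cfg.w, tau0)
        # the delay series (every argmax decision) must agree bit-exactly;
        # correlation values may differ by one ulp (BLAS dot vs elementwise)
        np.testing.assert_array_equal(track.tau_frames, o_tau)
        np.testing.assert_allclose(track.gamma, o_gam, rtol=0, atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(rot=st.floats(-np.pi, np.pi), seed=st.integers(0, 100))
    def test_global_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.normal(0, 0.3, 150))
        b = np.cumsum(rng.normal(0, 0.3, 150))
        cfg = AnalysisConfig(tau0=20)
        t1 = extract_delays(unit(a), unit(b), cfg)
        t2 = extract_delays(unit(a + rot), unit(b + rot), cfg)
        np.testing.assert_array_equal(t1.tau_frames, t2.tau_frames)
        np.testing.assert_allclose(t1.gamma, t2.gamma, atol=1e-12)


def make_track(tau_frames, gammas, focal, neighbor, t_total):
    tf = np.full(t_total, -1, dtype=int)
    gm = np.full(t_total, np.nan)
    for t, (tau, g) in enumerate(zip(tau_frames, gammas)):
        tf[t] = tau
        gm[t] = g
    from schoolnet.influence import DelayTrack
    return DelayTrack(focal=focal, neighbor=neighbor, w=2,
                      tau_frames=tf, gamma=gm)


class TestIdentify:
    TIMES = np.arange(10) * 0.02

    def run(self, tracks):
        return identify_influential(tracks, 1, AnalysisConfig(), self.TIMES)

    def test_single_passing_neighbor(self):
        tracks = {2: make_track([20], [0.99], 1, 2, 10)}
        rec = self.run(tracks)
        assert len(rec) == 1
        assert rec.loc[0, "neighbor"] == 2 and rec.loc[0, "tau_s"] == pytest.approx(0.4)

    def test_reaction_time_floor(self):
        tracks = {2: make_track([1], [0.99], 1, 2, 10)}  # tau = 0.02 s <= 0.04
        assert len(self.run(tracks)) == 0
        tracks = {2: make_track([2], [0.99], 1, 2, 10)}  # 0.04 s, not strictly above
        assert len(self.run(tracks)) == 0

    def test_epsilon_percent_of_max_rule(self):
        tracks = {2: make_track([10], [0.99], 1, 2, 10),
                  3: make_track([10], [0.97], 1, 3, 10),
                  4: make_track([10], [0.90], 1, 4, 10)}
        rec = self.run(tracks)
        # 0.97 >= 0.97 * 0.99 qualifies; 0.90 fails C_min outright
        assert sorted(rec["neighbor"]) == [2, 3]


class TestCountsAndEta:
    def test_count_distinct_neighbors(self):
        rec = pd.DataFrame({"frame": [5, 5, 6], "focal": [1, 1, 2],
                            "neighbor": [2, 3, 1]})
        nif = count_influential(rec, [1, 2, 3], np.arange(10))
        assert nif[0, 5] == 2 and nif[1, 6] == 1 and nif[2].sum() == 0

    def test_eta_reference_values(self):
        e = eta(np.array([2.0, 1.0, 1.0, 0.0, 3.0]))
        assert e[0] == pytest.approx(0.5)
        assert e[1] == pytest.approx(0.0)
        assert np.isnan(e[3])  # zero denominator -> undefined marker
        assert np.isnan(e[-1])


class TestChainRemoval:
    def rec(self, triples):
        return pd.DataFrame([{"frame": 0, "focal": a, "neighbor": b}
                             for a, b in triples],
                            columns=["frame", "focal", "neighbor"])

    def pairs(self, df):
        return sorted(zip(df["focal"], df["neighbor"]))

    def test_basic_chain_dropped(self):
        out, n = remove_influence_chains(self.rec([(1, 2), (1, 3), (2, 3)]))
        assert self.pairs(out) == [(1, 3), (2, 3)] and n == 1

    def test_no_link_unchanged(self):
        out, n = remove_influence_chains(self.rec([(1, 2), (1, 3)]))
        assert n == 0 and len(out) == 2

    def test_mutual_link_drops_both(self):
        out, n = remove_influence_chains(
            self.rec([(1, 2), (1, 3), (2, 3), (3, 2)]))
        assert self.pairs(out) == [(2, 3), (3, 2)] and n == 2

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    max_size=15))
    def test_idempotent_and_never_adds(self, triples):
        triples = [(a, b) for a, b in triples if a != b]
        df = self.rec(triples).drop_duplicates()
        once, n1 = remove_influence_chains(df)
        twice, n2 = remove_influence_chains(once)
        assert len(once) <= len(df) and n2 == 0
        assert self.pairs(twice) == self.pairs(once)


class TestGlobalDelay:
    def test_exact_lag(self):
        rng = np.random.default_rng(2)
        a = np.cumsum(rng.normal(0, 0.3, 300))
        b = np.concatenate([np.zeros(20), a[:-20]])
        assert global_delay(unit(b), unit(a), max_tau=60) == 20

    def test_identical_series_tie_break(self):
        e = unit(np.cumsum(np.full(50, 0.1)))
        assert global_delay(e, e) == 0

    def test_disjoint_halves_yield_compromise(self):
        # two halves with lags 16 and 48: each per-half delay is recovered,
        # while the whole-series delay is a single compromise value
        rng = np.random.default_rng(9)
        a = np.cumsum(rng.normal(0, 0.3, 400))
        t = np.arange(400)
        b = np.where(t < 200, a[np.maximum(t - 16, 0)], a[t - 48])
        first = global_delay(unit(b[:200]), unit(a[:200]), max_tau=80)
        second = global_delay(unit(b[200:]), unit(a[200:]), max_tau=80)
        whole = global_delay(unit(b), unit(a), max_tau=80)
        assert first == 16 and second == 48
        # the whole dataset collapses to one delay between the two regimes,
        # so no single value can describe both halves
        assert 16 <= whole <= 48
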