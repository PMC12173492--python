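"""Co-minute permutation test, peri-event alignment, window fractions,
negative-binomial model comparison, pair-level Spearman analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mousebarn import rfid, vocal
from mousebarn.audio import Recording
from mousebarn import synth


class TestCominute:
    def test_saturated_recording_p_one(self):
        s = np.ones(20, dtype=int)
        u = np.ones(20, dtype=int)
        res = vocal.cominute_test(s, u, n_perm=50, seed=0)
        assert res.observed == 20
        assert res.p_value == 1.0  # null always equals the observed maximum

    def test_zero_squeaks_p_one(self):
        res = vocal.cominute_test(np.zeros(10, dtype=int),
                                  np.ones(10, dtype=int), n_perm=50, seed=0)
        assert res.observed == 0 and res.p_value == 1.0

    def test_addone_estimator_identity(self):
        rng = np.random.default_rng(0)
        s = rng.poisson(1.0, 50)
        u = rng.poisson(0.5, 50)
        res = vocal.cominute_test(s, u, n_perm=199, seed=1)
        expect = (1 + np.sum(res.null_values >= res.observed)) / 200
        assert res.p_value == pytest.approx(expect)
        assert 0 < res.p_value <= 1

    def test_null_preserves_squeak_total(self):
        """The permutation reassigns squeaks among segments; joint planted
        structure inflates the observed statistic above the null mean."""
        rng = np.random.default_rng(2)
        u = rng.poisson(0.5, 200)
        s = (u > 0).astype(int) * 3  # squeaks exactly where USVs are
        res = vocal.cominute_test(s, u, n_perm=500, seed=3)
        assert res.observed > res.null_values.mean()
        assert res.p_value < 0.05

    def test_zero_segments_error(self):
        with pytest.raises(ValueError):
            vocal.cominute_test(np.array([]), np.array([]), n_perm=10)


class TestAlignToEvents:
    def test_single_event_bin_placement(self):
        h = vocal.align_to_events([110.0], [100.0])
        # lag +10 falls in bin [10, 15)
        i = np.searchsorted(h.edges, 10.0, side="right") - 1
        assert h.counts[i] == 1 and h.n_vocalizations == 1
        assert h.pct[i] == 100.0

    def test_window_boundary_excluded(self):
        h = vocal.align_to_events([161.0], [100.0])
        assert h.n_vocalizations == 0

    def test_percentages_sum_to_100(self, rng):
        onsets = rng.uniform(0, 1000, 300)
        events = rng.uniform(0, 1000, 20)
        h = vocal.align_to_events(onsets, events)
        assert h.pct.sum() == pytest.approx(100.0)

    def test_shifted_event_stream_shifts_mode(self, rng):
        """Aligning to a time-shifted copy of the event stream moves the
        modal lag by exactly that shift."""
        events = np.sort(rng.uniform(100, 10000, 50))
        onsets = np.concatenate([events + 10.0 + rng.normal(0, 1, 50)])
        h0 = vocal.align_to_events(onsets, events, bin_width=5.0)
        h1 = vocal.align_to_events(onsets, events + 20.0, bin_width=5.0)
        assert h1.modal_lag() == pytest.approx(h0.modal_lag() - 20.0,
                                               abs=5.0)

    def test_empty_event_stream(self):
        h = vocal.align_to_events([1.0, 2.0], [])
        assert h.n_events == 0 and h.counts.sum() == 0


class TestAlignmentNull:
    def test_replicate_count_and_empty_case(self):
        rec = Recording("r", "b", 0.0, 20)
        null = vocal.alignment_null(0, rec, [100.0], n_rand=7, seed=0)
        assert null.null_counts.shape[0] == 7
        assert null.null_counts.sum() == 0

    def test_uniform_events_inside_envelope(self, rng):
        """Uniformly planted vocal times stay within the pointwise null
        range in the vast majority of bins."""
        rec = Recording("r", "b", 0.0, 120)
        seg = rng.integers(120, size=400)
        onsets = 60.0 * seg + rng.uniform(0, 55, 400)
        events = np.sort(rng.uniform(500, 6500, 30))
        h = vocal.align_to_events(onsets, events)
        null = vocal.alignment_null(400, rec, events, n_rand=200, seed=1)
        lo, hi = null.envelope(0.0, 100.0)
        inside = (h.counts >= lo) & (h.counts <= hi)
        assert inside.mean() >= 0.9


class TestWindowFractions:
    def _events(self, times, sexes=None, seasons=None):
        n = len(times)
        return pd.DataFrame({
            "time": times,
            "sex": sexes or ["male"] * n,
            "season": seasons or ["spring"] * n})

    def test_followed_counts_within_window(self):
        out = vocal.window_fractions(self._events([100.0]), [130.0],
                                     "followed")
        assert out["pct"].iloc[0] == 100.0

    def test_simultaneous_onset_not_followed(self):
        out = vocal.window_fractions(self._events([100.0]), [100.0],
                                     "followed")
        assert out["pct"].iloc[0] == 0.0

    def test_preceded_boundary(self):
        # onset exactly at t is not "preceded"; t-60 is included
        out = vocal.window_fractions(self._events([100.0]), [100.0],
                                     "preceded")
        assert out["pct"].iloc[0] == 0.0
        out = vocal.window_fractions(self._events([100.0]), [40.0],
                                     "preceded")
        assert out["pct"].iloc[0] == 100.0

    def test_hand_built_fixture(self):
        """Five entrances, manual enumeration: events at 0, 100, 200, 300,
        400; onsets at 30, 130, 461 -> entrances 0 and 100 are followed."""
        events = self._events([0.0, 100.0, 200.0, 300.0, 400.0],
                              sexes=["male"] * 5)
        out = vocal.window_fractions(events, [30.0, 130.0, 461.0],
                                     "followed")
        assert out["pct"].iloc[0] == pytest.approx(40.0)
        assert out["n_events"].iloc[0] == 5

    def test_grouping(self):
        events = self._events([0.0, 100.0], sexes=["male", "female"])
        out = vocal.window_fractions(events, [10.0], "followed")
        out = out.set_index("sex")
        assert out.loc["male", "pct"] == 100.0
        assert out.loc["female", "pct"] == 0.0


def _glm_table(rng, n=144, beta_pup=0.5, alpha=0.4, base=2.0):
    seasons = np.repeat(["spring", "summer", "autumn", "winter"], n // 4)
    season_fx = {"spring": 0.5, "summer": 0.3, "autumn": -0.3, "winter": 0.0}
    pups = rng.poisson(2.0, n)
    adults = rng.integers(1, 10, n)
    sex_ratio = rng.uniform(0, 1, n)
    exposure = np.full(n, 660.0)
    eta = base + np.array([season_fx[s] for s in seasons]) \
        + beta_pup * pups + np.log(exposure)
    mu = np.exp(eta - np.log(exposure) + np.log(exposure))  # = exp(eta)
    # negative binomial via gamma-Poisson mixture
    lam = rng.gamma(shape=1 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam)
    return pd.DataFrame({"count": counts, "season": seasons,
                         "n_adults": adults, "sex_ratio": sex_ratio,
                         "n_pups": pups, "exposure": exposure})


class TestVocalGlms:
    def test_pup_model_wins_and_recovers_beta(self, rng):
        table = _glm_table(rng)
        comp = vocal.fit_vocal_glms(table)
        assert comp.best == "season+pups"
        beta = comp.models["season+pups"].params["n_pups"]
        assert beta == pytest.approx(0.5, rel=0.25)
        tab = comp.aic_table()
        assert tab.iloc[0]["model"] == "season+pups"

    def test_aic_identity_and_pseudo_r2_range(self, rng):
        table = _glm_table(rng, beta_pup=0.0)
        comp = vocal.fit_vocal_glms(table)
        for m in comp.models.values():
            k = len(m.params) + 1
            assert m.aic == pytest.approx(2 * k - 2 * m.llf)
            assert 0.0 <= m.pseudo_r2 <= 1.0

    def test_single_season_rejected(self, rng):
        table = _glm_table(rng)
        table["season"] = "spring"
        with pytest.raises(ValueError, match="season"):
            vocal.fit_vocal_glms(table)

    def test_all_zero_counts_rejected(self, rng):
        table = _glm_table(rng)
        table["count"] = 0
        with pytest.raises(ValueError, match="zero"):
            vocal.fit_vocal_glms(table)

    def test_nb_approaches_poisson_at_small_alpha(self, rng):
        """On equidispersed data the NB log-likelihood converges to the
        Poisson log-likelihood as the dispersion vanishes."""
        n = 60
        x = rng.uniform(0, 1, n)
        counts = rng.poisson(np.exp(1.0 + 0.5 * x))
        X = sm.add_constant(x)
        llf_pois = sm.GLM(counts, X, family=sm.families.Poisson()).fit().llf
        llf_nb = sm.GLM(counts, X, family=sm.families.NegativeBinomial(
            alpha=1e-8)).fit().llf
        assert abs(llf_nb - llf_pois) < 1e-3


def _toy_series(counts, coi):
    return vocal.PairSeries(
        mouse_a="a", mouse_b="b", box_id="x", recording_id="r",
        counts=pd.DataFrame({"squeak": counts,
                             "usv": [0] * len(counts)}),
        coi_next=np.asarray(coi, dtype=float))


class TestPairSpearman:
    def test_monotone_series(self):
        assert vocal.pair_spearman(_toy_series([1, 2, 3],
                                               [0.1, 0.2, 0.3])) == 1.0
        assert vocal.pair_spearman(_toy_series([3, 2, 1],
                                               [0.1, 0.2, 0.3])) == -1.0

    def test_tied_data_matches_average_rank_formula(self):
        counts = [1, 2, 2, 3]
        coi = [0.1, 0.4, 0.2, 0.3]

        def avg_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based
                i = j
            return ranks

        rx, ry = avg_ranks(counts), avg_ranks(coi)
        expected = (np.mean(rx * ry) - rx.mean() * ry.mean()) \
            / (rx.std() * ry.std())
        assert vocal.pair_spearman(_toy_series(counts, coi)) \
            == pytest.approx(expected)

    def test_constant_series_undefined(self):
        assert np.isnan(vocal.pair_spearman(_toy_series([1, 1, 1],
                                                        [0.1, 0.2, 0.3])))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            vocal.pair_spearman(_toy_series([1], [0.1]))


class TestBuildPairSeries:
    def _fixture(self):
        """Two mice meeting three times in a recorded box, with hand-placed
        vocal events."""
        rows = []
        rec = Recording("r1", "bx", 0.0, n_segments=200)
        meet_times = [(100.0, 200.0), (1000.0, 1100.0), (2000.0, 2100.0)]
        for s, e in meet_times:
            rows.append(("a", "female", "bx", s, e))
            rows.append(("b", "male", "bx", s, e))
        stays = pd.DataFrame(rows, columns=["mouse_id", "sex", "box_id",
                                            "entry", "exit"])
        stays, _ = rfid.validate_stays(stays)
        meetings = rfid.detect_meetings(stays)
        # meeting 1: onsets 110 (in segment 1) and 115.5 (gap: 115 in
        # [115,120) which is the pause after segment 1)  -> only 110 counts
        events = pd.DataFrame({
            "recording_id": ["r1"] * 3, "box_id": ["bx"] * 3,
            "onset": [110.0, 115.5, 1050.0],
            "offset": [110.1, 115.6, 1050.1],
            "label": ["squeak", "squeak", "squeak"]})
        return meetings, events, stays, [rec]

    def test_off_by_one_and_hand_tally(self):
        meetings, events, stays, recs = self._fixture()
        series = vocal.build_pair_series(meetings, events, stays, recs,
                                         min_meetings=2)
        assert len(series) == 1
        s = series[0]
        # 3 meetings -> 2 usable points; gap event at 115.5 not counted
        assert len(s) == 2
        assert list(s.counts["squeak"]) == [1, 1]
        assert s.pair_type == "female-male"
        # COI at t=1000: overlap 100, each mouse total 100 -> 100/100 = 1
        assert s.coi_next[0] == pytest.approx(1.0)

    def test_min_meetings_excludes_short_series(self):
        meetings, events, stays, recs = self._fixture()
        assert vocal.build_pair_series(meetings, events, stays, recs,
                                       min_meetings=4) == []

    def test_no_vocal_events_all_zero_counts(self):
        meetings, events, stays, recs = self._fixture()
        series = vocal.build_pair_series(meetings, events.iloc[0:0], stays,
                                         recs, min_meetings=2)
        assert list(series[0].counts["squeak"]) == [0, 0]


class TestShuffledControls:
    def test_two_point_series_null_is_plus_minus_one(self):
        s = _toy_series([1, 2], [0.1, 0.2])
        res = vocal.shuffled_pair_controls([s], n_shuffles=400, seed=0)
        vals, counts = np.unique(np.round(res.null, 6), return_counts=True)
        assert set(vals) == {-1.0, 1.0}
        assert abs(counts[0] - counts[1]) < 80  # roughly equal frequencies

    def test_planted_coupling_detected(self):
        stays, events, recs, _ = synth.simulate_pair_coupling(
            n_pairs=40, n_meetings=10, gamma_pair=1.0, seed=4)
        stays, _ = rfid.validate_stays(stays)
        meetings = rfid.detect_meetings(stays)
        series = vocal.build_pair_series(meetings, events, stays, recs)
        res = vocal.shuffled_pair_controls(series, n_shuffles=30, seed=0)
        assert res.actual.mean() > res.null.mean()
        assert res.p_greater < 0.01

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            vocal.shuffled_pair_controls([])
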