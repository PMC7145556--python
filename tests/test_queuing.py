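"""The C-terminal ribosome queuing metric, filtering and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import riboqueue as rq
from riboqueue.errors import RiboQueueError
from riboqueue.queuing import TOO_SHORT, ZERO_INTERPEAK

from conftest import make_orf, make_track


def track_with_rpm(orf, rpm):
    t = rq.CoverageTrack(orf.transcript_id, np.zeros(orf.tx_len, dtype=np.int64), 1)
    t.rpm = np.asarray(rpm, dtype=float)
    return t


class TestQueuingMetric:
    def test_flat_positive_track_gives_exactly_three(self, flat_track_and_orf):
        track, orf = flat_track_and_orf
        q, flag = rq.queuing_metric(track, orf)
        assert flag is None
        assert q == 3.0

    def test_scale_invariance(self, flat_track_and_orf):
        track, orf = flat_track_and_orf
        q1, _ = rq.queuing_metric(track, orf)
        track.rpm = track.rpm * 1000.0
        q2, _ = rq.queuing_metric(track, orf)
        assert q1 == q2

    def test_hand_evaluated_example(self):
        # 10 at -33, 8 at -63, 6 at -93, 2 between the peaks -> (10+8+6)/2
        orf = make_orf(cds_len=300)
        rpm = np.zeros(orf.tx_len)
        ss = orf.stop_start
        for lo, hi in rq.default_peak_layout().inter_windows:
            rpm[ss + lo : ss + hi] = 2.0
        rpm[ss - 33], rpm[ss - 63], rpm[ss - 93] = 10.0, 8.0, 6.0
        q, flag = rq.queuing_metric(track_with_rpm(orf, rpm), orf)
        assert flag is None
        assert q == pytest.approx(12.0)

    def test_zero_interpeak_flagged_undefined(self):
        orf = make_orf(cds_len=300)
        rpm = np.zeros(orf.tx_len)
        ss = orf.stop_start
        rpm[ss - 33] = 5.0
        q, flag = rq.queuing_metric(track_with_rpm(orf, rpm), orf)
        assert np.isnan(q)
        assert flag == ZERO_INTERPEAK

    def test_short_orf_excluded(self):
        orf = make_orf(cds_len=90)
        track = make_track(np.ones(orf.tx_len, dtype=int))
        q, flag = rq.queuing_metric(track, orf)
        assert np.isnan(q) and flag == TOO_SHORT

    def test_monotone_in_amplitude_on_expected_intensity(self):
        qs = []
        for amp in [0.0, 5.0, 20.0, 80.0]:
            c = rq.SimConfig(
                n_orfs=1, orf_length_range=(300, 300), body_intensity=2.0,
                queue_amplitude=amp, expression_sigma=0.0, queued_fraction=1.0,
                queue_cterm_aas=None, seed=4,
            )
            orfs, _ = rq.generate_annotation(c)
            lam = rq.expected_intensity(c, orfs[0], True)
            q, _ = rq.queuing_metric_vector(lam, orfs[0].stop_start)
            qs.append(q)
        assert all(a < b for a, b in zip(qs, qs[1:]))
        rho = 0.7
        assert qs[1] == pytest.approx((3 * 2 + 5 * (1 + rho + rho**2)) / 2)


class TestCoverageFilter:
    def _setup(self, means, cds_len=300):
        orf = make_orf(cds_len=cds_len)
        conds = {}
        for cond, mean in means.items():
            rpm = np.zeros(orf.tx_len)
            rpm[orf.stop_start - 120 : orf.stop_start] = mean
            conds[cond] = {orf.transcript_id: track_with_rpm(orf, rpm)}
        return conds, orf

    def test_boundary_mean_exactly_ten_passes(self):
        conds, orf = self._setup({c: 10.0 for c in "abcd"})
        ok, reason = rq.coverage_filter(conds, orf, rq.QueuingConfig())
        assert ok and reason is None

    def test_single_low_condition_fails_and_is_named(self):
        conds, orf = self._setup({"a": 10.0, "b": 9.9, "c": 12.0, "d": 11.0})
        ok, reason = rq.coverage_filter(conds, orf, rq.QueuingConfig())
        assert not ok
        assert reason == "low_coverage:b"

    def test_short_orf_fails_with_reason(self):
        conds, orf = self._setup({"a": 100.0}, cds_len=90)
        ok, reason = rq.coverage_filter(conds, orf, rq.QueuingConfig())
        assert not ok and reason == TOO_SHORT

    def test_missing_condition_is_an_error(self):
        conds, orf = self._setup({"a": 10.0})
        cfg = rq.QueuingConfig(conditions=("a", "b"))
        with pytest.raises(RiboQueueError, match="b"):
            rq.coverage_filter(conds, orf, cfg)


def _scores_from_qs(qs):
    """Build a score table via score_all from constructed flat+peak tracks."""
    orfs, conds = [], {"c1": {}}
    for i, q in enumerate(qs):
        orf = make_orf(tx=f"t{i}", cds_len=300)
        rpm = np.zeros(orf.tx_len)
        ss = orf.stop_start
        # inter-peak density 20, single spike per peak window at 20*q/3:
        # Q = 3 * (20q/3) / 20 = q, and the window mean stays above 10 RPM
        for lo, hi in rq.default_peak_layout().inter_windows:
            rpm[ss + lo : ss + hi] = 20.0
        for pos in (-33, -63, -93):
            rpm[ss + pos] = 20.0 * q / 3.0
        conds["c1"][orf.transcript_id] = track_with_rpm(orf, rpm)
        orfs.append(orf)
    return conds, orfs


class TestScoreAll:
    def test_zscore_matches_hand_calculation(self):
        conds, orfs = _scores_from_qs([1, 2, 3, 4, 10])
        scores = rq.score_all(conds, orfs)
        assert scores["Q"].mean() == pytest.approx(4.0)
        z10 = scores.loc[scores["Q"].idxmax(), "z"]
        assert z10 == pytest.approx((10 - 4) / np.std([1, 2, 3, 4, 10], ddof=1))
        assert z10 == pytest.approx(1.697, abs=1e-3)

    def test_equal_qs_leave_z_undefined_with_warning(self):
        conds, orfs = _scores_from_qs([5, 5, 5])
        with pytest.warns(UserWarning, match="zero Q variance"):
            scores = rq.score_all(conds, orfs)
        assert scores["z"].isna().all()
        assert rq.zscore_select(scores).empty

    def test_undefined_q_orf_does_not_change_others(self):
        conds, orfs = _scores_from_qs([1, 2, 3, 4, 10])
        base = rq.score_all(conds, orfs)
        # add an ORF with coverage only inside peak windows: Q undefined
        orf = make_orf(tx="t_undef", cds_len=300)
        rpm = np.zeros(orf.tx_len)
        ss = orf.stop_start
        rpm[ss - 120 : ss - 98] = 120.0  # outside layout windows, high mean
        rpm[ss - 33] = 50.0
        conds["c1"][orf.transcript_id] = track_with_rpm(orf, rpm)
        extended = rq.score_all(conds, orfs + [orf])
        merged = base.merge(
            extended, on="orf_id", suffixes=("_a", "_b")
        )
        assert np.allclose(merged["z_a"], merged["z_b"])

    def test_selection_invariant_to_rescaling(self):
        conds, orfs = _scores_from_qs([1, 2, 3, 4, 10])
        sel1 = rq.zscore_select(rq.score_all(conds, orfs))
        for t in conds["c1"].values():
            t.rpm = t.rpm * 7.0
        sel2 = rq.zscore_select(rq.score_all(conds, orfs))
        assert set(sel1["orf_id"]) == set(sel2["orf_id"])

    @pytest.mark.parametrize("cutoff,expected", [(np.inf, 0), (-np.inf, 5)])
    def test_select_extreme_cutoffs(self, cutoff, expected):
        conds, orfs = _scores_from_qs([1, 2, 3, 4, 10])
        scores = rq.score_all(conds, orfs)
        assert len(rq.zscore_select(scores, cutoff)) == expected


class TestGroupByCterm:
    def test_group_means(self):
        scores = pd.DataFrame(
            {
                "orf_id": list("abc"),
                "condition": ["c1"] * 3,
                "Q": [4.0, 6.0, 10.0],
                "cterm_aa": ["K", "K", "R"],
                "stop_codon": ["UAA"] * 3,
                "mean_rpm": [20.0] * 3,
                "flag": [None] * 3,
                "z": [0.0] * 3,
            }
        )
        groups = rq.group_by_cterm(scores)
        k = groups[(groups.cterm_aa == "K")].iloc[0]
        r = groups[(groups.cterm_aa == "R")].iloc[0]
        w = groups[(groups.cterm_aa == "W")].iloc[0]
        assert k.mean_Q == pytest.approx(5.0) and k.n == 2
        assert r.mean_Q == pytest.approx(10.0)
        assert w.n == 0 and np.isnan(w.mean_Q)

    def test_kr_queued_simulation_separates_groups(self):
        """With queuing imposed only on K/R-ending ORFs, mean Q for K and R
        exceeds the rest (one-sided Mann-Whitney p < 0.01)."""
        cfg = rq.SimConfig(n_orfs=200, seed=13)
        orfs, truth = rq.generate_annotation(cfg)
        aln, _ = rq.simulate_footprints(cfg, orfs, truth, seed=14)
        tracks, _ = rq.assign_psites(
            aln, rq.default_offset_table(), {o.transcript_id: o.tx_len for o in orfs}
        )
        rq.normalize_rpm(tracks)
        scores = rq.score_all(
            {"sim": tracks}, orfs, rq.QueuingConfig(min_coverage_rpm=0.0)
        )
        kr = scores[scores["cterm_aa"].isin(["K", "R"])]["Q"].dropna()
        other = scores[~scores["cterm_aa"].isin(["K", "R"])]["Q"].dropna()
        assert kr.mean() > other.mean()
        p = sps.mannwhitneyu(kr, other, alternative="greater").pvalue
        assert p < 0.01
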