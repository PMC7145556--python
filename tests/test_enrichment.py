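"""Binomial log-odds positional enrichment and stop-codon tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riboqueue as rq
from riboqueue.errors import ConfigurationError, RiboQueueError
from riboqueue.enrichment import LOGODDS_CAP, cterm_window

from conftest import make_orf


def brute_force_tail(k, n, p, upper):
    """Independent oracle: explicit binomial tail sum."""
    idx = range(k, n + 1) if upper else range(0, k + 1)
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in idx)


class TestBackgroundFrequencies:
    def test_counting_example(self):
        bg = rq.background_frequencies([], n_codons=2, windows=["AK", "AR"])
        assert bg.prob(-2, "A") == 1.0
        assert bg.prob(-1, "K") == 0.5
        assert bg.prob(-1, "R") == 0.5

    def test_single_sequence_gives_zero_one(self):
        bg = rq.background_frequencies([], n_codons=2, windows=["AK"])
        vals = bg.freqs.to_numpy().ravel()
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        windows = ["".join(rng.choice(aas, 5)) for _ in range(40)]
        bg = rq.background_frequencies([], n_codons=5, windows=windows)
        assert np.allclose(bg.freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_set_is_an_error(self):
        with pytest.raises(RiboQueueError):
            rq.background_frequencies([], n_codons=3, windows=[])


class TestSignedLogodds:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [
            (1, 1, 0.5, 0.0),  # symmetric single draw
            (4, 4, 0.5, math.log10(15)),  # P[X>=4] = 1/16 -> log10(15/1)
            (0, 4, 0.5, -math.log10(15)),
        ],
    )
    def test_reference_values(self, k, n, p, expected):
        s, _, flag = rq.signed_logodds(k, n, p)
        assert flag is None
        assert s == pytest.approx(expected, abs=1e-9)

    def test_matches_bruteforce_tails_for_all_small_n(self):
        """Exact equivalence against an explicit tail summation, n <= 50."""
        for n in range(1, 51):
            for p in (0.05, 0.3, 0.5, 0.9):
                for k in range(0, n + 1):
                    s, p_val, flag = rq.signed_logodds(k, n, p)
                    assert flag is None
                    upper = k >= n * p
                    oracle_p = brute_force_tail(k, n, p, upper)
                    oracle_s = math.log10((1 - oracle_p) / oracle_p) if oracle_p < 1 else 0.0
                    if not upper:
                        oracle_s = -oracle_s
                    if 0 < oracle_p < 1:
                        assert s == pytest.approx(oracle_s, abs=1e-9), (k, n, p)

    @given(
        n=st.integers(1, 60),
        k=st.integers(0, 60),
        p=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, n, k, p):
        """k <-> n-k with p <-> 1-p flips the sign of s (away from the
        exact tie k = n*p, where the tail convention is one-sided)."""
        if k > n or k == n * p or (n - k) == n * (1 - p):
            return
        s1, _, _ = rq.signed_logodds(k, n, p)
        s2, _, _ = rq.signed_logodds(n - k, n, 1 - p)
        assert s1 == pytest.approx(-s2, abs=1e-9)

    def test_degenerate_background_capped_and_flagged(self):
        s, _, flag = rq.signed_logodds(3, 5, 0.0)
        assert s == LOGODDS_CAP and flag == "p_bg_zero"
        s, _, flag = rq.signed_logodds(3, 5, 1.0)
        assert s == -LOGODDS_CAP and flag == "p_bg_one"

    def test_invalid_background_rejected(self):
        with pytest.raises(ConfigurationError):
            rq.signed_logodds(1, 2, 1.5)


class TestBonferroniThreshold:
    def test_half_alpha_single_test_is_zero(self):
        assert rq.bonferroni_threshold(0.5, 1) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert rq.bonferroni_threshold(0.05, 100) == pytest.approx(
            math.log10(1999), abs=1e-9
        )

    def test_monotone_in_number_of_tests(self):
        ts = [rq.bonferroni_threshold(0.05, n) for n in (1, 10, 140, 1000)]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            rq.bonferroni_threshold(1.5, 10)


class TestStopCodonContext:
    def _orfs_with_last_codons(self, codons):
        return [
            make_orf(tx=f"t{i}", cds_len=300, seq="GCT" * 98 + c + "TAA")
            for i, c in enumerate(codons)
        ]

    def test_null_case_foreground_equals_background(self):
        codons = ["AAA", "AGA", "GCT", "TGG", "CAA"] * 4
        orfs = self._orfs_with_last_codons(codons)
        mat = rq.stop_codon_context(orfs, orfs)
        assert mat.significant().empty
        assert mat.table["s"].abs().max() < 1.0

    def test_binomial_example_value(self):
        # 6/10 foreground ORFs end AAA against p_bg = 0.1; expected tail
        # frozen from the explicit summation oracle
        oracle_p = brute_force_tail(6, 10, 0.1, upper=True)
        s, p, flag = rq.signed_logodds(6, 10, 0.1)
        assert p == pytest.approx(oracle_p, abs=1e-12)
        assert p == pytest.approx(1.46903e-4, rel=1e-4)
        assert s == pytest.approx(3.833, abs=1e-3)

    def test_simulated_aaa_enrichment_flagged(self):
        rng = np.random.default_rng(21)
        from riboqueue.simulate import SENSE_CODONS

        bg_codons = list(rng.choice(SENSE_CODONS, 200))
        fg_codons = ["AAA"] * 60 + list(rng.choice(SENSE_CODONS, 20))
        background = self._orfs_with_last_codons(bg_codons + fg_codons)
        foreground = self._orfs_with_last_codons(fg_codons)
        mat = rq.stop_codon_context(foreground, background)
        sig = set(mat.significant()["residue"])
        assert "AAA" in sig


class TestStopIdentityAssociation:
    def _scores(self, groups):
        rows = []
        for stop, qs in groups.items():
            for i, q in enumerate(qs):
                rows.append(
                    {"orf_id": f"{stop}{i}", "condition": "c", "Q": q,
                     "stop_codon": stop}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_h0_p1(self):
        h, p = rq.stop_identity_association(
            self._scores({"UAA": [1, 2, 3], "UAG": [1, 2, 3], "UGA": [1, 2, 3]})
        )
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        groups = {
            "UAA": rng.normal(3, 1, 50),
            "UAG": rng.normal(3, 1, 50),
            "UGA": rng.normal(103, 1, 50),
        }
        _, p = rq.stop_identity_association(self._scores(groups))
        assert p < 0.001

    def test_degenerate_grouping_is_an_error(self):
        with pytest.raises(RiboQueueError):
            rq.stop_identity_association(self._scores({"UAA": [1.0, 2.0]}))


class TestEndToEndRecovery:
    def test_kr_flagged_at_minus_one_and_control_clean(self):
        """Queuing on K/R-ending ORFs only: after Z-score selection, K and R
        at the last codon exceed the log-odds line; the no-queue control
        flags nothing."""
        found = {}
        for label, scale in [("queued", 1.0), ("control", 0.0)]:
            cfg = rq.SimConfig(n_orfs=400, seed=31)
            orfs, truth = rq.generate_annotation(cfg)
            aln, _ = rq.simulate_footprints(cfg, orfs, truth, seed=32, amplitude_scale=scale)
            tracks, _ = rq.assign_psites(
                aln, rq.default_offset_table(),
                {o.transcript_id: o.tx_len for o in orfs},
            )
            rq.normalize_rpm(tracks)
            scores = rq.score_all(
                {"x": tracks}, orfs, rq.QueuingConfig(min_coverage_rpm=0.0)
            )
            sel = rq.zscore_select(scores)
            by_id = {o.transcript_id: o for o in orfs}
            universe = [by_id[i] for i in scores["orf_id"].unique()]
            bg = rq.background_frequencies(universe, n_codons=7)
            fgw = [
                w for i in sel["orf_id"]
                if (w := cterm_window(by_id[i], 7)) is not None
            ]
            mat = rq.positional_logodds(fgw, bg)
            sig = mat.significant()
            found[label] = set(zip(sig["position"], sig["residue"]))
        assert {(-1, "K"), (-1, "R")} <= found["queued"]
        assert found["control"] == set()
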