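"""Exact Poisson tag-count test, BH adjustment, direction calls, consistency."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcscnet import (
    ThresholdConfig,
    bh_adjust,
    call_de,
    consistent_features,
    poisson_tagcount_p,
    tpm_normalize,
)

from _oracles import bh_oracle, poisson_p_oracle


class TestPoissonTagCountP:
    def test_symmetric_zero_case(self):
        """x=0, y=0, equal depths: lower tail is 1/2, doubled and capped -> 1."""
        assert poisson_tagcount_p(0, 0, 10**6, 10**6) == 1.0

    def test_against_direct_summation_oracle(self):
        assert poisson_tagcount_p(5, 0, 1e6, 1e6) == pytest.approx(
            poisson_p_oracle(5, 0, 1.0), abs=1e-15
        )
        rng = np.random.default_rng(11)
        for _ in range(200):
            x, y = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            r = float(rng.choice([0.5, 1.0, 2.0]))
            assert poisson_tagcount_p(x, y, 1e6, r * 1e6) == pytest.approx(
                poisson_p_oracle(x, y, r), abs=1e-12
            ), (x, y, r)

    def test_pmf_swap_identity(self):
        """P(X=x | y, 1/r) = r * P(Y=y | x, r): the point probabilities of the
        swapped problem rescale by the depth ratio (exactly symmetric at r=1).
        The doubled-tail p-value itself is endpoint-asymmetric, so symmetry is
        checked where it genuinely holds."""
        import itertools

        from _oracles import poisson_tail_terms

        def pmf(x, y, r):
            return next(itertools.islice(poisson_tail_terms(x, r), y, None))

        rng = np.random.default_rng(7)
        for _ in range(1000):
            x, y = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            r = float(rng.integers(1, 4)) / float(rng.integers(1, 4))
            assert pmf(y, x, 1.0 / r) == pytest.approx(r * pmf(x, y, r), rel=1e-9)
        # and at equal depths the pmf is symmetric in its two counts
        for x, y in [(0, 5), (3, 17), (20, 20)]:
            assert pmf(x, y, 1.0) == pytest.approx(pmf(y, x, 1.0), rel=1e-12)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            poisson_tagcount_p(1.5, 2, 1e6, 1e6)
        with pytest.raises(ValueError):
            poisson_tagcount_p(-1, 2, 1e6, 1e6)
        with pytest.raises(ValueError):
            poisson_tagcount_p(1, 2, 0, 1e6)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.8]), bh_oracle([0.005, 0.04, 0.8])
        )

    @settings(max_examples=100)
    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        seed=st.integers(0, 10**6),
    )
    def test_matches_oracle_and_permutation_consistent(self, ps, seed):
        adjusted = bh_adjust(ps)
        np.testing.assert_allclose(adjusted, bh_oracle(ps), atol=1e-12)
        perm = np.random.default_rng(seed).permutation(len(ps))
        np.testing.assert_allclose(bh_adjust(np.asarray(ps)[perm]), adjusted[perm], atol=1e-12)
        assert np.all(adjusted >= 0) and np.all(adjusted <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDe:
    def test_identical_counts_give_zero_fc_and_no_call(self, mirna_table):
        norm = tpm_normalize(mirna_table)
        calls = call_de(mirna_table, norm, ("s1-stem", "s1-cancer"), ThresholdConfig())
        row = calls[calls.feature_id == "mir-a"].iloc[0]
        assert row.log2fc == 0.0
        assert row.direction == "none"

    def test_planted_fourfold_feature_called_up(self, mirna_table):
        norm = tpm_normalize(mirna_table)
        calls = call_de(mirna_table, norm, ("s1-stem", "s1-cancer"), ThresholdConfig())
        assert calls[calls.feature_id == "mir-b"].iloc[0].direction == "up"

    def test_boundaries_are_inclusive(self):
        """|log2fc| exactly at threshold with fdr exactly at threshold is a call."""
        from hcscnet.diffexpr import _direction

        direction = _direction(
            np.array([1.0, -1.0, 0.99]), np.array([0.01, 0.01, 0.01]), ThresholdConfig()
        )
        assert list(direction) == ["up", "down", "none"]

    def test_unknown_sample_rejected(self, mirna_table):
        norm = tpm_normalize(mirna_table)
        with pytest.raises(ValueError, match="unknown sample"):
            call_de(mirna_table, norm, ("s1-stem", "nope"), ThresholdConfig())


def _calls(universe, up=(), down=()):
    return pd.DataFrame(
        {
            "feature_id": list(universe),
            "direction": [
                "up" if f in up else "down" if f in down else "none" for f in universe
            ],
        }
    )


class TestConsistentFeatures:
    def test_disjoint_pairs_yield_empty(self):
        sets = consistent_features(
            _calls("abc", up={"a"}), _calls("abc", up={"b"})
        )
        assert sets.up_features == frozenset()

    def test_discordant_feature_excluded(self):
        sets = consistent_features(
            _calls("abc", up={"a"}), _calls("abc", down={"a"})
        )
        assert "a" not in sets.all_features

    def test_mismatched_universe_reports_difference(self):
        with pytest.raises(ValueError, match="d"):
            consistent_features(_calls("abc"), _calls("abd"))

    @settings(max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"f{i}" for i in range(rng.integers(1, 40))]
        tables = []
        for _ in range(2):
            dirs = rng.choice(["up", "down", "none"], size=len(universe))
            tables.append(pd.DataFrame({"feature_id": universe, "direction": dirs}))
        sets = consistent_features(*tables)
        d1 = dict(zip(tables[0].feature_id, tables[0].direction))
        d2 = dict(zip(tables[1].feature_id, tables[1].direction))
        brute = sum(
            1 for f in universe if d1[f] == d2[f] and d1[f] in ("up", "down")
        )
        assert len(sets.up_features) + len(sets.down_features) == brute
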