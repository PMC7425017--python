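"""Empirical null, local FDR, FTR gating and equal-score merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sifcall.calling import (
    FdrTable, SIF, build_fdr_table, call_sifs, empirical_null, local_fdr,
    merge_equal_score, read_sif_bedpe, tp_density, write_sif_bedpe,
)
from sifcall.mixture import PoissonMixture

from conftest import TOY_LENGTHS


def _model(lam1=1.0, lam2=8.0, w2=0.1):
    m = PoissonMixture()
    m.weights_ = np.array([1 - w2, w2])
    m.lambdas_ = np.array([lam1, lam2])
    m.converged_ = True
    m.degenerate_ = False
    return m


class TestEmpiricalNull:
    def test_point_mass(self):
        null = empirical_null([4] * 20, n_resample=500, seed=0)
        assert null.index.tolist() == [4]
        assert null.iloc[0] == 1.0

    def test_single_draw_is_indicator(self):
        null = empirical_null([1, 8, 3], n_resample=1, seed=5)
        assert len(null) == 1 and null.iloc[0] == 1.0
        assert null.index[0] in {1, 8, 3}

    def test_binomial_oracle(self):
        """Null density at score 1 matches the multiset fraction within 3 SE."""
        scores = np.array([1] * 900 + [8] * 100)
        np_draws = 50_000
        null = empirical_null(scores, n_resample=np_draws, seed=2)
        se = np.sqrt(0.9 * 0.1 / np_draws)
        assert abs(null.loc[1] - 0.9) < 3 * se

    def test_empty_records(self):
        with pytest.raises(ValueError):
            empirical_null([], n_resample=10)


class TestTpDensity:
    def test_pmf_value(self):
        import math
        tp = tp_density(_model(lam2=8.0))
        assert tp.loc[8] == pytest.approx(np.exp(-8) * 8**8 / math.factorial(8))
        assert tp.loc[8] == pytest.approx(0.1396, abs=5e-5)

    def test_normalization_and_mode(self):
        tp = tp_density(_model(lam2=8.0))
        assert tp.sum() == pytest.approx(1.0, abs=1e-9)
        assert tp.loc[7] == pytest.approx(tp.loc[8])       # Poisson mode tie
        assert tp.loc[7] == tp.max()

    def test_indistinct_components_rejected(self):
        with pytest.raises(ValueError):
            tp_density(_model(lam1=4.0, lam2=4.0))


class TestLocalFdr:
    @pytest.mark.parametrize("fp,tp,expected", [
        (0.0, 0.2, 0.0),
        (0.1, 0.1, 0.5),
        (0.03, 0.12, 0.2),
    ])
    def test_arithmetic(self, fp, tp, expected):
        fp_s = pd.Series({5: fp})
        tp_s = pd.Series({5: tp})
        assert local_fdr(5, fp_s, tp_s) == pytest.approx(expected)

    def test_undefined(self):
        with pytest.raises(ValueError):
            local_fdr(5, pd.Series({5: 0.0}), pd.Series({5: 0.0}))

    def test_monotone_on_fitted_model(self):
        """FDR decreases over the upper score tail of a fitted mixture."""
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.poisson(1, 9000) + 1, rng.poisson(8, 1000)])
        model = PoissonMixture().fit(scores)
        table = build_fdr_table(scores, model, n_resample=2_000_000, seed=8)
        upper = table.table.loc[4:11, "fdr"].dropna()
        # tolerance covers residual resampling noise of the empirical null
        assert np.all(np.diff(upper.to_numpy()) <= 2e-3)


class TestCallSifs:
    def _table_passing_all(self, max_score=20):
        support = np.arange(max_score + 1)
        tab = pd.DataFrame({"fp": 0.0, "tp": 1.0, "fdr": 0.0}, index=support)
        return FdrTable(table=tab, n_resample=1)

    def test_worked_example(self, toy_records):
        """FTR=3 discards the score-3 random ligation, keeps the other 3."""
        out = call_sifs(toy_records, ftr=3, fdr_threshold=0.1,
                        fdr_table=self._table_passing_all())
        kept = set(zip(out["idx1"], out["idx2"]))
        assert kept == {(0, 7), (1, 6), (2, 4)}

    def test_infinite_ftr(self, toy_records):
        out = call_sifs(toy_records, ftr=10**9, fdr_threshold=1.0,
                        fdr_table=self._table_passing_all())
        assert len(out) == 0

    def test_matches_brute_force_double_filter(self):
        """1000 synthetic records vs exhaustive enumeration of both gates."""
        rng = np.random.default_rng(55)
        rec = pd.DataFrame({
            "chrom1": "c", "idx1": rng.integers(0, 500, 1000),
            "chrom2": "c", "idx2": rng.integers(500, 1000, 1000),
            "score": rng.integers(1, 15, 1000),
        })
        support = np.arange(16)
        fdr_vals = rng.random(16)
        tab = pd.DataFrame({"fp": 0.1, "tp": 0.1, "fdr": fdr_vals}, index=support)
        table = FdrTable(table=tab, n_resample=1)
        ftr, cutoff = 4, 0.5
        out = call_sifs(rec, ftr, cutoff, table)
        expected = [(r.idx1, r.idx2) for r in rec.itertuples()
                    if r.score > ftr and fdr_vals[r.score] < cutoff]
        assert list(zip(out["idx1"], out["idx2"])) == expected

    def test_filter_conservation(self, toy_records):
        table = self._table_passing_all()
        out = call_sifs(toy_records, 3, 0.1, table)
        discarded = len(toy_records) - len(out)
        assert len(out) + discarded == len(toy_records)

    def test_tail_inherits_last_fdr(self):
        tab = pd.DataFrame({"fp": [0.1, 0.05], "tp": [0.1, 0.2],
                            "fdr": [0.5, 0.2]}, index=[1, 2])
        table = FdrTable(table=tab, n_resample=1)
        assert table.fdr(100) == 0.2


class TestMerging:
    def _calls(self, toy_map, interactions):
        rows = [("chrT", i, "chrT", j, s, 0.01) for i, j, s in interactions]
        return pd.DataFrame(rows, columns=["chrom1", "idx1", "chrom2", "idx2",
                                           "score", "fdr"])

    def test_worked_example_resolutions(self, toy_map):
        """F1-F8 + F2-F7 (score 4) merge to resolution (L1+L2, L7+L8);
        F3-F5 (score 5) stays single with resolution (L3, L5)."""
        calls = self._calls(toy_map, [(0, 7, 4), (1, 6, 4), (2, 4, 5)])
        sifs = merge_equal_score(calls, toy_map)
        assert len(sifs) == 2
        by_score = {s.score: s for s in sifs}
        merged = by_score[4]
        assert merged.resolution1 == TOY_LENGTHS[0] + TOY_LENGTHS[1]
        assert merged.resolution2 == TOY_LENGTHS[6] + TOY_LENGTHS[7]
        assert merged.fragments1 == [0, 1] and merged.fragments2 == [6, 7]
        single = by_score[5]
        assert single.resolution1 == TOY_LENGTHS[2]
        assert single.resolution2 == TOY_LENGTHS[4]

    def test_no_adjacent_calls_pass_through(self, toy_map):
        calls = self._calls(toy_map, [(0, 4, 3), (2, 7, 3), (5, 1, 9)])
        calls.loc[2, ["idx1", "idx2"]] = [1, 5]
        sifs = merge_equal_score(calls, toy_map)
        assert len(sifs) == 3

    def test_unequal_scores_do_not_merge(self, toy_map):
        calls = self._calls(toy_map, [(0, 7, 4), (1, 6, 5)])
        assert len(merge_equal_score(calls, toy_map)) == 2

    def test_transitive_merge(self, toy_map):
        calls = self._calls(toy_map, [(0, 7, 4), (1, 6, 4), (2, 5, 4)])
        sifs = merge_equal_score(calls, toy_map)
        assert len(sifs) == 1
        assert sifs[0].fragments1 == [0, 1, 2]
        assert sifs[0].fragments2 == [5, 6, 7]

    def test_merged_score_is_shared_score(self, toy_map):
        calls = self._calls(toy_map, [(0, 7, 4), (1, 6, 4)])
        assert merge_equal_score(calls, toy_map)[0].score == 4


def test_sif_bedpe_round_trip(tmp_path, toy_map):
    calls = pd.DataFrame([("chrT", 0, "chrT", 7, 4, 0.02)],
                         columns=["chrom1", "idx1", "chrom2", "idx2",
                                  "score", "fdr"])
    sifs = merge_equal_score(calls, toy_map)
    path = tmp_path / "sifs.bedpe"
    write_sif_bedpe(sifs, path)
    again = read_sif_bedpe(path)
    assert len(again) == 1
    assert (again[0].start1, again[0].end1) == (sifs[0].start1, sifs[0].end1)
    assert again[0].score == 4 and again[0].fdr == pytest.approx(0.02)
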