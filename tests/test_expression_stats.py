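import math

import numpy as np
import pandas as pd
import pytest

from acetrank.expression_stats import (
    bh_fdr,
    cpm,
    de_table,
    group_expression_shift,
    mean_replicate_fc,
    rank_correlation,
    welch_t,
)
from acetrank.io_formats import GenomicInterval
from acetrank.preference import PreferenceRecord


def counts_frame(data, samples):
    return pd.DataFrame(data, columns=samples, index=[f"g{i}" for i in range(len(data))])


class TestCpm:
    def test_closed_form(self):
        df = counts_frame([[100], [900]], ["s1"])
        out = cpm(df)
        assert out["s1"].tolist() == [1e5, 9e5]

    def test_all_zero_gene_stays_zero(self):
        df = counts_frame([[0, 0], [10, 20]], ["s1", "s2"])
        assert cpm(df).loc["g0"].tolist() == [0.0, 0.0]

    def test_scale_invariance(self):
        df = counts_frame([[3, 5], [7, 11]], ["s1", "s2"])
        assert np.allclose(cpm(df).values, cpm(df * 2).values)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(counts_frame([[0], [0]], ["s1"]))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_step_up_worked_example(self):
        # q(i) = min_{j>=i} p(j)*m/j: all collapse to 0.04*4/4 = 0.04
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_bounds_and_sorted_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_hand_computation(self):
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert round(res.t, 3) == -3.674
        assert round(res.df) == 4
        assert 0 < res.p < 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        assert math.isclose(welch_t(x, y).t, welch_t(x * 3.7, y * 3.7).t)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(2, 30)))
            y = rng.normal(0.5, 2, int(rng.integers(2, 30)))
            res = welch_t(x, y)
            se = math.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
            assert math.isclose(res.t, (x.mean() - y.mean()) / se, rel_tol=1e-12)

    def test_constant_equal_samples(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestRankCorrelation:
    def test_monotone_pairs(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert rank_correlation([1, 2, 3, 4], [40, 30, 20, 10]) == -1.0

    def test_average_rank_ties(self):
        assert math.isclose(
            rank_correlation([1, 2, 2, 3], [10, 20, 20, 40]), 1.0
        )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(1, 10, 50), rng.uniform(1, 10, 50)
        rho = rank_correlation(a, b)
        assert math.isclose(rank_correlation(np.exp(a), b**3), rho)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(rank_correlation([1, 1, 1], [1, 2, 3]))


class TestDeTable:
    def test_identical_conditions_all_ns(self):
        rng = np.random.default_rng(4)
        block = rng.poisson(100, (50, 2))
        df = counts_frame(np.hstack([block, block]), ["c1", "c2", "t1", "t2"])
        de = de_table(df, ["c1", "c2"], ["t1", "t2"])
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["de_class"] == "ns").all()

    def test_overlapping_sample_groups_rejected(self):
        df = counts_frame([[1, 2, 3]], ["a", "b", "c"])
        with pytest.raises(ValueError):
            de_table(df, ["a", "b"], ["b", "c"])

    def test_single_replicate_gives_fc_only(self):
        df = counts_frame([[100, 400], [200, 200]], ["c1", "t1"])
        de = de_table(df, ["c1"], ["t1"])
        assert de["p"].isna().all()
        assert (de["de_class"] == "ns").all()
        assert de.loc["g0", "log2fc"] > 0

    def test_planted_downregulation_recovery(self):
        """100/1000 genes with a true 2-fold decrease, NB dispersion 0.1,
        3 vs 3 replicates.  The Welch-on-log-CPM stand-in estimates the
        effects accurately and makes no false calls; with df ~ 4 it is
        deliberately conservative at FDR 0.05, so recall is checked at the
        nominal-p + fold-change operating point."""
        rng = np.random.default_rng(20240601)
        m, ntrue, nrep, disp = 1000, 100, 3, 0.1
        base = rng.lognormal(np.log(300), 1.0, m)
        lfc = np.zeros(m)
        lfc[:ntrue] = -1.0
        r = 1 / disp
        def nb(mu, size):
            p = r / (r + mu)
            return rng.negative_binomial(r, p[:, None], (len(mu), size))
        df = counts_frame(
            np.hstack([nb(base, nrep), nb(base * 2.0**lfc, nrep)]),
            [f"c{i}" for i in range(nrep)] + [f"t{i}" for i in range(nrep)],
        )
        de = de_table(df, [f"c{i}" for i in range(nrep)], [f"t{i}" for i in range(nrep)])
        planted = de.iloc[:ntrue]
        null = de.iloc[ntrue:]
        assert abs(planted["log2fc"].mean() + 1.0) < 0.1
        assert (null["de_class"] == "down").sum() == 0  # no false discoveries
        nominal = (planted["p"] < 0.05) & (planted["log2fc"] < -0.5)
        assert nominal.mean() >= 0.3


class TestGroupShift:
    def _records(self, genes_by_group):
        records = []
        pos = 0
        for group, genes in genes_by_group.items():
            for g in genes:
                records.append(
                    PreferenceRecord(
                        GenomicInterval("chr1", pos, pos + 100),
                        1.0, 1.0, 0.0, group, "promoter", (g,),
                    )
                )
                pos += 1000
        return records

    def _de(self, logfc_by_gene):
        return pd.DataFrame(
            {"log2fc": list(logfc_by_gene.values())},
            index=pd.Index(list(logfc_by_gene), name="gene_id"),
        )

    def test_no_shift_gives_t_zero(self):
        records = self._records({6: ["a", "b"], 1: ["c", "d"]})
        de = self._de({"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0})
        assert group_expression_shift(records, de, 6, 1).t == 0.0

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(5)
        genes6 = [f"x{i}" for i in range(30)]
        genes1 = [f"y{i}" for i in range(30)]
        records = self._records({6: genes6, 1: genes1})
        de = self._de(
            {**{g: v for g, v in zip(genes6, rng.normal(-1, 0.3, 30))},
             **{g: v for g, v in zip(genes1, rng.normal(0, 0.3, 30))}}
        )
        fwd = group_expression_shift(records, de, 6, 1)
        rev = group_expression_shift(records, de, 1, 6)
        assert math.isclose(fwd.t, -rev.t)
        assert fwd.t < 0 and fwd.p < 0.01
        assert fwd.group_x == 6 and fwd.group_y == 1

    def test_gene_contributes_once_per_group(self):
        records = self._records({6: ["a", "b"], 1: ["c", "d"]})
        records += self._records({6: ["a"]})  # duplicate association
        de = self._de({"a": -2.0, "b": 0.0, "c": 0.5, "d": -0.5})
        res = group_expression_shift(records, de, 6, 1)
        assert res.n_x == 2  # 'a' counted once

    def test_empty_group_rejected(self):
        records = self._records({6: ["a", "b"]})
        de = self._de({"a": 0.0, "b": 0.0})
        with pytest.raises(ValueError, match="empty group"):
            group_expression_shift(records, de, 6, 1)


def test_mean_replicate_fc_averages_per_gene():
    out = mean_replicate_fc([{"a": 1.0, "b": 2.0}, {"a": 3.0}])
    assert out == {"a": 2.0, "b": 2.0}
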