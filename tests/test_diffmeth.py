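"""Promoter aggregation, batch normalization, BH, and KS behavior."""

import numpy as np
import pandas as pd
import pytest

from graftage.diffmeth import (
    PromoterMethylation,
    aggregate_promoters,
    batch_normalize,
    benjamini_hochberg,
    gene_set_ks,
    global_mean_compare,
    promoter_tests,
)
from graftage.errors import ValidationError
from graftage.io import BetaMatrix, GeneSetCollection, PromoterMap


def _bm(arr, samples=None, cpgs=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    cpgs = cpgs or [f"cg{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=samples, columns=cpgs))


def _pmap(pairs):
    rows = [(cpg, gene, "chr1", 0, 10, "+") for cpg, gene in pairs]
    return PromoterMap(pd.DataFrame(rows, columns=PromoterMap.COLUMNS))


class TestGlobalMean:
    def test_constant_matrix(self):
        bm = _bm(np.full((6, 4), 0.5))
        means, p = global_mean_compare(bm, [0, 0, 0, 1, 1, 1])
        assert means["control"] == means["case"] == 0.5
        assert p == 1.0

    def test_uniform_shift_perfectly_separates(self):
        base = np.tile(np.linspace(0.2, 0.8, 10), (20, 1))
        base[10:] += 0.1
        means, p = global_mean_compare(_bm(base), [0] * 10 + [1] * 10)
        assert means["case"] - means["control"] == pytest.approx(0.1)
        assert p < 1e-12


class TestAggregation:
    def test_single_cpg_promoter_passthrough(self):
        bm = _bm([[0.3], [0.6]])
        pm = aggregate_promoters(bm, _pmap([("cg0", "G1")]))
        assert pm.values["G1"].tolist() == [0.3, 0.6]

    def test_mean_of_two_cpgs(self):
        bm = _bm([[0.2, 0.4]])
        pm = aggregate_promoters(bm, _pmap([("cg0", "G1"), ("cg1", "G1")]))
        assert pm.values.loc["S0", "G1"] == pytest.approx(0.3)

    def test_overlapping_promoters_share_cpg(self):
        bm = _bm([[0.2, 0.4]])
        pm = aggregate_promoters(
            bm, _pmap([("cg0", "G1"), ("cg1", "G1"), ("cg1", "G2")]))
        assert pm.values.loc["S0", "G2"] == pytest.approx(0.4)
        assert pm.values.loc["S0", "G1"] == pytest.approx(0.3)

    def test_empty_overlap_is_error(self):
        bm = _bm([[0.2]])
        with pytest.raises(ValidationError):
            aggregate_promoters(bm, _pmap([("other", "G1")]))


class TestBatchNormalize:
    def test_single_batch_noop(self):
        pm = PromoterMethylation(
            pd.DataFrame({"G1": [0.2, 0.4]}, index=["a", "b"]),
            batch=pd.Series(["b1", "b1"], index=["a", "b"]))
        out = batch_normalize(pm)
        assert out.values.equals(pm.values)

    def test_offset_batches_equalized(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.3, 0.6, size=(10, 5))
        shifted = np.vstack([base, base + 0.1])
        pm = PromoterMethylation(
            pd.DataFrame(shifted, index=[f"s{i}" for i in range(20)],
                         columns=[f"G{j}" for j in range(5)]),
            batch=pd.Series(["b1"] * 10 + ["b2"] * 10,
                            index=[f"s{i}" for i in range(20)]))
        out = batch_normalize(pm)
        b1 = out.values.iloc[:10].mean()
        b2 = out.values.iloc[10:].mean()
        assert np.allclose(b1, b2, atol=1e-12)
        # per-promoter grand mean preserved
        assert np.allclose(out.values.mean(), pm.values.mean(), atol=1e-12)

    def test_group_contrast_preserved_when_balanced(self):
        """With groups balanced across batches, location normalization
        must not move the within-batch group difference."""
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.5, size=(16, 3))
        group = np.tile([0, 0, 1, 1], 4)
        base[group == 1] += 0.05
        batch = np.repeat(["b1", "b2"], 8)
        base[batch == "b2"] += 0.1
        idx = [f"s{i}" for i in range(16)]
        pm = PromoterMethylation(
            pd.DataFrame(base, index=idx, columns=["G1", "G2", "G3"]),
            batch=pd.Series(batch, index=idx))
        out = batch_normalize(pm)
        diff_before = (base[group == 1].mean(axis=0)
                       - base[group == 0].mean(axis=0))
        diff_after = (out.values.to_numpy()[group == 1].mean(axis=0)
                      - out.values.to_numpy()[group == 0].mean(axis=0))
        assert np.allclose(diff_before, diff_after, atol=1e-12)

    def test_single_sample_batch_rejected(self):
        pm = PromoterMethylation(
            pd.DataFrame({"G1": [0.2, 0.4, 0.5]}, index=["a", "b", "c"]),
            batch=pd.Series(["b1", "b1", "b2"], index=["a", "b", "c"]))
        with pytest.raises(ValidationError, match="single-sample"):
            batch_normalize(pm)


class TestPromoterTests:
    def test_single_promoter_q_equals_p(self):
        rng = np.random.default_rng(0)
        pm = PromoterMethylation(pd.DataFrame(
            {"G1": rng.uniform(0.2, 0.8, 10)},
            index=[f"s{i}" for i in range(10)]))
        dm = promoter_tests(pm, [0] * 5 + [1] * 5)
        row = dm.table.iloc[0]
        assert row["q"] == pytest.approx(row["p"])

    def test_sign_convention_case_hypomethylated(self):
        vals = np.vstack([np.full((5, 1), 0.6), np.full((5, 1), 0.4)])
        vals = vals + np.linspace(0, 0.01, 10)[:, None]
        pm = PromoterMethylation(pd.DataFrame(
            vals, index=[f"s{i}" for i in range(10)], columns=["G1"]))
        dm = promoter_tests(pm, [0] * 5 + [1] * 5)
        assert dm.table.iloc[0]["t"] < 0  # lower in exposed group

    def test_degenerate_promoter_excluded_from_bh(self):
        vals = np.column_stack([np.full(8, 0.5),
                                np.linspace(0.2, 0.8, 8)])
        pm = PromoterMethylation(pd.DataFrame(
            vals, index=[f"s{i}" for i in range(8)], columns=["G1", "G2"]))
        dm = promoter_tests(pm, [0] * 4 + [1] * 4)
        tab = dm.table.set_index("gene")
        assert np.isnan(tab.loc["G1", "p"])
        assert tab.loc["G2", "q"] == pytest.approx(tab.loc["G2", "p"])

    def test_null_fdr_calibration(self):
        """With no group effect, promoters passing q < 0.05 are rare."""
        clean = 0
        for k in range(20):
            rng = np.random.default_rng(k)
            pm = PromoterMethylation(pd.DataFrame(
                rng.uniform(0.2, 0.8, size=(16, 500)),
                index=[f"s{i}" for i in range(16)],
                columns=[f"G{j}" for j in range(500)]))
            dm = promoter_tests(pm, [0] * 8 + [1] * 8)
            clean += int((dm.table["q"] < 0.05).sum() == 0)
        assert clean >= 19


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_nan_excluded_from_family(self):
        q = benjamini_hochberg([0.02, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.04)  # m = 2, not 3

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = int(rng.integers(1, 100))
            p = rng.uniform(size=m)
            q = benjamini_hochberg(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                oracle[i] = min(running, 1.0)
            assert np.allclose(q, oracle, atol=1e-12)


class TestGeneSetKS:
    def _dm(self, genes, tvals):
        return_table = pd.DataFrame({
            "gene": genes, "mean_control": 0.5, "mean_case": 0.5,
            "t": tvals, "p": np.full(len(genes), 0.5),
            "q": np.full(len(genes), 0.5)})
        from graftage.diffmeth import DiffMethTable
        return DiffMethTable(return_table)

    def test_separated_sets_have_d_one_exact_p(self):
        dm = self._dm(["A", "B", "C", "D", "E", "F"],
                      [-2.0, -1.0, -1.5, 1.0, 2.0, 1.5])
        sets = GeneSetCollection({"DOWN": ["A", "B", "C"]})
        res = gene_set_ks(dm, sets, q_threshold=1.1)
        assert res[0].statistic == 1.0
        assert res[0].direction == "hypo"
        # exact two-sided p for complete separation of 3 vs 3: 2/C(6,3)
        assert res[0].p == pytest.approx(0.1, abs=1e-9)

    def test_identical_distributions_d_zero(self):
        dm = self._dm(["A", "B", "C", "D", "E", "F"],
                      [1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        sets = GeneSetCollection({"SAME": ["A", "B", "C"]})
        res = gene_set_ks(dm, sets, q_threshold=1.1)
        assert res[0].statistic == pytest.approx(0.0)

    def test_small_sets_skipped_with_warning(self):
        dm = self._dm(["A", "B", "C", "D"], [1.0, 2.0, 3.0, 4.0])
        sets = GeneSetCollection({"TINY": ["A"], "OK": ["A", "B", "C"]})
        with pytest.warns(UserWarning, match="TINY"):
            res = gene_set_ks(dm, sets, q_threshold=1.1)
        assert [r.name for r in res] == ["OK"]

    def test_d_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        from scipy.stats import ks_2samp
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 50))
            b = rng.normal(size=rng.integers(3, 50))
            pooled = np.concatenate([a, b])
            d_oracle = max(
                abs((a <= v).mean() - (b <= v).mean()) for v in pooled)
            assert ks_2samp(a, b).statistic == pytest.approx(d_oracle,
                                                             abs=1e-12)

    def test_sample_permutation_equivariance(self, default_cohort):
        """Permuting sample order changes no promoter statistic."""
        cohort = default_cohort
        g = cohort.samples.data["pgd"].to_numpy()
        pm = aggregate_promoters(cohort.betas, cohort.promoters)
        dm = promoter_tests(pm, g)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(g))
        pm2 = PromoterMethylation(pm.values.iloc[perm])
        dm2 = promoter_tests(pm2, g[perm])
        assert np.allclose(dm.table["t"], dm2.table["t"], atol=1e-10,
                           equal_nan=True)
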