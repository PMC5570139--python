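"""Differential-expression scores, selection, and RIF statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regtrail import (
    DEScoreTable, ExpressionMatrix, GroupDesign, InputError, de_score,
    rif_scores, select_regulated,
)
from regtrail.expression import DE_METHODS


def _matrix(values, genes=None, n_case=None, paired=False):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    n_case = n_case if n_case is not None else values.shape[1] // 2
    samples = [f"c{i}" for i in range(n_case)] + [
        f"k{i}" for i in range(values.shape[1] - n_case)
    ]
    df = pd.DataFrame(values, index=genes, columns=samples)
    em = ExpressionMatrix(df)
    design = GroupDesign(tuple(samples[:n_case]), tuple(samples[n_case:]), paired)
    return em, design


class TestDeScores:
    def test_log_fold_change_is_mean_difference(self):
        em, design = _matrix([[4, 4, 2, 2], [4, 4, 2, 2]])
        tbl = de_score(em, design, "log2_fold_change")
        np.testing.assert_allclose(tbl.scores().to_numpy(), [2.0, 2.0])

    @pytest.mark.parametrize("method", [m for m in DE_METHODS if m != "wilcoxon_signed"])
    def test_identical_groups_score_zero(self, method, rng):
        block = rng.normal(size=(6, 5))
        em, design = _matrix(np.hstack([block, block]), paired=True)
        tbl = de_score(em, design, method)
        np.testing.assert_allclose(tbl.scores().to_numpy(), 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "method", ["log2_fold_change", "zscore", "snr", "t_independent",
                   "wilcoxon_ranksum", "shrinkage_t"]
    )
    def test_antisymmetric_under_group_swap(self, method, rng):
        em, design = _matrix(rng.normal(size=(10, 12)))
        swapped = GroupDesign(design.control_samples, design.case_samples)
        a = de_score(em, design, method).scores().to_numpy()
        b = de_score(em, swapped, method).scores().to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_equal_variances_collapse_shrinkage_to_pooled_t(self, rng):
        """When all per-gene pooled variances are equal, the shrinkage
        target coincides with each gene's variance, so the statistic equals
        the classical pooled two-sample t (independent oracle)."""
        n1 = n2 = 6
        base = rng.normal(size=n1 + n2)
        base = (base - base.mean()) / base.std(ddof=1)  # unit sample variance
        shifts = rng.normal(size=8)
        data = np.vstack([base + s * np.r_[np.ones(n1), np.zeros(n2)] for s in shifts])
        em, design = _matrix(data, n_case=n1)
        got = de_score(em, design, "shrinkage_t").scores().to_numpy()
        for g in range(data.shape[0]):
            t_oracle = stats.ttest_ind(data[g, :n1], data[g, n1:], equal_var=True).statistic
            assert got[g] == pytest.approx(t_oracle, abs=1e-9)

    def test_wilcoxon_depends_only_on_ranks(self, rng):
        em, design = _matrix(np.abs(rng.normal(size=(8, 10))) + 0.1)
        a = de_score(em, design, "wilcoxon_ranksum").scores().to_numpy()
        em2 = ExpressionMatrix(np.exp(em.values * 3))  # strictly monotone
        b = de_score(em2, design, "wilcoxon_ranksum").scores().to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_welch_matches_scipy(self, rng):
        em, design = _matrix(rng.normal(size=(5, 9)), n_case=4)
        got = de_score(em, design, "t_independent").scores().to_numpy()
        case = em.values.iloc[:, :4].to_numpy()
        ctrl = em.values.iloc[:, 4:].to_numpy()
        want = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).statistic
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_spread_reported_not_dropped(self):
        em, design = _matrix([[1, 1, 1, 1], [1, 2, 3, 4]])
        tbl = de_score(em, design, "zscore")
        assert np.isnan(tbl.scores()["g0"])
        assert "undefined" in tbl.table.set_index("gene_id").loc["g0", "note"]
        assert len(tbl.table) == 2

    def test_paired_method_requires_paired_design(self):
        em, design = _matrix(np.arange(8.0).reshape(2, 4))
        with pytest.raises(InputError, match="paired"):
            de_score(em, design, "t_dependent")


class TestSelection:
    def _table(self, scores, genes=None):
        genes = genes or [f"g{i}" for i in range(len(scores))]
        return DEScoreTable(
            pd.DataFrame({"gene_id": genes, "score": scores, "note": ""}), "test"
        )

    def test_top_one_upper_tail(self):
        assert select_regulated(self._table([3, 1, -2]), "upper_tail", top_k=1) == ["g0"]

    def test_cutoff_zero_keeps_positive(self):
        got = select_regulated(self._table([3, 1, -2, 0]), "upper_tail", cutoff=0)
        assert got == ["g0", "g1"]

    def test_top_k_clamps_and_ties_break_by_id(self):
        tbl = self._table([1.0, 1.0, 1.0], ["b", "a", "c"])
        assert select_regulated(tbl, "upper_tail", top_k=10) == ["a", "b", "c"]
        assert select_regulated(tbl, "upper_tail", top_k=2) == ["a", "b"]

    def test_lower_tail_and_empty_selection(self):
        tbl = self._table([3, 1, 2])
        assert select_regulated(tbl, "lower_tail", top_k=1) == ["g1"]
        with pytest.raises(InputError, match="empty"):
            select_regulated(tbl, "lower_tail", cutoff=-5)


def _rif_oracle(expr, design, regulators, de_genes):
    """Straight-loop reference implementation of RIF1/RIF2."""
    case = expr.values[list(design.case_samples)]
    ctrl = expr.values[list(design.control_samples)]
    out = {}
    for reg in regulators:
        rif1 = rif2 = 0.0
        for g in de_genes:
            e1 = case.loc[g].mean()
            e2 = ctrl.loc[g].mean()
            r1 = np.corrcoef(case.loc[reg], case.loc[g])[0, 1]
            r2 = np.corrcoef(ctrl.loc[reg], ctrl.loc[g])[0, 1]
            pif = 0.5 * (e1 + e2) * (e1 - e2)
            rif1 += pif * (r1 - r2) ** 2
            rif2 += (e1 * r1) ** 2 - (e2 * r2) ** 2
        out[reg] = (rif1 / len(de_genes), rif2 / len(de_genes))
    return out


class TestRif:
    def _random_input(self, rng, n_genes=10, n_regs=3, n=6):
        genes = [f"g{i}" for i in range(n_genes)]
        regs = [f"r{i}" for i in range(n_regs)]
        data = rng.normal(5, 2, size=(n_genes + n_regs, 2 * n))
        df = pd.DataFrame(data, index=genes + regs,
                          columns=[f"s{i}" for i in range(2 * n)])
        em = ExpressionMatrix(df)
        design = GroupDesign(tuple(df.columns[:n]), tuple(df.columns[n:]))
        return em, design, regs, genes

    @staticmethod
    def _pair_with_exact_corr(rng, n, r, gene_mean):
        """(regulator, gene) sample vectors with exactly Pearson r and the
        requested gene mean, built from an orthonormal centered basis."""
        a, b = rng.normal(size=(2, n))
        u = a - a.mean()
        u /= np.linalg.norm(u)
        v = b - b.mean()
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        reg = u + 3.0
        gene = r * u + np.sqrt(1 - r * r) * v + gene_mean
        return reg, gene

    def test_hand_computed_single_pair(self, rng):
        """One regulator, one DE gene with e1=2, e2=1, r1=0.9, r2=0.1:
        PIF=1.5, RIF1=1.5*0.8^2=0.96, RIF2=1.8^2-0.1^2=3.23."""
        n = 8
        reg_case, gene_case = self._pair_with_exact_corr(rng, n, 0.9, 2.0)
        reg_ctrl, gene_ctrl = self._pair_with_exact_corr(rng, n, 0.1, 1.0)
        df = pd.DataFrame(
            np.vstack([np.r_[gene_case, gene_ctrl], np.r_[reg_case, reg_ctrl]]),
            index=["gene", "reg"],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        em = ExpressionMatrix(df)
        design = GroupDesign(tuple(df.columns[:n]), tuple(df.columns[n:]))
        (res,) = rif_scores(em, design, ["reg"], ["gene"])
        assert res.rif1_raw == pytest.approx(0.96, abs=1e-10)
        assert res.rif2_raw == pytest.approx(3.23, abs=1e-10)
        assert res.direction == "activating"

    def test_group_identical_data_gives_zero(self, rng):
        block = rng.normal(size=(5, 6))
        df = pd.DataFrame(np.hstack([block, block]),
                          index=[f"g{i}" for i in range(4)] + ["r0"],
                          columns=[f"s{i}" for i in range(12)])
        em = ExpressionMatrix(df)
        design = GroupDesign(tuple(df.columns[:6]), tuple(df.columns[6:]))
        (res,) = rif_scores(em, design, ["r0"], [f"g{i}" for i in range(4)])
        assert res.rif1_raw == pytest.approx(0.0, abs=1e-12)
        assert res.rif2_raw == pytest.approx(0.0, abs=1e-12)

    def test_matches_straight_loop_oracle(self, rng):
        for _ in range(10):
            em, design, regs, genes = self._random_input(rng)
            results = rif_scores(em, design, regs, genes)
            oracle = _rif_oracle(em, design, regs, genes)
            for res in results:
                want1, want2 = oracle[res.regulator]
                assert res.rif1_raw == pytest.approx(want1, abs=1e-10)
                assert res.rif2_raw == pytest.approx(want2, abs=1e-10)

    def test_z_columns_standardized(self, rng):
        em, design, regs, genes = self._random_input(rng, n_regs=5)
        results = rif_scores(em, design, regs, genes)
        z1 = np.array([r.rif1_z for r in results])
        z2 = np.array([r.rif2_z for r in results])
        assert z1.mean() == pytest.approx(0.0, abs=1e-12)
        assert z1.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert z2.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_rif_columns_antisymmetric_under_group_swap(self, rng):
        """Swapping case/control flips the sign of both RIF columns: the
        impact factor PIF changes sign while the squared correlation change
        is symmetric (RIF1), and RIF2's difference of squares reverses."""
        em, design, regs, genes = self._random_input(rng)
        swapped = GroupDesign(design.control_samples, design.case_samples)
        fwd = {r.regulator: r for r in rif_scores(em, design, regs, genes)}
        rev = {r.regulator: r for r in rif_scores(em, swapped, regs, genes)}
        for reg in regs:
            assert fwd[reg].rif1_raw == pytest.approx(-rev[reg].rif1_raw, abs=1e-10)
            assert fwd[reg].rif2_raw == pytest.approx(-rev[reg].rif2_raw, abs=1e-10)

    def test_direction_reflects_mean_correlation(self, rng):
        n = 30
        z = rng.normal(size=2 * n)
        gene = 0.9 * z + 0.1 * rng.normal(size=2 * n) + 5
        df = pd.DataFrame(np.vstack([gene, z + 5]), index=["g0", "r0"],
                          columns=[f"s{i}" for i in range(2 * n)])
        em = ExpressionMatrix(df)
        design = GroupDesign(tuple(df.columns[:n]), tuple(df.columns[n:]))
        (res,) = rif_scores(em, design, ["r0"], ["g0"])
        assert res.direction == "activating"
        df2 = df.copy()
        df2.loc["g0"] = -df.loc["g0"] + 10
        (res2,) = rif_scores(ExpressionMatrix(df2), design, ["r0"], ["g0"])
        assert res2.direction == "repressing"

    def test_validation_errors(self, rng):
        em, design, regs, genes = self._random_input(rng)
        with pytest.raises(InputError, match="nope"):
            rif_scores(em, design, ["nope"], genes)
        with pytest.raises(InputError):
            rif_scores(em, design, regs, [])

    def test_zero_variance_regulator_skipped_with_warning(self, rng):
        em, design, regs, genes = self._random_input(rng)
        df = em.values.copy()
        df.loc[regs[0]] = 1.0
        em2 = ExpressionMatrix(df)
        with pytest.warns(UserWarning, match=regs[0]):
            results = rif_scores(em2, design, regs, genes)
        assert {r.regulator for r in results} == set(regs[1:])
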