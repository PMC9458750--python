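"""Expression pipeline: RCC I/O, normalization, moderated t, set tests, Cox."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, polygamma
from scipy.stats import ttest_ind

from conftest import cox_grid_mle
from tcrbm.nanostring import (
    NormalizationParams,
    _membership_table,
    _odds_ratio,
    competitive_fisher,
    cox_per_gene,
    filter_gene_sets,
    global_significance,
    global_stat,
    moderated_t,
    moderated_t_group,
    normalize_counts,
    paired_timepoint_lme,
)
from tcrbm.types import ExpressionExperiment, GeneSet


def make_experiment(raw: dict[str, list], classes: dict[str, str], samples=None):
    genes = pd.DataFrame({"code_class": pd.Series(classes)})
    genes.index.name = "gene"
    raw_counts = pd.DataFrame(raw, index=genes.index)
    if samples is None:
        samples = pd.DataFrame(
            {
                "patient_id": [f"pt{i}" for i in range(raw_counts.shape[1])],
                "timepoint": "pre",
                "responder": False,
            },
            index=raw_counts.columns,
        )
        samples.index.name = "sample_id"
    return ExpressionExperiment(genes=genes, samples=samples, raw_counts=raw_counts)


TOY_CLASSES = {
    "POS_A": "Positive", "POS_B": "Positive",
    "NEG_A": "Negative", "NEG_B": "Negative",
    "ENDO1": "Endogenous", "HK1": "Housekeeping",
}
TOY_RAW = {
    "s1": [100, 100, 2, 4, 50, 20],
    "s2": [400, 400, 8, 16, 200, 80],
}


class TestNormalization:
    def test_hand_computed_two_sample_toy(self):
        """Frozen hand calculation of the full recipe on the 2-sample toy.

        Positive geomeans 100/400 give lane factors 2.5/0.625; the scaled
        negatives are {5,10} in both samples, so background = 7.5 +
        2*sd = 7.5 + 2*sqrt(12.5); the endogenous probe lands at
        125 - background in both samples and housekeeping factors are 1.
        """
        exp = normalize_counts(make_experiment(TOY_RAW, TOY_CLASSES))
        background = 7.5 + 2.0 * math.sqrt(12.5)
        expected_endo = 125.0 - background  # = 110.42893218813452
        pre_round = exp.meta["pre_round"]["all"]
        for s in ("s1", "s2"):
            assert pre_round.loc["ENDO1", s] == pytest.approx(expected_endo, abs=1e-12)
            assert pre_round.loc["HK1", s] == pytest.approx(50.0 - background, abs=1e-12)
        assert (exp.norm_log2.loc["ENDO1"] == np.log2(110.0)).all()  # rounded half away

    def test_identical_samples(self):
        """Equal samples: all factors are 1; output = log2(max(round(c-b),1))."""
        raw = {"s1": [100, 100, 2, 4, 50, 20], "s2": [100, 100, 2, 4, 50, 20]}
        exp = normalize_counts(make_experiment(raw, TOY_CLASSES))
        b = 3.0 + 2.0 * np.std([2, 4], ddof=1)
        assert exp.norm_log2.loc["ENDO1", "s1"] == pytest.approx(
            np.log2(max(np.floor(50 - b + 0.5), 1.0))
        )

    def test_exact_invariance_to_per_sample_scaling(self):
        """Scaling all of one sample's counts by c is inverted exactly.

        The lane factor cancels the sample's own scale to machine
        precision; with a data-driven count-scale reference the whole
        pre-log matrix moves by exactly the reference ratio (one global
        constant, so every between-sample/between-gene contrast is
        unchanged), and with a fixed reference the output is bit-identical.
        """
        from scipy.stats import gmean

        rng = np.random.default_rng(0)
        classes = {f"P{i}": "Positive" for i in range(4)}
        classes |= {f"N{i}": "Negative" for i in range(6)}
        classes |= {f"H{i}": "Housekeeping" for i in range(5)}
        classes |= {f"G{i}": "Endogenous" for i in range(30)}

        def lane():
            return (
                rng.integers(200, 5000, 4).tolist()
                + rng.integers(1, 20, 6).tolist()
                + rng.integers(300, 3000, 5).tolist()
                + rng.integers(50, 4000, 30).tolist()
            )

        raw = {f"s{j}": lane() for j in range(4)}
        scaled_raw = {k: list(v) for k, v in raw.items()}
        scaled_raw["s2"] = [3 * c for c in scaled_raw["s2"]]

        base = normalize_counts(make_experiment(raw, classes))
        scaled = normalize_counts(make_experiment(scaled_raw, classes))
        pos = [f"P{i}" for i in range(4)]
        g_base = np.array([gmean([raw[s][i] for i in range(4)]) for s in raw])
        g_scaled = np.array([gmean([scaled_raw[s][i] for i in range(4)]) for s in raw])
        k = g_scaled.mean() / g_base.mean()  # only the shared reference moves
        np.testing.assert_allclose(
            scaled.meta["pre_round"]["all"].to_numpy(),
            k * base.meta["pre_round"]["all"].to_numpy(),
            rtol=1e-12,
        )
        # pinning the count-scale reference makes the output exactly invariant
        ref = float(g_base.mean())
        base_fixed = normalize_counts(make_experiment(raw, classes), code_count_reference=ref)
        scaled_fixed = normalize_counts(
            make_experiment(scaled_raw, classes), code_count_reference=ref
        )
        pd.testing.assert_frame_equal(base_fixed.norm_log2, scaled_fixed.norm_log2)
        np.testing.assert_allclose(
            base_fixed.meta["pre_round"]["all"].to_numpy(),
            scaled_fixed.meta["pre_round"]["all"].to_numpy(),
            rtol=1e-12,
        )

    def test_missing_control_class_errors(self):
        classes = {k: v for k, v in TOY_CLASSES.items() if v != "Negative"}
        raw = {s: v[:2] + v[4:] for s, v in TOY_RAW.items()}
        with pytest.raises(ValueError, match="Negative"):
            normalize_counts(make_experiment(raw, classes))

    def test_zero_positive_geomean_names_sample(self):
        raw = {"s1": [0, 100, 2, 4, 50, 20], "s2": [400, 400, 8, 16, 200, 80]}
        with pytest.raises(ValueError, match="s1"):
            normalize_counts(make_experiment(raw, TOY_CLASSES))

    def test_alternative_dialects_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            NormalizationParams(code_count="sum")


class TestRCC:
    def test_round_trip(self, default_dataset, tmp_path):
        from tcrbm.io import read_expression, write_expression

        exp = default_dataset.expression
        write_expression(exp, tmp_path)
        back = read_expression(tmp_path)
        pd.testing.assert_frame_equal(back.raw_counts, exp.raw_counts)
        assert list(back.genes["code_class"]) == list(exp.genes["code_class"])

    def test_missing_code_summary_errors(self, tmp_path):
        from tcrbm.io import read_rcc

        path = tmp_path / "bad.RCC"
        path.write_text("<Header>\nFileVersion,1.7\n</Header>\n")
        with pytest.raises(ValueError, match="Code_Summary"):
            read_rcc(path)

    def test_malformed_count_names_probe(self, tmp_path):
        from tcrbm.io import read_rcc

        path = tmp_path / "bad.RCC"
        path.write_text(
            "<Code_Summary>\nCodeClass,Name,Accession,Count\n"
            "Endogenous,CD163,NA_1,NA\n</Code_Summary>\n"
        )
        with pytest.raises(ValueError, match="CD163"):
            read_rcc(path)

    def test_missing_negatives_loads_then_normalize_errors(self, tmp_path):
        """Control-class validation is deferred to normalization."""
        from tcrbm.io import read_expression, write_rcc

        counts = pd.Series([100, 50, 20], index=pd.Index(["POS_A", "G1", "HK1"], name="gene"))
        classes = pd.Series(
            ["Positive", "Endogenous", "Housekeeping"], index=counts.index
        )
        for sid in ("s1", "s2"):
            write_rcc(sid, counts, classes, tmp_path / f"{sid}.RCC")
        pd.DataFrame(
            {"sample_id": ["s1", "s2"], "patient_id": ["p1", "p2"],
             "timepoint": "pre", "responder": False}
        ).to_csv(tmp_path / "samples.csv", index=False)
        exp = read_expression(tmp_path)  # loads fine
        with pytest.raises(ValueError, match="Negative"):
            normalize_counts(exp)


def moderated_t_oracle(M, labels):
    """Step-by-step recomputation of the shrinkage formulas (bisection inverse)."""
    g1, g0 = M[:, labels], M[:, ~labels]
    n1, n0 = g1.shape[1], g0.shape[1]
    dg = n1 + n0 - 2
    tvals = []
    s2s = []
    diffs = []
    for row1, row0 in zip(g1, g0):
        v1 = row1.var(ddof=1)
        v0 = row0.var(ddof=1)
        s2s.append(((n1 - 1) * v1 + (n0 - 1) * v0) / dg)
        diffs.append(row1.mean() - row0.mean())
    s2s = np.array(s2s)
    e = np.log(s2s) - digamma(dg / 2) + np.log(dg / 2)
    evar = e.var(ddof=1) - polygamma(1, dg / 2)
    if evar > 0:
        lo, hi = 1e-6, 1e8
        for _ in range(200):  # bisection: trigamma is decreasing
            mid = 0.5 * (lo + hi)
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s0_2 = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
        post = (d0 * s0_2 + dg * s2s) / (d0 + dg)
    else:
        post = np.full_like(s2s, np.exp(e.mean()))
    su = math.sqrt(1 / n1 + 1 / n0)
    return np.array(diffs) / (np.sqrt(post) * su)


class TestModeratedT:
    def test_matches_step_by_step_recomputation(self):
        rng = np.random.default_rng(1)
        M = rng.normal(5, 1, size=(5, 6))
        labels = np.array([True, True, True, False, False, False])
        t, _, _ = moderated_t(M, labels)
        np.testing.assert_allclose(t, moderated_t_oracle(M, labels), atol=1e-8)

    def test_d0_zero_limit_is_ordinary_t(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(8, 10))
        labels = np.arange(10) < 5
        t, df, _ = moderated_t(M, labels, d0=0)
        ref = ttest_ind(M[:, labels], M[:, ~labels], axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)
        assert df == 8

    def test_equal_true_variances_shrink_toward_pooled(self):
        from tcrbm.nanostring import _group_stats, squeeze_var

        rng = np.random.default_rng(3)
        M = rng.normal(0, 1.0, size=(400, 8))  # all genes share one variance
        labels = np.arange(8) < 4
        _, s2, n1, n0 = _group_stats(M, labels)
        post, d0, s0_2 = squeeze_var(s2, n1 + n0 - 2)
        # shared true variance: strong shrinkage toward one common value
        assert np.std(post) < 0.25 * np.std(s2)
        assert 0.5 < s0_2 < 2.0
        assert d0 > 10

    def test_group_interface_and_zero_variance_flag(self, default_dataset):
        exp = normalize_counts(default_dataset.expression)
        table = moderated_t_group(exp, grouping="responder")
        assert {"logFC", "t", "p"} <= set(table.columns)
        zv = table["zero_variance"]
        assert (table.loc[zv, "t"] == 0).all()


class TestPairedLME:
    def test_perfectly_paired_estimate_is_mean_difference(self):
        rng = np.random.default_rng(4)
        n_pat = 8
        pre = rng.normal(8, 1, n_pat)
        delta = rng.normal(-1, 0.3, n_pat)
        genes = pd.DataFrame(
            {"code_class": ["Endogenous", "Housekeeping", "Positive", "Negative"]},
            index=pd.Index(["G1", "HK1", "POS_A", "NEG_A"], name="gene"),
        )
        sample_ids = [f"p{i}_{tp}" for i in range(n_pat) for tp in ("pre", "prog")]
        samples = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n_pat) for _ in range(2)],
                "timepoint": ["pre", "progression"] * n_pat,
                "responder": False,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        vals = np.empty((4, 2 * n_pat))
        vals[0] = np.ravel(np.column_stack([pre, pre + delta]))
        vals[1:] = 5.0
        exp = ExpressionExperiment(
            genes=genes, samples=samples,
            raw_counts=pd.DataFrame(
                np.ones((4, 2 * n_pat), int), index=genes.index, columns=samples.index
            ),
            norm_log2=pd.DataFrame(vals, index=genes.index, columns=samples.index),
        )
        res = paired_timepoint_lme(exp, genes=["G1"])
        assert res.loc["G1", "estimate"] == pytest.approx(delta.mean(), abs=1e-5)


class TestCoxPerGene:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        n = 8
        times = np.arange(1, n + 1) * 10.0 + rng.uniform(0, 1, n)  # no ties
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1], bool)
        genes = pd.DataFrame(
            {"code_class": ["Endogenous", "Endogenous", "Housekeeping",
                            "Positive", "Negative"]},
            index=pd.Index(["G1", "G2", "HK1", "POS_A", "NEG_A"], name="gene"),
        )
        samples = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)], "timepoint": "pre",
             "responder": False},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        norm = pd.DataFrame(
            rng.normal(8, 1, size=(5, n)), index=genes.index, columns=samples.index
        )
        exp = ExpressionExperiment(
            genes=genes, samples=samples,
            raw_counts=pd.DataFrame(np.ones((5, n), int), index=genes.index,
                                    columns=samples.index),
            norm_log2=norm,
        )
        pfs = pd.DataFrame(
            {"pfs_days": times, "pfs_event": events},
            index=pd.Index([f"p{i}" for i in range(n)]),
        )
        table = cox_per_gene(exp, pfs)
        for gene in ("G1", "G2"):
            x = norm.loc[gene].to_numpy()
            assert table.loc[gene, "log_hr"] == pytest.approx(
                cox_grid_mle(times, events, x), abs=1e-6
            )

    def test_identical_groups_zero_hr(self):
        # every survival outcome appears at both covariate levels: HR must be 1
        times = np.array([10, 10, 20, 20, 30, 30, 40, 40.0])
        events = np.array([1, 1, 1, 1, 0, 0, 1, 1], bool)
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1.0])
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": times, "E": events, "x": x}), "T", "E")
        assert abs(float(cph.params_["x"])) < 1e-6


class TestGeneSetFilter:
    def _norm(self, genes_constant, genes_varying):
        rng = np.random.default_rng(6)
        idx = pd.Index(genes_constant + genes_varying, name="gene")
        vals = np.vstack(
            [np.full((len(genes_constant), 6), 5.0),
             rng.normal(5, 1, size=(len(genes_varying), 6))]
        )
        return pd.DataFrame(vals, index=idx)

    def test_boundary_cases(self):
        varying = [f"V{i}" for i in range(10)]
        norm = self._norm(["C1", "C2"], varying)
        panel = list(norm.index)
        ten = GeneSet("ten", tuple(varying[:5] + [f"off{i}" for i in range(5)]))
        twelve = GeneSet("twelve", tuple(varying[:5] + [f"off{i}" for i in range(7)]))
        four = GeneSet("four", tuple(varying[:4]))
        constant5 = GeneSet("constant5", ("C1", "C2") + tuple(varying[:3]))
        kept = filter_gene_sets([ten, twelve, four, constant5], panel, norm)
        assert [g.name for g in kept] == ["ten"]  # 5/10 coverage at exactly 0.5


class TestGlobalSignificance:
    def test_worked_statistic_values(self):
        assert global_stat([2.0]) == 2.0
        assert global_stat([3.0, 4.0]) == 5.0  # 3-4-5
        assert global_stat([-3.0, 4.0]) == 5.0  # sign-invariant

    def _data(self, seed=7, n_genes=40, n=12):
        rng = np.random.default_rng(seed)
        M = pd.DataFrame(
            rng.normal(7, 1, size=(n_genes, n)),
            index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene"),
        )
        labels = np.arange(n) < n // 2
        return M, labels

    def test_deterministic_and_bounded(self):
        M, labels = self._data()
        gs = GeneSet("s", tuple(f"G{i}" for i in range(8)))
        r1 = global_significance(M, labels, gs, B=199, seed=42)
        r2 = global_significance(M, labels, gs, B=199, seed=42)
        assert r1 == r2
        assert 1.0 / 200 <= r1["perm_p"] <= 1.0

    def test_invariant_to_gene_order(self):
        M, labels = self._data()
        gs = GeneSet("s", tuple(f"G{i}" for i in range(8)))
        r1 = global_significance(M, labels, gs, B=99, seed=1)
        perm = np.random.default_rng(0).permutation(len(M))
        r2 = global_significance(M.iloc[perm], labels, gs, B=99, seed=1)
        assert r1["global_stat"] == pytest.approx(r2["global_stat"], rel=1e-12)

    def test_label_swap_preserves_statistic(self):
        M, labels = self._data()
        gs = GeneSet("s", tuple(f"G{i}" for i in range(8)))
        r1 = global_significance(M, labels, gs, B=99, seed=1)
        r2 = global_significance(M, ~labels, gs, B=99, seed=1)
        assert r1["global_stat"] == pytest.approx(r2["global_stat"], rel=1e-12)

    def test_exact_enumeration_for_tiny_designs(self):
        M, _ = self._data(n=4)
        labels = np.array([True, True, False, False])
        gs = GeneSet("s", tuple(f"G{i}" for i in range(8)))
        res = global_significance(M, labels, gs, B=5000, seed=0)
        # C(4,2) = 6 distinct labelings: p is a multiple of 1/6
        assert res["perm_p"] * 6 == pytest.approx(round(res["perm_p"] * 6))


class TestCompetitiveFisher:
    def test_odds_ratio_arithmetic(self):
        assert _odds_ratio(np.array([[4, 6], [10, 180]])) == 12.0

    def test_haldane_correction_engages(self):
        or_ = _odds_ratio(np.array([[5, 0], [0, 50]]))
        assert np.isfinite(or_) and or_ > 1

    def test_membership_table(self):
        in_set = np.array([True, True, False, False])
        sig = np.array([True, False, True, False])
        assert _membership_table(in_set, sig).tolist() == [[1, 1], [1, 1]]

    def test_independence_gives_or_near_one(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(
            rng.normal(size=(300, 16)),
            index=pd.Index([f"G{i}" for i in range(300)], name="gene"),
        )
        labels = np.arange(16) < 8
        gs = GeneSet("s", tuple(f"G{i}" for i in range(100)))
        res = competitive_fisher(M, labels, gs, B=99, seed=0)
        assert 0.2 < res["fisher_or"] < 5.0
        assert res["fisher_perm_p"] > 0.05
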