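"""Normalization, detection-call filtering, moderated t, BH FDR, reporting."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aldhkit.errors import InputError
from aldhkit.expression import (
    ExpressionMatrix,
    ModeratedTParams,
    bh_fdr,
    de_call,
    estimate_prior,
    filter_absent,
    moderated_t,
    quantile_normalize,
    responsiveness_report,
)
from aldhkit.synthetic import ExpressionSpec, SyntheticSpec, make_expression


def small_matrix(values, calls=None, conditions=("control", "control",
                                                 "treatment", "treatment")):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    probes = [f"p{i}" for i in range(n)]
    arrays = [f"a{j}" for j in range(k)]
    vdf = pd.DataFrame(values, index=probes, columns=arrays)
    if calls is None:
        cdf = pd.DataFrame("P", index=probes, columns=arrays)
    else:
        cdf = pd.DataFrame(calls, index=probes, columns=arrays)
    design = pd.Series(list(conditions), index=arrays, name="condition")
    probe_gene = pd.Series(probes, index=probes, name="gene_id")
    return ExpressionMatrix(vdf, cdf, design, probe_gene)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = small_matrix([[1, 1], [2, 2], [3, 3]], conditions=("c", "t"))
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_permuted_columns_get_mean_order_statistics(self):
        # hand-computed 4-row case: col2 is a permutation of col1
        m = small_matrix([[1, 8], [2, 5], [5, 2], [8, 1]], conditions=("c", "t"))
        out = quantile_normalize(m).values.to_numpy()
        expect = np.array([[1, 8], [2, 5], [5, 2], [8, 1]], dtype=float)
        # shared distribution = mean of sorted columns = (sorted col) itself
        assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))
        assert np.allclose(out, expect)

    def test_rank_preservation_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 3))
        warped = base.copy()
        warped[:, 2] = np.exp(base[:, 2])  # monotone warp of one column
        out = quantile_normalize(small_matrix(warped, conditions=("c", "c", "t")))
        for j in range(3):
            assert (stats.rankdata(out.values.to_numpy()[:, j]) ==
                    stats.rankdata(warped[:, j])).all()


class TestFilterAbsent:
    def test_single_present_call_retains(self):
        calls = [["P", "A", "A", "A"], ["A", "A", "A", "A"],
                 ["M", "M", "M", "M"]]
        m = small_matrix(np.zeros((3, 4)), calls)
        kept, dropped = filter_absent(m)
        assert list(kept.values.index) == ["p0"]
        assert dropped == ["p1", "p2"]  # all-A and all-M both excluded

    def test_generator_planted_absent_count(self):
        spec = SyntheticSpec(seed=3, expression=ExpressionSpec(
            n_genes=400, n_planted=40, absent_fraction=0.25))
        m, truth = make_expression(spec)
        kept, dropped = filter_absent(m)
        assert len(dropped) == 100
        assert set(dropped) == set(truth.index[truth["absent"]])


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        m = small_matrix(rng.normal(size=(100, 6)),
                         conditions=("control",) * 3 + ("treatment",) * 3)
        res = moderated_t(m, ("treatment", "control"),
                          prior=ModeratedTParams(d0=0.0, s02=1.0, d=4))
        x = m.values.iloc[:, 3:].to_numpy()
        y = m.values.iloc[:, :3].to_numpy()
        t_ref, p_ref = stats.ttest_ind(x, y, axis=1, equal_var=True)
        assert np.allclose(res["t"], t_ref)
        assert np.allclose(res["pvalue"], p_ref)

    def test_homogeneous_variances_full_pooling(self):
        # equal true variances: prior df goes to infinity, statistic ~ z
        spec = SyntheticSpec(seed=2, expression=ExpressionSpec(
            n_genes=4000, n_planted=0, absent_fraction=0.0))
        m, _ = make_expression(spec)
        res = moderated_t(m, ("treatment", "control"))
        prior = res.attrs["prior"]
        assert prior.d0 > 50 or np.isinf(prior.d0)
        assert prior.s02 == pytest.approx(1.0, rel=0.15)

    def test_null_pvalues_uniform(self):
        spec = SyntheticSpec(seed=11, expression=ExpressionSpec(
            n_genes=5000, n_planted=0, absent_fraction=0.0))
        m, _ = make_expression(spec)
        res = moderated_t(m, ("treatment", "control"))
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_single_array_condition_rejected(self):
        m = small_matrix(np.zeros((5, 3)), conditions=("control", "control",
                                                       "treatment"))
        with pytest.raises(InputError, match="descriptive"):
            moderated_t(m, ("treatment", "control"))

    def test_shrinkage_direction(self):
        # every posterior variance lies between the sample variance and s0^2
        rng = np.random.default_rng(5)
        scale = rng.uniform(0.3, 3.0, size=300)
        vals = rng.normal(size=(300, 6)) * scale[:, None]
        m = small_matrix(vals, conditions=("control",) * 3 + ("treatment",) * 3)
        res = moderated_t(m, ("treatment", "control"))
        prior = res.attrs["prior"]
        assert np.isfinite(prior.d0)
        lo = np.minimum(res["s2"], prior.s02)
        hi = np.maximum(res["s2"], prior.s02)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()

    def test_matches_limma_reference(self, tmp_path):
        # Bioconductor limma as independent oracle on a small matrix
        spec = SyntheticSpec(seed=5, expression=ExpressionSpec(
            n_genes=300, n_planted=30, absent_fraction=0.0))
        m, _ = make_expression(spec)
        expr_path = tmp_path / "expr.tsv"
        m.values.to_csv(expr_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        rcode = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{expr_path}", row.names=1))
design <- cbind(ctrl=1, trt=c(0,0,0,1,1,1))
fit <- eBayes(lmFit(x, design))
write.table(data.frame(t=fit$t[,"trt"], p=fit$p.value[,"trt"]),
            "{out_path}", sep="\\t", quote=FALSE)
"""
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        theirs = pd.read_csv(out_path, sep="\t")
        res = moderated_t(m, ("treatment", "control"))
        assert np.allclose(res["t"], theirs["t"], atol=1e-8)
        assert np.allclose(res["pvalue"], theirs["p"], atol=1e-8)


def bh_oracle(p):
    """Direct step-up: adj_i = min over j>=rank(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for k in range(m - 1, -1, -1):
        running = min(running, m * p[order[k]] / (k + 1))
        adj_sorted[k] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhFdr:
    def test_closed_form_triplet(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.1, float("nan")])

    @given(st.lists(st.sampled_from([0.0, 0.001, 0.01, 0.02, 0.05, 0.1, 0.3,
                                     0.5, 0.8, 1.0]),
                    min_size=1, max_size=6))
    def test_equals_step_up_oracle_small_vectors(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_oracle(pvals))

    def test_equals_oracle_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.allclose(bh_fdr(p), bh_oracle(p))


class TestResponsivenessReport:
    def _result(self, lfcs, padjs, probes=None):
        probes = probes or [f"p{i}" for i in range(len(lfcs))]
        df = pd.DataFrame({"lfc": lfcs, "pvalue": padjs, "padj": padjs,
                           "de": np.asarray(padjs) < 0.05}, index=probes)
        return df

    def test_any_probe_de_makes_gene_responsive(self):
        res = self._result([2.0, 0.1], [0.01, 0.9], probes=["p1", "p2"])
        probe_gene = pd.Series(["g1", "g1"], index=["p1", "p2"])
        rep = responsiveness_report({"salt": res}, probe_gene)
        assert rep.calls.loc["g1", "salt"] == "up"
        assert rep.lfc.loc["g1", "salt"] == 2.0

    def test_all_mode_requires_every_probe(self):
        res = self._result([2.0, 0.1], [0.01, 0.9], probes=["p1", "p2"])
        probe_gene = pd.Series(["g1", "g1"], index=["p1", "p2"])
        rep = responsiveness_report({"salt": res}, probe_gene, aggregate="all")
        assert rep.calls.loc["g1", "salt"] == "not_de"

    def test_down_direction(self):
        res = self._result([-1.5], [0.001], probes=["p1"])
        probe_gene = pd.Series(["g1"], index=["p1"])
        rep = responsiveness_report({"cold": res}, probe_gene)
        assert rep.calls.loc["g1", "cold"] == "down"

    def test_not_assayed_distinct_from_not_de(self):
        res = self._result([0.1], [0.9], probes=["p1"])
        probe_gene = pd.Series(["g1", "g2"], index=["p1", "p_gone"])
        rep = responsiveness_report({"heat": res}, probe_gene)
        assert rep.calls.loc["g1", "heat"] == "not_de"
        assert rep.calls.loc["g2", "heat"] == "not_assayed"

    def test_clustering_never_alters_values(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(12)]
        probe_gene = pd.Series([f"g{i}" for i in range(12)], index=probes)
        results = {}
        for cname in ("c1", "c2", "c3"):
            lfc = rng.normal(size=12)
            results[cname] = self._result(lfc, rng.uniform(size=12), probes)
        rep = responsiveness_report(results, probe_gene)
        for cname, res in results.items():
            for probe in probes:
                gene = probe_gene[probe]
                assert rep.lfc.loc[gene, cname] == res.loc[probe, "lfc"]


class TestScreenIntegration:
    def test_planted_effects_found_null_mostly_not(self):
        spec = SyntheticSpec(seed=17)
        m, truth = make_expression(spec)
        kept, _ = filter_absent(m)
        res = de_call(moderated_t(kept, ("treatment", "control")))
        de = res["de"]
        planted = truth.loc[de.index, "planted"]
        # at these settings recall is partial but highly enriched
        assert (de & planted).sum() > 10
        fdp = (de & ~planted).sum() / max(int(de.sum()), 1)
        assert fdp < 0.2
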