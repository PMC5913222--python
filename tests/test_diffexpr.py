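import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from refnorm.diffexpr import (
    bh_adjust,
    ebayes_moderate,
    fit_two_group,
    quantile_normalize,
    run_de,
)
from refnorm.io import ExpressionMatrix, ProbesetAnnotation, ValidationError
from refnorm.simulate import DeSimConfig, simulate_de_matrix


def matrix_of(arr, log2=True):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(arr,
                      index=[f"g{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    return ExpressionMatrix(values=df, log2=log2)


def two_group_labels(n, control="control", treatment="treated"):
    idx = [f"s{j}" for j in range(2 * n)]
    return pd.Series([control] * n + [treatment] * n, index=idx)


class TestQuantileNormalize:
    def test_two_by_two_example(self):
        m = matrix_of([[1, 2], [3, 6]])
        q = quantile_normalize(m).values.to_numpy()
        # sorted columns (1,3) and (2,6) -> row means (1.5, 4.5)
        assert np.allclose(q[:, 0], [1.5, 4.5])
        assert np.allclose(q[:, 1], [1.5, 4.5])

    def test_identical_distributions_unchanged(self):
        rng = np.random.default_rng(1)
        col = np.sort(rng.normal(8, 1, 30))
        arr = np.column_stack([col, rng.permutation(col), rng.permutation(col)])
        m = matrix_of(arr)
        q = quantile_normalize(m)
        assert np.allclose(q.values.to_numpy(), arr, atol=1e-12)

    def test_columns_share_distribution_afterwards(self):
        rng = np.random.default_rng(2)
        m = matrix_of(rng.normal(8, 2, (50, 5)))
        q = quantile_normalize(m).values.to_numpy()
        ref = np.sort(q[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(q[:, j]), ref, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = matrix_of(rng.normal(8, 2, (40, 4)))
        q1 = quantile_normalize(m)
        q2 = quantile_normalize(q1)
        assert np.allclose(q1.values.to_numpy(), q2.values.to_numpy(), atol=1e-12)

    def test_within_column_ties_get_spanned_mean(self):
        m = matrix_of([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        q = quantile_normalize(m).values.to_numpy()
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        # column 0 has a tie over the two lowest positions
        assert q[0, 0] == pytest.approx(ref[:2].mean())
        assert q[1, 0] == pytest.approx(ref[:2].mean())

    def test_single_sample_identity_with_warning(self):
        m = matrix_of([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single sample"):
            q = quantile_normalize(m)
        assert np.allclose(q.values.to_numpy(), m.values.to_numpy())


class TestFitTwoGroup:
    def test_hand_computed_pooled_variance(self):
        m = matrix_of([[0.0, 2.0, 1.0, 3.0]])
        fits = fit_two_group(m, two_group_labels(2), control_label="control")
        assert fits["logFC"].iloc[0] == pytest.approx(1.0)
        assert fits["AveExpr"].iloc[0] == pytest.approx(1.5)
        assert fits["s2"].iloc[0] == pytest.approx(2.0)
        assert fits["df"].iloc[0] == 2.0

    def test_no_within_group_variance(self):
        m = matrix_of([[1.0, 1.0, 3.0, 3.0]])
        fits = fit_two_group(m, two_group_labels(2), control_label="control")
        assert fits["logFC"].iloc[0] == pytest.approx(2.0)
        assert fits["s2"].iloc[0] == pytest.approx(0.0)

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(5)
        m, labels, _ = simulate_de_matrix(DeSimConfig(n_genes=30, n_per_group=4, seed=7))
        fits = fit_two_group(m, labels, control_label="control")
        perm = rng.permutation(m.values.columns.to_numpy())
        m2 = ExpressionMatrix(values=m.values[perm], log2=True)
        fits2 = fit_two_group(m2, labels[perm], control_label="control")
        assert np.allclose(fits["logFC"], fits2["logFC"])
        assert np.allclose(fits["s2"], fits2["s2"])


class TestEbayes:
    def test_equal_variances_reduce_to_ordinary_t(self):
        rng = np.random.default_rng(11)
        n = 4
        logfc = rng.normal(0, 1, 50)
        fits = pd.DataFrame({
            "logFC": logfc, "AveExpr": 8.0, "s2": 0.25, "df": float(2 * n - 2),
            "n1": n, "n2": n,
        })
        prior, mod = ebayes_moderate(fits)
        ordinary = logfc / (math.sqrt(0.25) * math.sqrt(2 / n))
        assert np.allclose(mod["t"], ordinary, rtol=1e-6)

    def test_infinite_d0_gives_complete_shrinkage(self):
        rng = np.random.default_rng(12)
        m, labels, _ = simulate_de_matrix(DeSimConfig(n_genes=100, n_per_group=4, seed=1))
        fits = fit_two_group(m, labels, control_label="control")
        prior, mod = ebayes_moderate(fits, d0_override=math.inf)
        n = 4
        expected_t = fits["logFC"] / (math.sqrt(prior.s0_sq) * math.sqrt(2 / n))
        assert np.allclose(mod["t"], expected_t, rtol=1e-9)

    def test_prior_moment_recovery(self):
        cfg = DeSimConfig(n_genes=2000, n_per_group=6, d0_true=4.0,
                          s0_sq_true=0.05, seed=9)
        m, labels, _ = simulate_de_matrix(cfg)
        fits = fit_two_group(m, labels, control_label="control")
        prior, _ = ebayes_moderate(fits)
        assert prior.d0 == pytest.approx(4.0, rel=0.25)
        assert prior.s0_sq == pytest.approx(0.05, rel=0.25)

    def test_null_type_one_error_calibrated(self):
        rates = []
        for seed in (21, 22, 23):
            m, labels, _ = simulate_de_matrix(
                DeSimConfig(n_genes=1000, n_per_group=6, fraction_de=0.0, seed=seed))
            fits = fit_two_group(m, labels, control_label="control")
            _, mod = ebayes_moderate(fits)
            rates.append(float((mod["p_value"] < 0.05).mean()))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Independent oracle: the Bioconductor implementation of the same model."""
        cfg = DeSimConfig(n_genes=150, n_per_group=5, fraction_de=0.1, seed=31)
        m, labels, _ = simulate_de_matrix(cfg)
        fits = fit_two_group(m, labels, control_label="control")
        prior, mod = ebayes_moderate(fits)
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "limma.tsv"
        m.values.to_csv(mat_path, sep="\t")
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_path}", row.names=1))
        grp <- factor(rep(c("control","treated"), each=5), levels=c("control","treated"))
        fit <- eBayes(lmFit(m, model.matrix(~grp)))
        res <- topTable(fit, coef=2, number=Inf, sort.by="none")
        res$d0 <- fit$df.prior; res$s0sq <- fit$s2.prior
        write.table(res, "{out_path}", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        assert prior.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert prior.s0_sq == pytest.approx(float(ref["s0sq"].iloc[0]), rel=1e-4)
        assert np.allclose(mod["t"], ref["t"], rtol=1e-6, atol=1e-8)
        assert np.allclose(mod["p_value"], ref["P.Value"], rtol=1e-6, atol=1e-12)
        assert np.allclose(mod["B"], ref["B"], rtol=1e-4, atol=1e-6)


def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        j = m - rank_from_top  # 1-based rank of this p in ascending order
        running_min = min(running_min, p[idx] * m / j)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_stepped_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2])

    def test_output_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 60)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_brute_force_on_short_grids(self):
        rng = np.random.default_rng(15)
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        for length in range(1, 9):
            for _ in range(40):
                p = rng.choice(grid, size=length)
                assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestRunDe:
    def test_recovers_planted_effects(self):
        cfg = DeSimConfig(n_genes=800, n_per_group=6, fraction_de=0.05,
                          logfc_magnitude=1.0, seed=41)
        m, labels, is_de = simulate_de_matrix(cfg)
        results = run_de(m, labels, pre_normalized=True, control_label="control")
        by_gene = {r.probeset_id: r for r in results}
        genes = list(m.values.index)
        hits = {g for g in genes if by_gene[g].adj_p_value < 0.05}
        true_set = {g for g, flag in zip(genes, is_de) if flag}
        assert len(hits) > 0
        # discoveries should be dominated by planted genes (FDR control)
        false_hits = hits - true_set
        assert len(false_hits) <= max(1, 0.2 * len(hits))
        # good power at |logFC| = 1 with n = 6 per group
        assert len(hits & true_set) >= 0.5 * len(true_set)

    def test_null_matrix_yields_no_discoveries(self):
        m, labels, _ = simulate_de_matrix(
            DeSimConfig(n_genes=500, n_per_group=6, fraction_de=0.0, seed=43))
        results = run_de(m, labels, pre_normalized=True, control_label="control")
        assert sum(r.adj_p_value < 0.05 for r in results) <= 2

    def test_result_invariants_and_annotation(self):
        m, labels, _ = simulate_de_matrix(
            DeSimConfig(n_genes=60, n_per_group=4, fraction_de=0.1, seed=44))
        ann = ProbesetAnnotation({g: f"SYM_{g}" for g in m.values.index})
        results = run_de(m, labels, annotation=ann, pre_normalized=True,
                         control_label="control")
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        for r in results:
            assert r.adj_p_value >= r.p_value - 1e-15
            assert 0.0 <= r.adj_p_value <= 1.0
            assert r.gene_symbol == f"SYM_{r.probeset_id}"
            if r.logFC != 0:
                assert math.copysign(1, r.t) == math.copysign(1, r.logFC)
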