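"""Differential-expression stage: normalization, dispersion, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimertarget.diffexpr import (
    CountMatrix,
    DEError,
    bh_adjust,
    build_normalization_matrix,
    estimate_dispersion,
    nb_wald_test,
    run_de,
    size_factors,
)
from dimertarget.synthetic import SimulationConfig, simulate_counts


def _cm(counts: np.ndarray, n_tumor: int) -> CountMatrix:
    n = counts.shape[1]
    df = pd.DataFrame(
        counts,
        index=[f"G{i}" for i in range(counts.shape[0])],
        columns=[f"S{i}" for i in range(n)],
    )
    cond = pd.Series(["tumor"] * n_tumor + ["normal"] * (n - n_tumor), index=df.columns)
    return CountMatrix(counts=df, condition=cond)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: adj_i = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        i = rank_pos + 1
        candidates = [p[order[j - 1]] * m / j for j in range(i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(DEError, match="non-negative"):
            _cm(np.array([[1, -1], [0, 2]]), 1)

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["G", "G"], columns=["a", "b"])
        cond = pd.Series(["tumor", "normal"], index=df.columns)
        with pytest.raises(DEError, match="duplicate"):
            CountMatrix(counts=df, condition=cond)

    def test_missing_condition_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["G"], columns=["a", "b"])
        with pytest.raises(DEError, match="missing"):
            CountMatrix(counts=df, condition=pd.Series(["tumor"], index=["a"]))


class TestSizeFactors:
    def test_exact_scaling_recovered(self):
        # every column a scalar multiple of one reference profile: the size
        # factors must be proportional to those scalars
        ref = np.array([10, 40, 160, 640])
        scalars = np.array([1.0, 2.0, 0.5, 4.0])
        counts = np.round(ref[:, None] * scalars[None, :]).astype(int)
        sf = size_factors(_cm(counts, 2)).to_numpy()
        assert np.allclose(sf / sf[0], scalars / scalars[0])

    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 3])
        counts = np.tile(col[:, None], (1, 4))
        sf = size_factors(_cm(counts, 2))
        assert np.allclose(sf, 1.0)

    def test_matches_independent_median_of_ratios_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 0.05, size=(50, 8)) + 1
        sf = size_factors(_cm(x, 4)).to_numpy()
        # independent oracle, computed column by column
        log_ref = np.log(x).mean(axis=1)
        expected = [np.exp(np.median(np.log(x[:, j]) - log_ref)) for j in range(8)]
        assert np.allclose(sf, expected)

    def test_no_universally_expressed_gene_errors(self):
        x = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(DEError, match="size factors"):
            size_factors(_cm(x, 1))


class TestNormalizationMatrix:
    def test_default_rows_equal_size_factors(self, small_counts):
        norm = build_normalization_matrix(small_counts)
        sf = size_factors(small_counts)
        assert np.allclose(norm.to_numpy(), np.tile(sf.to_numpy(), (6, 1)))

    def test_constant_gene_factor_row_is_neutral(self, small_counts):
        gf = pd.DataFrame(
            2.0, index=small_counts.gene_ids, columns=small_counts.sample_ids
        )
        norm = build_normalization_matrix(small_counts, gf)
        assert np.allclose(norm, build_normalization_matrix(small_counts))

    def test_gene_component_geomean_is_one(self, small_counts):
        rng = np.random.default_rng(0)
        gf = pd.DataFrame(
            np.exp(rng.normal(0, 0.5, size=(6, 6))),
            index=small_counts.gene_ids,
            columns=small_counts.sample_ids,
        )
        norm = build_normalization_matrix(small_counts, gf)
        gene_component = norm.to_numpy() / size_factors(small_counts).to_numpy()[None, :]
        geomeans = np.exp(np.log(gene_component).mean(axis=1))
        assert np.allclose(geomeans, 1.0, atol=1e-8)

    def test_nonpositive_gene_factor_rejected(self, small_counts):
        gf = pd.DataFrame(
            1.0, index=small_counts.gene_ids, columns=small_counts.sample_ids
        )
        gf.iloc[0, 0] = 0.0
        with pytest.raises(DEError, match="positive"):
            build_normalization_matrix(small_counts, gf)


class TestDispersion:
    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(500, size=(1, 400))
        cm = _cm(x, 200)
        disp = estimate_dispersion(cm, build_normalization_matrix(cm))
        assert disp.iloc[0] < 0.02

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(
            genes=[f"G{i}" for i in range(300)], n_tumor=200, n_normal=200,
            baseline_mean=500.0, dispersion=0.2, seed=9,
        )
        cm, _ = simulate_counts(cfg)
        disp = estimate_dispersion(cm, build_normalization_matrix(cm))
        assert 0.15 <= disp.mean() <= 0.25

    def test_constant_counts_floor_and_all_zero_nan(self):
        x = np.vstack([np.full(6, 7), np.zeros(6, dtype=int)])
        cm = _cm(x, 3)
        norm = pd.DataFrame(1.0, index=cm.gene_ids, columns=cm.sample_ids)
        disp = estimate_dispersion(cm, norm)
        assert disp.iloc[0] == pytest.approx(1e-8)
        assert np.isnan(disp.iloc[1])


class TestWaldTest:
    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(50, size=(5, 8))
        x[3] = 0
        cm = _cm(x, 4)
        de = run_de(cm)
        rec = de.loc["G3"]
        assert not rec["tested"]
        assert np.isnan(rec["log2fc"]) and np.isnan(rec["pvalue"]) and np.isnan(rec["fdr"])
        assert de.loc["G0", "tested"]

    def test_up_in_tumor_gives_positive_log2fc(self):
        cfg = SimulationConfig(
            genes=[f"G{i}" for i in range(60)], n_tumor=30, n_normal=30,
            baseline_mean=300.0, dispersion=0.05,
            planted_log2fc={"G0": 3.0}, seed=5,
        )
        cm, _ = simulate_counts(cfg)
        de = run_de(cm)
        assert de.loc["G0", "log2fc"] > 2.0
        assert de.loc["G0", "fdr"] < 1e-6

    def test_one_condition_all_zero_gets_finite_capped_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(100, size=(10, 12))
        x[0, 6:] = 0  # expressed in tumor only
        cm = _cm(x, 6)
        de = run_de(cm)
        rec = de.loc["G0"]
        assert rec["tested"]
        assert np.isfinite(rec["log2fc"])
        assert 0 < rec["log2fc"] <= 20 / np.log(2)

    def test_sample_scaling_absorbed_by_normalization(self):
        cfg = SimulationConfig(
            genes=[f"G{i}" for i in range(80)], n_tumor=40, n_normal=40,
            baseline_mean=400.0, dispersion=0.05, seed=8,
        )
        cm, _ = simulate_counts(cfg)
        de0 = run_de(cm)
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        de1 = run_de(CountMatrix(counts=scaled, condition=cm.condition))
        # tripling one sample's depth moves size factors, not fold changes
        assert np.abs(de0["log2fc"] - de1["log2fc"]).mean() < 0.05

    def test_poisson_limit_agrees_with_poisson_glm(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(
            genes=[f"G{i}" for i in range(40)], n_tumor=100, n_normal=100,
            baseline_mean=500.0, dispersion=0.0, seed=12,
        )
        cm, _ = simulate_counts(cfg)
        norm = build_normalization_matrix(cm)
        disp = pd.Series(1e-8, index=cm.gene_ids)
        de = nb_wald_test(cm, norm, disp)
        tumor = cm.is_tumor().astype(float)
        design = np.column_stack([np.ones_like(tumor), tumor])
        for gene in cm.gene_ids[:10]:
            res = sm.GLM(
                cm.counts.loc[gene].to_numpy(float), design,
                family=sm.families.Poisson(),
                offset=np.log(norm.loc[gene].to_numpy()),
            ).fit()
            from scipy import stats as sps

            p_pois = 2 * sps.norm.sf(abs(res.params[1] / res.bse[1]))
            assert de.loc[gene, "pvalue"] == pytest.approx(p_pois, rel=0.1)


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0]) and np.isfinite(out[2])

    def test_out_of_range_rejected(self):
        with pytest.raises(DEError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_brute_force_oracle(self, pvals):
        p = np.array(pvals)
        out = np.asarray(bh_adjust(p))
        assert np.allclose(out, brute_force_bh(p), atol=1e-12)
        assert (out >= p - 1e-12).all() and (out <= 1.0 + 1e-12).all()


def test_fdr_at_least_pvalue_on_simulated_data():
    cfg = SimulationConfig(
        genes=[f"G{i}" for i in range(100)], n_tumor=10, n_normal=10,
        baseline_mean=100.0, dispersion=0.1, seed=21,
    )
    cm, _ = simulate_counts(cfg)
    de = run_de(cm)
    tested = de[de["tested"]]
    assert (tested["fdr"] >= tested["pvalue"] - 1e-12).all()
    assert (tested["fdr"] <= 1.0).all()


def test_agrees_with_pydeseq2_on_strong_effects():
    """Independent cross-check: log2fc from an established NB DE tool.

    pydeseq2 shrinks dispersions and uses a different normalization path, so
    agreement is checked loosely on genes with large planted effects.
    """
    pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    planted = {"G0": 2.0, "G1": -2.0, "G2": 3.0}
    cfg = SimulationConfig(
        genes=[f"G{i}" for i in range(60)], n_tumor=25, n_normal=25,
        baseline_mean=300.0, dispersion=0.05, planted_log2fc=planted, seed=17,
    )
    cm, _ = simulate_counts(cfg)
    de = run_de(cm)

    import warnings

    meta = pd.DataFrame({"condition": cm.condition})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta,
            design="~condition", ref_level=["condition", "normal"], quiet=True,
        )
        dds.deseq2()
        res = DeseqStats(dds, contrast=["condition", "tumor", "normal"], quiet=True)
        res.summary()
    ref = res.results_df
    for g in planted:
        assert de.loc[g, "log2fc"] == pytest.approx(ref.loc[g, "log2FoldChange"], abs=0.25)
        assert (de.loc[g, "fdr"] < 0.05) == (ref.loc[g, "padj"] < 0.05)
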