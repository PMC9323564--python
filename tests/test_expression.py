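"""Normalization, transforms and the NB Wald differential expression caller."""

import math

import numpy as np
import pandas as pd
import pytest

from glyconet import (
    SimDesign,
    differential_expression,
    linear_fold_change,
    simulate_counts,
    size_factors,
    transform_counts,
)
from glyconet.errors import InvalidDesignError, NormalizationError
from glyconet.simulate import CountMatrix


def _cm(counts: np.ndarray, n_case: int, n_ref: int) -> CountMatrix:
    genes = [f"G{i}" for i in range(counts.shape[0])]
    samples = [f"S{i}" for i in range(counts.shape[1])]
    groups = pd.Series(["case"] * n_case + ["reference"] * n_ref, index=samples)
    return CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples), groups=groups)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        x = np.tile([[10], [20], [30]], (1, 2))
        f = size_factors(pd.DataFrame(x, index=list("abc"), columns=["s1", "s2"]))
        assert np.allclose(f, [1.0, 1.0])

    def test_doubled_sample_scales(self):
        x = np.array([[10, 20], [30, 60], [5, 10]])
        f = size_factors(pd.DataFrame(x, index=list("abc"), columns=["s1", "s2"]))
        # proportional to (1, 2), renormalized to geometric mean 1
        assert np.allclose(f, [1 / math.sqrt(2), math.sqrt(2)])

    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(0)
        x = rng.negative_binomial(10, 0.05, size=(50, 6)) + 1  # all positive
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(50)],
                          columns=[f"s{i}" for i in range(6)])
        # independent brute-force oracle: per-gene geometric mean, per-sample median ratio
        oracle = []
        for j in range(6):
            ratios = []
            for i in range(50):
                gm = np.prod(x[i].astype(float)) ** (1 / 6)
                ratios.append(x[i, j] / gm)
            oracle.append(np.median(ratios))
        oracle = np.asarray(oracle)
        oracle /= np.prod(oracle) ** (1 / 6)
        assert np.allclose(size_factors(df).to_numpy(), oracle, rtol=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(100, size=(30, 4)) + 1
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(30)], columns=list("abcd"))
        f0 = size_factors(df)
        scaled = df.copy()
        scaled["b"] = scaled["b"] * 3
        f1 = size_factors(scaled)
        assert (f1["b"] / f0["b"]) / (f1["a"] / f0["a"]) == pytest.approx(3.0, rel=1e-10)

    def test_no_universally_expressed_gene_errors(self):
        df = pd.DataFrame([[0, 5], [5, 0]], index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(NormalizationError):
            size_factors(df)


class TestTransform:
    def test_zero_count_maps_to_zero(self):
        df = pd.DataFrame([[0, 4]], index=["g"], columns=["s1", "s2"])
        f = pd.Series([1.0, 1.0], index=["s1", "s2"])
        out = transform_counts(df, f)
        assert out.loc["g", "s1"] == 0.0
        assert out.loc["g", "s2"] == pytest.approx(math.log2(5))

    def test_log2norm_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(50, size=(20, 8))
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(8)])
        f = pd.Series(rng.uniform(0.5, 2.0, 8), index=df.columns)
        out = transform_counts(df, f)
        for i in range(20):
            for j in range(8):
                assert out.iloc[i, j] == pytest.approx(
                    math.log2(x[i, j] / f.iloc[j] + 1), abs=1e-12
                )

    def test_shrunken_constant_gene_unchanged(self):
        df = pd.DataFrame([[7, 7, 7, 7], [1, 5, 9, 2]], index=["const", "var"],
                          columns=list("abcd"))
        f = pd.Series(np.ones(4), index=list("abcd"))
        plain = transform_counts(df, f, mode="log2norm")
        shr = transform_counts(df, f, mode="shrunken")
        assert np.allclose(shr.loc["const"], plain.loc["const"])
        # variable gene is pulled toward its mean, not past it
        dev_plain = plain.loc["var"] - plain.loc["var"].mean()
        dev_shr = shr.loc["var"] - plain.loc["var"].mean()
        assert (np.abs(dev_shr) <= np.abs(dev_plain) + 1e-12).all()

    def test_unknown_mode_rejected(self):
        df = pd.DataFrame([[1]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            transform_counts(df, pd.Series([1.0], index=["s"]), mode="rlog")


class TestLinearFoldChange:
    @pytest.mark.parametrize(
        "log2fc,printed,places",
        [(0.631, 1.55, 2), (0.0, 1.0, 2), (-1.462, 0.363, 3)],
    )
    def test_printed_precision(self, log2fc, printed, places):
        assert round(linear_fold_change(log2fc), places) == printed

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(3)
        for lfc in rng.uniform(-5, 5, 50):
            assert linear_fold_change(lfc) * linear_fold_change(-lfc) == pytest.approx(
                1.0, abs=1e-12
            )


class TestDifferentialExpression:
    def test_identical_groups_all_ns(self):
        x = np.tile(np.arange(1, 11)[:, None] * 7, (1, 6))
        cm = _cm(x, 3, 3)
        de = differential_expression(cm)
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["status"] == "ns").all()

    def test_group_swap_antisymmetry(self):
        design = SimDesign(n_tf=20, n_target=20, n_case=5, n_ref=5,
                           de_plan=[("TF0001", 2.0)], latent_sd=0.3, seed=8)
        cm, _ = simulate_counts(design)
        de_fwd = differential_expression(cm, case="case", reference="reference")
        de_rev = differential_expression(cm, case="reference", reference="case")
        assert np.allclose(de_fwd["log2fc"], -de_rev["log2fc"], atol=1e-10)
        assert np.allclose(de_fwd["p"].dropna(), de_rev["p"].dropna(), atol=1e-10)
        assert ((de_fwd["status"] == "up") == (de_rev["status"] == "down")).all()

    def test_power_on_planted_shift(self):
        """A log2fc=2 shift at mu=500, phi=0.05, n=10/group is almost always called up.

        The 200 planted genes sit in a 2,000-gene background so that
        median-of-ratios normalization is not distorted by the plants.
        """
        de_plan = [(f"TF{i:04d}", 2.0) for i in range(1, 201)]  # first 200 TF-role genes
        design = SimDesign(
            n_tf=200, n_target=1800, n_case=10, n_ref=10,
            mu_range=(500.0, 500.0), dispersion=0.05, latent_sd=0.0,
            de_plan=de_plan, seed=12,
        )
        cm, truth = simulate_counts(design)
        de = differential_expression(cm)
        planted = de.loc[list(truth.de_genes)]
        sensitivity = (planted["status"] == "up").mean()
        assert sensitivity >= 0.9
        null = de.drop(index=list(truth.de_genes))
        assert (null["status"] != "ns").mean() < 0.05

    def test_null_p_uniform_and_no_discoveries(self):
        from scipy import stats

        design = SimDesign(
            n_tf=1000, n_target=1000, n_case=10, n_ref=10,
            mu_range=(100.0, 1000.0), dispersion=0.05, latent_sd=0.0, seed=13,
        )
        cm, _ = simulate_counts(design)
        de = differential_expression(cm)
        assert (de["status"] != "ns").sum() <= 2
        ks = stats.kstest(de["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_bh_monotone_in_rank(self):
        design = SimDesign(n_tf=50, n_target=50, n_case=5, n_ref=5, seed=14)
        cm, _ = simulate_counts(design)
        de = differential_expression(cm).dropna(subset=["p"]).sort_values("p")
        assert (de["adj_p"].diff().dropna() >= -1e-12).all()
        assert (de["adj_p"] <= 1.0).all()
        assert (de["adj_p"] >= de["p"] - 1e-12).all()

    def test_all_zero_gene_untested(self):
        x = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        cm = _cm(x, 3, 3)
        de = differential_expression(cm)
        assert de.loc["G0", "status"] == "untested"
        assert np.isnan(de.loc["G0", "p"])

    def test_small_group_rejected(self):
        x = np.full((5, 4), 10)
        genes = [f"G{i}" for i in range(5)]
        samples = [f"S{i}" for i in range(4)]
        groups = pd.Series(["case", "reference", "reference", "reference"], index=samples)
        cm = CountMatrix(counts=pd.DataFrame(x, index=genes, columns=samples), groups=groups)
        with pytest.raises(InvalidDesignError):
            differential_expression(cm)
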