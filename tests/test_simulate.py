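"""Generator correctness: roles, planted correlations, NB marginals, DBs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glyconet import (
    SimDesign,
    generate_gene_roles,
    simulate_counts,
    simulate_regulatory_db,
)
from glyconet.errors import InvalidDesignError
from glyconet.simulate import canonical, tf_names, target_names

from conftest import hub_block_plan


class TestGeneRoles:
    @pytest.mark.parametrize(
        "n_tf,n_target",
        [(1233, 74), (1, 1), (5, 3)],
    )
    def test_counts_and_uniqueness(self, n_tf, n_target):
        roles = generate_gene_roles(n_tf, n_target, seed=0)
        assert len(roles) == n_tf + n_target
        assert roles["gene_id"].is_unique
        assert (roles["role"] == "TF").sum() == n_tf
        assert (roles["role"] == "target").sum() == n_target

    def test_deterministic(self):
        a = generate_gene_roles(5, 3, seed=7)
        b = generate_gene_roles(5, 3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_gene_roles(0, 5)


class TestSimulateCounts:
    def test_seed_determinism(self):
        design = SimDesign(n_tf=5, n_target=5, n_case=4, n_ref=4, seed=42)
        a, _ = simulate_counts(design)
        b, _ = simulate_counts(design)
        assert (a.counts.to_numpy() == b.counts.to_numpy()).all()

    def test_counts_nonnegative_integers(self):
        design = SimDesign(n_tf=5, n_target=5, n_case=4, n_ref=4, seed=0)
        cm, _ = simulate_counts(design)
        x = cm.counts.to_numpy()
        assert (x >= 0).all()
        assert np.issubdtype(x.dtype, np.integer)

    def test_attained_correlation_large_n(self):
        """Planted latent correlations survive to log counts within 0.1.

        At n=1500/group the sampling noise of r-hat (< 0.03 SD) is well inside
        the band, so this isolates the systematic attenuation from count noise.
        """
        design = SimDesign(
            n_tf=20, n_target=80, n_case=1500, n_ref=1500,
            coexpr_plan=hub_block_plan(), seed=5,
        )
        cm, _ = simulate_counts(design)
        logx = np.log2(cm.counts + 1.0)
        case = cm.groups[cm.groups == "case"].index
        ref = cm.groups[cm.groups == "reference"].index
        for a, b, r_case, r_ref in design.coexpr_plan:
            rc = np.corrcoef(logx.loc[a, case], logx.loc[b, case])[0, 1]
            rr = np.corrcoef(logx.loc[a, ref], logx.loc[b, ref])[0, 1]
            assert abs(rc - r_case) < 0.1, (a, b, rc)
            assert abs(rr - r_ref) < 0.1, (a, b, rr)

    def test_nb_marginals(self):
        """Sample mean ~ mu and variance >= mean (overdispersion) at large n."""
        design = SimDesign(
            n_tf=2, n_target=2, n_case=500, n_ref=500,
            mu_range=(300.0, 300.0), dispersion=0.05, latent_sd=0.0, seed=3,
        )
        cm, _ = simulate_counts(design)
        means = cm.counts.mean(axis=1)
        variances = cm.counts.var(axis=1)
        assert np.allclose(means, 300.0, rtol=0.1)
        assert (variances > means).all()  # var = mu + phi mu^2 >> mu
        # MoM dispersion close to the design value
        phi_hat = (variances - means) / means**2
        assert np.allclose(phi_hat, 0.05, atol=0.02)

    def test_de_plan_shifts_case_means(self):
        design = SimDesign(
            n_tf=2, n_target=2, n_case=400, n_ref=400,
            mu_range=(200.0, 200.0), dispersion=0.02, latent_sd=0.0,
            de_plan=[("TF0001", 1.0)], seed=9,
        )
        cm, truth = simulate_counts(design)
        case = cm.groups[cm.groups == "case"].index
        ref = cm.groups[cm.groups == "reference"].index
        ratio = cm.counts.loc["TF0001", case].mean() / cm.counts.loc["TF0001", ref].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)
        assert truth.de_genes == {"TF0001": 1.0}

    def test_null_design_groups_exchangeable(self):
        """With nothing planted, observed group-mean differences sit inside the
        permutation distribution (no systematic case/reference asymmetry)."""
        design = SimDesign(n_tf=10, n_target=10, n_case=8, n_ref=8, seed=21)
        cm, truth = simulate_counts(design)
        assert not truth.diff_pairs and not truth.de_genes
        rng = np.random.default_rng(0)
        x = np.log2(cm.counts.to_numpy() + 1.0)
        obs = x[:, :8].mean(axis=1) - x[:, 8:].mean(axis=1)
        perm_ps = []
        for g in range(x.shape[0]):
            null = []
            for _ in range(200):
                idx = rng.permutation(16)
                null.append(x[g, idx[:8]].mean() - x[g, idx[8:]].mean())
            null = np.asarray(null)
            perm_ps.append((np.abs(null) >= abs(obs[g])).mean())
        # p-values should not pile up near 0 (expect ~1 of 20 below 0.05 by chance)
        assert sum(p < 0.05 for p in perm_ps) <= 4

    def test_non_psd_plan_rejected_with_pairs(self):
        """A correlation star too tight to be PSD fails loudly, naming pairs."""
        plan = [("TF0001", t, 0.9, 0.0) for t in ("GLY0001", "GLY0002", "GLY0003")]
        design = SimDesign(n_tf=1, n_target=3, n_case=4, n_ref=4, coexpr_plan=plan, seed=0)
        with pytest.raises(InvalidDesignError, match="TF0001"):
            simulate_counts(design)

    def test_invalid_designs_rejected(self):
        with pytest.raises(InvalidDesignError):
            SimDesign(n_tf=2, n_target=2, n_case=2, n_ref=4)  # <3 per group
        with pytest.raises(InvalidDesignError):
            SimDesign(n_tf=2, n_target=2, n_case=4, n_ref=4, dispersion=-0.1)
        with pytest.raises(InvalidDesignError):
            SimDesign(n_tf=2, n_target=2, n_case=4, n_ref=4,
                      coexpr_plan=[("TF0001", "GLY0001", 1.0, 0.0)])  # |r| not < 1
        with pytest.raises(InvalidDesignError):
            SimDesign(n_tf=2, n_target=2, n_case=4, n_ref=4,
                      de_plan=[("NOPE", 1.0)])


class TestRegulatoryDBSim:
    @pytest.fixture()
    def truth_and_roles(self):
        design = SimDesign(
            n_tf=20, n_target=80, n_case=4, n_ref=4,
            coexpr_plan=hub_block_plan(), seed=1,
        )
        _, truth = simulate_counts(design)
        roles = generate_gene_roles(20, 80)
        return truth, roles

    def test_full_coverage_records_tf_pairs_exactly(self, truth_and_roles):
        truth, roles = truth_and_roles
        db = simulate_regulatory_db(roles, truth, 1.0, region_class="promoter", seed=0)
        tf_pairs = {p for p in truth.diff_pairs if p[0].startswith("TF") or p[1].startswith("TF")}
        emitted = {canonical(r.tf, r.target) for r in db.itertuples()}
        assert emitted == tf_pairs
        assert (db["binding_sites"] >= 1).all()
        assert (db["tf"] != db["target"]).all()
        assert (db["tf"].str.startswith("TF")).all()

    def test_zero_coverage_empty(self, truth_and_roles):
        truth, roles = truth_and_roles
        db = simulate_regulatory_db(roles, truth, 0.0, region_class="enhancer", seed=0)
        assert len(db) == 0

    def test_coverage_rounding(self, truth_and_roles):
        """Emitted record count is round(coverage * candidates) exactly."""
        truth, roles = truth_and_roles
        n_candidates = sum(
            1 for p in truth.diff_pairs if p[0].startswith("TF") or p[1].startswith("TF")
        )
        cov = 0.59
        db = simulate_regulatory_db(roles, truth, cov, region_class="promoter", seed=4)
        assert len(db) == round(cov * n_candidates)

    def test_decoys_avoid_truth(self, truth_and_roles):
        truth, roles = truth_and_roles
        db = simulate_regulatory_db(
            roles, truth, 0.0, extra_edges=25, region_class="promoter", seed=2
        )
        assert len(db) == 25
        for r in db.itertuples():
            assert canonical(r.tf, r.target) not in truth.diff_pairs

    def test_db_edges_recorded_in_truth(self, truth_and_roles):
        truth, roles = truth_and_roles
        before = len(truth.db_edges)
        db = simulate_regulatory_db(roles, truth, 1.0, region_class="promoter", seed=0)
        assert len(truth.db_edges) == before + len(db)

    def test_hub_tf_identified(self, truth_and_roles):
        truth, _ = truth_and_roles
        assert truth.hub_tfs == {"TF0001"}
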