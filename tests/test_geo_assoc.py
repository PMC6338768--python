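import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geostrat.geo_assoc import (
    compute_pcs,
    genomic_lambda,
    ps_geo_battery,
    structure_gwas,
)
from geostrat.scores import build_ps, greedy_clump, ztransform
from geostrat.simpop import (
    GenotypeMatrix,
    SimulationConfig,
    TraitSpec,
    simulate_cohort,
    simulate_source_freqs,
    true_weight_table,
)


def _two_pop_matrix(seed=0, n_per=300, m=2000, fst=0.2):
    """Two well-separated source populations, no admixture."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    ratio = (1 - fst) / fst
    f = np.clip(rng.beta(p * ratio, (1 - p) * ratio, size=(2, m)), 0.001, 0.999)
    d = np.vstack([
        rng.binomial(2, f[0], size=(n_per, m)),
        rng.binomial(2, f[1], size=(n_per, m)),
    ]).astype(float)
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": (np.arange(m) % 22) + 1,
        "pos": (np.arange(m) // 22 + 1) * 500_000,
        "effect_allele": "A", "other_allele": "G",
        "maf": 0.25, "info": 1.0,
    })
    labels = np.array([0] * n_per + [1] * n_per)
    geno = GenotypeMatrix(d, variants, np.array([f"i{k}" for k in range(2 * n_per)]))
    return geno, labels


class TestComputePcs:
    def test_pc1_separates_two_populations(self):
        geno, labels = _two_pop_matrix()
        pcs = compute_pcs(geno, n_pcs=4, thin_kb=0)
        side = pcs.scores[:, 0] > 0
        acc = max((side == labels).mean(), (side == (1 - labels)).mean())
        assert acc >= 0.99

    def test_eigenvalues_non_increasing(self):
        geno, _ = _two_pop_matrix(seed=1, n_per=100, m=500)
        pcs = compute_pcs(geno, n_pcs=6, thin_kb=0)
        assert (np.diff(pcs.eigenvalues) <= 1e-9).all()

    def test_scores_unit_variance_and_orthogonal(self):
        geno, _ = _two_pop_matrix(seed=2, n_per=100, m=500)
        pcs = compute_pcs(geno, n_pcs=5, thin_kb=0)
        np.testing.assert_allclose(pcs.scores.std(axis=0), 1.0, atol=1e-6)
        gram = pcs.scores.T @ pcs.scores / pcs.scores.shape[0]
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-6)

    def test_permuting_individuals_permutes_scores(self):
        geno, _ = _two_pop_matrix(seed=3, n_per=50, m=400)
        pcs = compute_pcs(geno, n_pcs=3, thin_kb=0)
        perm = np.random.default_rng(0).permutation(geno.n_samples)
        geno_p = GenotypeMatrix(geno.dosages[perm], geno.variants, geno.sample_ids[perm])
        pcs_p = compute_pcs(geno_p, n_pcs=3, thin_kb=0)
        np.testing.assert_allclose(pcs_p.scores, pcs.scores[perm], atol=1e-6)

    def test_positional_thinning_reduces_variants(self):
        geno, _ = _two_pop_matrix(seed=4, n_per=50, m=440)
        pcs_all = compute_pcs(geno, n_pcs=2, thin_kb=0)
        pcs_thin = compute_pcs(geno, n_pcs=2, thin_kb=1000)
        assert len(pcs_thin.variant_ids) < len(pcs_all.variant_ids)

    def test_too_many_pcs_rejected(self):
        geno, _ = _two_pop_matrix(seed=5, n_per=10, m=50)
        with pytest.raises(ValueError):
            compute_pcs(geno, n_pcs=20)

    def test_pc1_tracks_gradient_over_seeds(self):
        """With a gradient on, PC1 aligns with the gradient projection."""
        passed = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_individuals=2000, n_variants=1000, n_sources=3, fst=0.05, seed=seed
            )
            sim = simulate_cohort(cfg, simulate_source_freqs(cfg))
            pcs = compute_pcs(sim.genotypes, n_pcs=2)
            axis = np.asarray(cfg.gradient_axis)
            proj = (
                sim.cohort.table["birth_north"] * axis[0]
                + sim.cohort.table["birth_east"] * axis[1]
            )
            passed += abs(np.corrcoef(pcs.scores[:, 0], proj)[0, 1]) > 0.5
        assert passed >= 8


class TestStructureGwas:
    def test_tier1_matches_simple_regression_closed_form(self, small_sim):
        res = structure_gwas(small_sim.genotypes, small_sim.cohort, "north_south", 1)
        y = small_sim.cohort.table["birth_north"].to_numpy(dtype=float)
        n = y.size
        for _, row in res.table.head(20).iterrows():
            j = list(small_sim.genotypes.variants["variant_id"]).index(row["variant_id"])
            x = small_sim.genotypes.dosages[:, j]
            xc = x - x.mean()
            beta = (xc @ y) / (xc @ xc)
            resid = y - y.mean() - beta * xc
            se = np.sqrt((resid @ resid) / (n - 2) / (xc @ xc))
            p = 2 * stats.t.sf(abs(beta / se), df=n - 2)
            assert row["beta"] == pytest.approx(beta, rel=1e-10)
            assert row["se"] == pytest.approx(se, rel=1e-10)
            assert row["p"] == pytest.approx(p, rel=1e-8)

    def test_constant_dosage_skipped(self, small_sim):
        geno = small_sim.genotypes
        d = geno.dosages.copy()
        d[:, 0] = 2.0
        geno2 = GenotypeMatrix(d, geno.variants, geno.sample_ids)
        res = structure_gwas(geno2, small_sim.cohort, "north_south", 1)
        assert geno.variants["variant_id"].iloc[0] in res.skipped
        assert geno.variants["variant_id"].iloc[0] not in set(res.table["variant_id"])

    def test_tier_ordering_median_chi2(self):
        """Median per-variant chi-square is non-increasing tier 1 -> 4 on
        clinal cohorts."""
        passed = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_individuals=1500, n_variants=600, n_sources=3, fst=0.1, seed=seed
            )
            sim = simulate_cohort(cfg, simulate_source_freqs(cfg))
            pcs = compute_pcs(sim.genotypes, n_pcs=20)
            med = []
            for tier in (1, 2, 3, 4):
                res = structure_gwas(
                    sim.genotypes, sim.cohort, "north_south", tier, pcs, pc_counts=(10, 20)
                )
                chi2 = stats.chi2.isf(np.maximum(res.table["p"], 1e-300), df=1)
                med.append(np.median(chi2))
            # the array covariate is pure noise, so allow 1% slack per step
            passed += all(med[i] >= med[i + 1] - 0.01 * med[i] - 0.05 for i in range(3))
        assert passed >= 2


class TestGenomicLambda:
    def test_uniform_pvalues_give_lambda_one(self):
        p = np.random.default_rng(0).uniform(0, 1, 10_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.05)

    def test_halving_pvalues_inflates(self):
        p = np.random.default_rng(1).uniform(0, 1, 5000)
        assert genomic_lambda(p / 2) > 1.0

    def test_hand_computed_on_fixed_values(self):
        p = np.array([0.01, 0.2, 0.5, 0.8, 0.95] * 20)
        expected = np.median(stats.chi2.isf(p, 1)) / 0.4549
        assert genomic_lambda(p) == pytest.approx(expected, rel=1e-12)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.full(50, 0.5))

    def test_zero_pvalues_clamped_with_warning(self):
        p = np.concatenate([[0.0], np.random.default_rng(2).uniform(0, 1, 200)])
        with pytest.warns(UserWarning, match="clamped"):
            genomic_lambda(p)


@pytest.fixture(scope="module")
def battery():
    cfg = SimulationConfig(
        n_individuals=1500, n_variants=500, n_sources=3, fst=0.1,
        gradient_axis=(1.0, 0.0), seed=55,
        trait_specs=[TraitSpec("t", genetic_weight=0.5, noise_sd=1.0, cline_coupling=0.9)],
    )
    sim = simulate_cohort(cfg, simulate_source_freqs(cfg))
    ps = ztransform(
        build_ps(sim.genotypes, greedy_clump(true_weight_table(sim, "t"), 250, 5e-8),
                 "weighted", 5e-8)
    )
    pcs = compute_pcs(sim.genotypes, n_pcs=20)
    return ps_geo_battery({"t_w": ps}, sim.cohort, pcs, pc_counts=(10, 20))


class TestPsGeoBattery:
    def test_tier1_detects_cline_on_gradient_axis(self, battery):
        row = battery.set_index("axis").loc["north_south"]
        assert row["model1"] < 1e-6

    def test_adjustment_attenuates_but_probably_not_off_axis(self, battery):
        ns = battery.set_index("axis").loc["north_south"]
        ew = battery.set_index("axis").loc["east_west"]
        # gradient is purely north-south: east-west tier 1 is null
        assert ew["model1"] > 0.001
        # adjustment attenuates evidence on the structured axis
        assert ns["model4"] > ns["model1"]

    def test_unstandardized_ps_rejected(self, small_sim):
        from geostrat.scores import PolygenicScore

        raw = PolygenicScore(
            pd.Series(np.ones(small_sim.cohort.n)), "weighted", 5e-8, False, 3
        )
        with pytest.raises(ValueError, match="z-transformed"):
            ps_geo_battery({"raw": raw}, small_sim.cohort, None, tiers=(1,))
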