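"""Genotype QC, Hardy-Weinberg exact test vs full-enumeration oracle, LD
pruning vs brute force, GRM/PCA, and burden collapsing bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from cmqtl import genotypes as gt
from cmqtl.config import SimulationConfig
from cmqtl.simulate import simulate_genotypes


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Direct log-factorial enumeration (independent of the recurrence)."""
    n = n_aa + n_ab + n_bb
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_ab)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def make_genotypes(dosages, chrom="1", pos_start=100, ref="A", alt="G",
                   genes=None, impacts=None, filters=None):
    dosages = np.asarray(dosages, dtype=float)
    n_donors, n_var = dosages.shape
    ids = [f"v{j}" for j in range(n_var)]
    variants = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n_var,
            "pos": np.arange(pos_start, pos_start + 10 * n_var, 10),
            "ref": ref if isinstance(ref, list) else [ref] * n_var,
            "alt": alt if isinstance(alt, list) else [alt] * n_var,
            "filter": filters or ["PASS"] * n_var,
        },
        index=pd.Index(ids, name="id"),
    )
    annotation = pd.DataFrame(
        {
            "gene": genes or [""] * n_var,
            "impact": impacts or ["MODIFIER"] * n_var,
        },
        index=variants.index,
    )
    donors = np.array([f"D{i}" for i in range(n_donors)])
    return gt.GenotypeSet(donors, variants, dosages, annotation)


class TestHWEExactTest:
    def test_perfect_proportions_give_p_one(self):
        assert gt.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_departure_is_tiny(self):
        assert gt.hwe_exact_test(50, 0, 50) < 1e-5

    def test_matches_enumeration_oracle_small_grid(self):
        for n_aa in range(0, 12):
            for n_ab in range(0, 12):
                for n_bb in range(0, 12):
                    if n_aa + n_ab + n_bb == 0:
                        continue
                    assert gt.hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_oracle(n_aa, n_ab, n_bb), abs=1e-10
                    ), (n_aa, n_ab, n_bb)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            gt.hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            gt.hwe_exact_test(0, 0, 0)


class TestCommonVariantQC:
    def test_structural_filters(self):
        doses = np.tile([0, 1, 2, 1, 0, 1, 2, 1, 0, 1], (20, 1)).T.astype(float)
        doses = np.random.default_rng(0).binomial(1, 0.4, size=(40, 6)).astype(float)
        g = make_genotypes(
            doses,
            chrom=["1", "X", "2", "2", "2", "3"],
            ref=["A", "A", "A", "ACGTACG", "A", "A"],
            alt=["G", "G", "G,T", "A", "G", "G"],
            filters=["PASS", "PASS", "PASS", "PASS", "PASS", "LOWQUAL"],
        )
        # duplicate position pair on chrom 2
        g.variants.loc["v4", "pos"] = g.variants.loc["v2", "pos"]
        out, report = gt.qc_common_variants(g, maf_min=0.0, miss_max=1.0, hwe_p_min=0.0)
        assert list(out.variant_ids) == ["v0"]

    def test_maf_boundary(self):
        rng = np.random.default_rng(1)
        low = rng.binomial(2, 0.04, size=(500, 1)).astype(float)
        ok = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
        g = make_genotypes(np.hstack([low, ok]))
        out, _ = gt.qc_common_variants(g)
        assert list(out.variant_ids) == ["v1"]

    def test_planted_failure_bookkeeping(self):
        cfg = SimulationConfig(
            n_donors=150, n_plates=2, n_traits=2, n_common_variants=40, n_genes=5,
            maf_range_common=(0.15, 0.45), seed=21,
            planted_qc_failures={"low_maf": 5, "high_missing": 4, "hwe_violation": 3},
        )
        g, truth = simulate_genotypes(cfg)
        out, report = gt.qc_common_variants(g)
        retained = set(out.variant_ids)
        for cls, ids in truth.planted_fail_ids.items():
            assert not retained & set(ids), cls
        # every common variant passes (MAF range comfortably above threshold)
        assert retained == {v for v in g.variant_ids if v.startswith("cv")}

    def test_donor_missingness_filter(self):
        rng = np.random.default_rng(2)
        doses = rng.binomial(2, 0.3, size=(50, 30)).astype(float)
        doses[0, :20] = np.nan  # donor 0: 66% missing
        g = make_genotypes(doses)
        out, report = gt.qc_common_variants(g, miss_max=1.0, hwe_p_min=0.0)
        assert report.counts["donors_dropped"] == 1
        assert "D0" not in out.donors


class TestLDPrune:
    def test_duplicate_pair_keeps_one(self, rng):
        x = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        g = make_genotypes(np.hstack([x, x]))
        kept = gt.ld_prune(g, mode="count")
        assert len(kept) == 1

    def test_independent_variants_all_kept(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, size=(500, 20)).astype(float))
        kept = gt.ld_prune(g, mode="count")
        assert len(kept) == 20

    def test_unsorted_positions_raise(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, size=(50, 3)).astype(float))
        g.variants["pos"] = [300, 100, 200]
        with pytest.raises(ValueError, match="sorted"):
            gt.ld_prune(g, mode="count")

    def test_exclusion_regions_removed_first(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, size=(50, 5)).astype(float))
        # positions 100,110,...; exclude [0, 115) 0-based half-open
        kept = gt.ld_prune(g, mode="bp", exclude_regions=[("1", 0, 115)])
        assert set(kept) <= {"v2", "v3", "v4"}

    @staticmethod
    def bruteforce_check(g, kept, r2_threshold):
        """Oracle properties: retained pairs below threshold; every removed
        variant exceeds the threshold with some retained one (maximality)."""
        dose = g.dosage_frame()
        kept = set(kept)
        r2 = gt._pairwise_r2(dose.to_numpy())
        ids = list(dose.columns)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j and a in kept and b in kept:
                    assert r2[i, j] <= r2_threshold + 1e-12
        for i, a in enumerate(ids):
            if a not in kept:
                partners = [r2[i, ids.index(b)] for b in kept]
                assert max(partners) > r2_threshold

    def test_block_fixture_matches_bruteforce(self, rng):
        blocks = []
        for _ in range(4):
            base = rng.binomial(2, 0.4, size=(300, 1)).astype(float)
            members = [base.copy() for _ in range(5)]
            for m in members[1:]:
                flip = rng.random(300) < 0.02
                m[flip, 0] = rng.binomial(2, 0.4, size=int(flip.sum()))
            blocks.append(np.hstack(members))
        g = make_genotypes(np.hstack(blocks))
        kept = gt.ld_prune(g, mode="count", r2_threshold=0.2, window=50, step=5)
        assert len(kept) == 4
        self.bruteforce_check(g, kept, 0.2)


class TestGRMAndPCA:
    def test_matches_double_loop_oracle(self, rng):
        doses = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(12, 30)).astype(float)
        g = make_genotypes(doses)
        grm = gt.compute_grm(g)
        p = doses.mean(axis=0) / 2
        expected = np.zeros((12, 12))
        m = 0
        for v in range(30):
            if 0 < p[v] < 1:
                w = (doses[:, v] - 2 * p[v]) / np.sqrt(2 * p[v] * (1 - p[v]))
                expected += np.outer(w, w)
                m += 1
        expected /= m
        np.testing.assert_allclose(grm.to_numpy(), expected, atol=1e-10)

    def test_diagonal_near_one_under_hwe(self, rng):
        doses = rng.binomial(2, 0.3, size=(100, 3000)).astype(float)
        grm = gt.compute_grm(make_genotypes(doses))
        assert np.diag(grm).mean() == pytest.approx(1.0, abs=0.05)

    def test_duplicate_donor_relatedness(self, rng):
        doses = rng.binomial(2, rng.uniform(0.1, 0.5, 500), size=(10, 500)).astype(float)
        doses = np.vstack([doses, doses[0]])  # donor 10 duplicates donor 0
        grm = gt.compute_grm(make_genotypes(doses))
        a = grm.to_numpy()
        assert a[0, 10] == pytest.approx(a[0, 0], rel=1e-9)

    def test_spectral_reconstruction(self, rng):
        doses = rng.binomial(2, 0.3, size=(25, 400)).astype(float)
        grm = gt.compute_grm(make_genotypes(doses))
        pcs = gt.pca_from_grm(grm, k=25)
        assert pcs.eigenvalues.sum() <= np.trace(grm.to_numpy()) + 1e-8
        recon = pcs.components.to_numpy() @ pcs.components.to_numpy().T
        np.testing.assert_allclose(recon, grm.to_numpy(), atol=1e-8)

    def test_two_population_separation(self, rng):
        from sklearn.metrics import silhouette_score

        n_var = 400
        p1 = rng.uniform(0.1, 0.9, n_var)
        shift = rng.choice([-0.3, 0.3], n_var)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        pop1 = rng.binomial(2, p1, size=(40, n_var)).astype(float)
        pop2 = rng.binomial(2, p2, size=(40, n_var)).astype(float)
        grm = gt.compute_grm(make_genotypes(np.vstack([pop1, pop2])))
        pcs = gt.pca_from_grm(grm, k=2)
        labels = np.repeat([0, 1], 40)
        score = silhouette_score(pcs.components.iloc[:, :1], labels)
        assert score > 0.8

    def test_k_too_large_raises(self, rng):
        grm = gt.compute_grm(make_genotypes(rng.binomial(2, 0.3, size=(5, 50)).astype(float)))
        with pytest.raises(ValueError, match="exceeds"):
            gt.pca_from_grm(grm, k=6)

    def test_sign_convention_deterministic(self, rng):
        doses = rng.binomial(2, 0.3, size=(20, 100)).astype(float)
        grm = gt.compute_grm(make_genotypes(doses))
        pcs = gt.pca_from_grm(grm, k=3).components
        for col in pcs.columns:
            assert pcs[col].iloc[np.argmax(np.abs(pcs[col].to_numpy()))] > 0


class TestBurdenCollapsing:
    def test_min_carrier_count_is_ceiling(self):
        import math

        assert math.ceil(0.02 * 297) == 6  # the cohort's printed floor

    def test_hom_alt_donor_is_carrier(self):
        doses = np.zeros((10, 1))
        doses[3, 0] = 2.0
        g = make_genotypes(doses, genes=["G1"], impacts=["HIGH"])
        burden = gt.collapse_rare_burden(g, maf_max=0.5, min_carrier_fraction=0.0)
        assert burden.indicators.loc["D3", "G1"] == 1
        assert burden.carrier_counts["G1"] == 1

    def test_carrier_registry_bookkeeping(self):
        cfg = SimulationConfig(
            n_donors=200, n_plates=2, n_traits=2, n_common_variants=0, n_genes=30,
            rare_variants_per_gene=(2, 5), maf_range_rare=(0.002, 0.008), seed=23,
        )
        g, truth = simulate_genotypes(cfg)
        burden = gt.collapse_rare_burden(
            g, maf_max=0.5, call_rate_min=0.0, min_carrier_fraction=0.0
        )
        for gene, carriers in truth.carriers.items():
            if carriers:
                observed = np.nonzero(burden.indicators[gene].to_numpy())[0]
                np.testing.assert_array_equal(observed, carriers)

    def test_carrier_floor_drops_sparse_genes(self):
        doses = np.zeros((100, 2))
        doses[:5, 0] = 1.0  # 5 carriers < ceil(0.06*100)=6
        doses[:10, 1] = 1.0
        g = make_genotypes(doses, genes=["G1", "G2"], impacts=["HIGH", "HIGH"])
        burden = gt.collapse_rare_burden(g, maf_max=0.5, min_carrier_fraction=0.06)
        assert burden.genes == ["G2"]

    def test_impact_filter(self):
        doses = np.zeros((50, 2))
        doses[:10, 0] = 1.0
        doses[:10, 1] = 1.0
        g = make_genotypes(doses, genes=["G1", "G2"], impacts=["LOW", "MODERATE"])
        burden = gt.collapse_rare_burden(g, maf_max=0.5, min_carrier_fraction=0.0)
        assert burden.genes == ["G2"]
        assert burden.contributing_variants["G2"] == ["v1"]
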