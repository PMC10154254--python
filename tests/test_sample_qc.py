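"""Kinship recovery, unrelated-set pruning and ancestry classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ssns_grs import (
    estimate_kinship,
    fit_reference_pca,
    maximal_unrelated_set,
    project_and_classify,
    select_pca_markers,
)
from ssns_grs.errors import DimensionError, InputError, ProjectionError
from ssns_grs.sample_qc import KinshipMatrix, project_onto_pca
from ssns_grs.synthetic_data import PanelSpec, PedigreeBlock, simulate_panel


@pytest.fixture(scope="module")
def pedigree_panel():
    """20k markers, 10 unrelated founders plus two sib-ship blocks."""
    spec = PanelSpec(
        n_markers=20_000,
        n_populations=1,
        divergence=0.0,
        n_per_population=10,
        pedigree_blocks=(PedigreeBlock(0, 2), PedigreeBlock(0, 3)),
        seed=901,
    )
    return simulate_panel(spec)


@pytest.fixture(scope="module")
def five_pop_panel():
    """5 populations at divergence 0.05, 10k markers, 140 samples each."""
    spec = PanelSpec(
        n_markers=10_000,
        n_populations=5,
        divergence=0.05,
        n_per_population=140,
        seed=902,
    )
    return simulate_panel(spec)


class TestSelectPcaMarkers:
    def test_independent_markers_mostly_retained(self, rng):
        from ssns_grs.synthetic_data import simulate_panel as sim

        spec = PanelSpec(
            n_markers=5_000, n_populations=1, n_per_population=2_000, seed=77
        )
        matrix, _, _ = sim(spec)
        kept = select_pca_markers(
            matrix, n_target=(1, 5_000), maf_min=0.01, r2_prune=0.1
        )
        assert len(kept) >= 0.95 * 5_000

    def test_duplicated_markers_pruned_to_one(self, rng):
        from ssns_grs.genotype_io import GenotypeMatrix
        from ssns_grs.genotype_io import VARIANT_COLUMNS

        base = rng.binomial(2, 0.4, size=(300, 20)).astype(float)
        dosages = np.column_stack([base, base])  # every marker duplicated
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(40) * 100 + 1,
                "id": [f"m{i}" for i in range(40)],
                "ref": "A",
                "alt": "G",
                "rsq": np.nan,
                "opr": np.nan,
                "multiallelic": False,
            },
            columns=VARIANT_COLUMNS,
        )
        matrix = GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(300)],
            variants=variants,
            dosages=dosages,
        )
        kept = select_pca_markers(matrix, n_target=(1, 40), window=40, step=20)
        assert len(kept) == 20
        # exactly one member of each duplicate pair survives
        assert sorted(k % 20 for k in kept) == list(range(20))

    def test_monomorphic_removed_by_maf_filter(self, rng):
        from ssns_grs.genotype_io import GenotypeMatrix, VARIANT_COLUMNS

        poly = rng.binomial(2, 0.3, size=(100, 30)).astype(float)
        mono = np.zeros((100, 10))
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(40) * 10 + 1,
                "id": [f"m{i}" for i in range(40)],
                "ref": "A",
                "alt": "G",
                "rsq": np.nan,
                "opr": np.nan,
                "multiallelic": False,
            },
            columns=VARIANT_COLUMNS,
        )
        matrix = GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(100)],
            variants=variants,
            dosages=np.column_stack([poly, mono]),
        )
        kept = select_pca_markers(matrix, n_target=(1, 40), maf_min=0.05)
        assert (kept < 30).all()


class TestKinship:
    def test_duplicate_sample_phi_half(self, pedigree_panel):
        matrix, samples, _ = pedigree_panel
        dup = matrix.subset_samples(matrix.sample_ids[:5])
        dup.sample_ids = [f"d{i}" for i in range(5)]
        import copy

        both = copy.deepcopy(matrix.subset_samples(matrix.sample_ids[:5]))
        both.sample_ids = [f"o{i}" for i in range(5)]
        merged_dosages = np.vstack([both.dosages, dup.dosages])
        from ssns_grs.genotype_io import GenotypeMatrix

        merged = GenotypeMatrix(
            sample_ids=both.sample_ids + dup.sample_ids,
            variants=matrix.variants.copy(),
            dosages=merged_dosages,
        )
        kin = estimate_kinship(merged)
        for i in range(5):
            assert kin.phi[i, i + 5] == pytest.approx(0.5, abs=1e-12)

    def test_full_sibs_quarter(self, pedigree_panel):
        matrix, _, pairs = pedigree_panel
        kin = estimate_kinship(matrix)
        idx = {s: i for i, s in enumerate(kin.sample_ids)}
        sib = pairs[pairs["relationship"] == "full-sib"]
        phis = [kin.phi[idx[a], idx[b]] for a, b in zip(sib["id1"], sib["id2"])]
        assert np.mean(phis) == pytest.approx(0.25, abs=0.02)

    def test_parent_offspring_quarter(self, pedigree_panel):
        matrix, _, pairs = pedigree_panel
        kin = estimate_kinship(matrix)
        idx = {s: i for i, s in enumerate(kin.sample_ids)}
        po = pairs[pairs["relationship"] == "parent-offspring"]
        phis = [kin.phi[idx[a], idx[b]] for a, b in zip(po["id1"], po["id2"])]
        assert np.mean(phis) == pytest.approx(0.25, abs=0.02)

    def test_unrelated_near_zero(self, pedigree_panel):
        matrix, samples, _ = pedigree_panel
        founders = samples[samples["block"] == -1]["sample_id"].tolist()
        kin = estimate_kinship(matrix.subset_samples(founders))
        off_diag = kin.phi[~np.eye(len(founders), dtype=bool)]
        assert np.abs(off_diag).max() < 0.02

    def test_symmetry_and_permutation_equivariance(self, pedigree_panel):
        matrix, _, _ = pedigree_panel
        sub = matrix.subset_samples(matrix.sample_ids[:8])
        kin = estimate_kinship(sub)
        np.testing.assert_allclose(kin.phi, kin.phi.T)
        perm = list(reversed(sub.sample_ids))
        kin_p = estimate_kinship(sub.subset_samples(perm))
        order = [sub.sample_ids.index(s) for s in perm]
        np.testing.assert_allclose(kin_p.phi, kin.phi[np.ix_(order, order)])

    def test_single_sample_rejected(self, pedigree_panel):
        matrix, _, _ = pedigree_panel
        with pytest.raises(InputError):
            estimate_kinship(matrix.subset_samples(matrix.sample_ids[:1]))


def _brute_force_mis_size(adj: np.ndarray) -> int:
    """Exact maximum-independent-set size by bitmask enumeration (n <= 15)."""
    n = adj.shape[0]
    nbr = [0] * n
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                nbr[i] |= 1 << j
    best = 0
    for mask in range(1 << n):
        ok = True
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if nbr[i] & mask:
                ok = False
                break
            m &= m - 1
        if ok:
            best = max(best, mask.bit_count())
    return best


class TestUnrelatedSet:
    def _kin(self, ids, related_pairs):
        n = len(ids)
        phi = np.zeros((n, n))
        for a, b in related_pairs:
            i, j = ids.index(a), ids.index(b)
            phi[i, j] = phi[j, i] = 0.25
        np.fill_diagonal(phi, 0.5)
        return KinshipMatrix(sample_ids=ids, phi=phi)

    def test_all_unrelated_all_kept(self):
        ids = [f"s{i}" for i in range(6)]
        kept = maximal_unrelated_set(self._kin(ids, []))
        assert kept == ids

    def test_duplicate_pair_drops_exactly_one(self):
        ids = ["a", "b", "c", "d"]
        kept = maximal_unrelated_set(self._kin(ids, [("a", "b")]))
        assert len(kept) == 3
        assert ("a" in kept) != ("b" in kept)

    def test_tie_breaks_toward_higher_missingness(self):
        ids = ["a", "b"]
        kept = maximal_unrelated_set(
            self._kin(ids, [("a", "b")]), missingness={"a": 0.1, "b": 0.0}
        )
        assert kept == ["b"]

    def test_threshold_must_be_positive(self):
        with pytest.raises(InputError):
            maximal_unrelated_set(self._kin(["a", "b"], []), threshold=0.0)

    def test_matches_exhaustive_search_on_trio_instances(self, rng):
        """On clique-structured relatedness graphs (simulated trios) the
        greedy set is a valid independent set within one of the optimum."""
        for rep in range(20):
            n = int(rng.integers(6, 15))
            ids = [f"s{i:02d}" for i in range(n)]
            phi = np.zeros((n, n))
            # random trio blocks: parent-parent unrelated, parent-child and
            # sib-sib related
            order = rng.permutation(n)
            for start in range(0, n - 2, 3):
                p1, p2, child = order[start : start + 3]
                phi[p1, child] = phi[child, p1] = 0.25
                phi[p2, child] = phi[child, p2] = 0.25
            # some extra random related pairs
            for _ in range(int(rng.integers(0, 4))):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    phi[i, j] = phi[j, i] = 0.1
            kin = KinshipMatrix(sample_ids=ids, phi=phi)
            kept = maximal_unrelated_set(kin, threshold=0.0442)
            keep_idx = [ids.index(s) for s in kept]
            adj = phi > 0.0442
            np.fill_diagonal(adj, False)
            assert not adj[np.ix_(keep_idx, keep_idx)].any()
            assert len(kept) >= _brute_force_mis_size(adj) - 1


class TestPcaAncestry:
    def test_two_populations_separate_on_pc1(self):
        spec = PanelSpec(
            n_markers=2_000,
            n_populations=2,
            divergence=0.1,
            n_per_population=100,
            seed=31,
        )
        matrix, samples, _ = simulate_panel(spec)
        pca = fit_reference_pca(matrix, k=2)
        pc1 = pca.reference_scores[:, 0]
        labels = samples["population"].to_numpy()
        a, b = pc1[labels == "POP0"], pc1[labels == "POP1"]
        # linear separability on PC1: the two ranges barely overlap
        cut = (a.mean() + b.mean()) / 2
        acc = max(
            np.mean(np.concatenate([(a < cut), (b >= cut)])),
            np.mean(np.concatenate([(a >= cut), (b < cut)])),
        )
        assert acc > 0.99

    def test_projection_identity_on_reference(self, five_pop_panel):
        matrix, _, _ = five_pop_panel
        ref = matrix.subset_samples(matrix.sample_ids[:200])
        pca = fit_reference_pca(ref, k=5)
        proj = project_onto_pca(pca, ref)
        np.testing.assert_allclose(proj, pca.reference_scores, atol=1e-8)

    def test_k_beyond_rank_rejected(self, rng):
        from ssns_grs.genotype_io import GenotypeMatrix, VARIANT_COLUMNS

        dosages = rng.binomial(2, 0.5, size=(4, 50)).astype(float)
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(50) + 1,
                "id": [f"m{i}" for i in range(50)],
                "ref": "A",
                "alt": "G",
                "rsq": np.nan,
                "opr": np.nan,
                "multiallelic": False,
            },
            columns=VARIANT_COLUMNS,
        )
        matrix = GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(4)],
            variants=variants,
            dosages=dosages,
        )
        with pytest.raises(DimensionError):
            fit_reference_pca(matrix, k=10)

    def test_five_population_classification_accuracy(self, five_pop_panel):
        """>= 99% correct labels on a 5-population panel (divergence 0.05)."""
        matrix, samples, _ = five_pop_panel
        by_pop = samples.groupby("population")["sample_id"]
        ref_ids = by_pop.apply(lambda s: s.iloc[:100]).tolist()
        study_ids = by_pop.apply(lambda s: s.iloc[100:]).tolist()
        ref = matrix.subset_samples(ref_ids)
        study = matrix.subset_samples(study_ids)
        pca = fit_reference_pca(ref, k=10)
        labels = samples.set_index("sample_id").loc[ref_ids, "population"].tolist()
        assigns = project_and_classify(pca, study, labels)
        truth = samples.set_index("sample_id")["population"]
        acc = np.mean([a.label == truth[a.sample_id] for a in assigns])
        assert acc >= 0.99

    def test_admixed_sample_unassigned(self, rng):
        """A 50/50 mixture of two distant populations stays unassigned."""
        spec = PanelSpec(
            n_markers=5_000,
            n_populations=2,
            divergence=0.15,
            n_per_population=100,
            seed=41,
        )
        matrix, samples, _ = simulate_panel(spec)
        pca = fit_reference_pca(matrix, k=4)
        freqs = matrix.variants.attrs["population_freqs"]
        admixed = rng.binomial(1, freqs[0]) + rng.binomial(1, freqs[1])
        from ssns_grs.genotype_io import GenotypeMatrix

        study = GenotypeMatrix(
            sample_ids=["admixed"],
            variants=matrix.variants.copy(),
            dosages=admixed[None, :].astype(float),
        )
        labels = samples["population"].tolist()
        assigns = project_and_classify(pca, study, labels, confidence_floor=0.9)
        assert assigns[0].label == "unassigned"

    def test_empty_study_empty_assignments(self, five_pop_panel):
        matrix, samples, _ = five_pop_panel
        ref = matrix.subset_samples(matrix.sample_ids[:200])
        pca = fit_reference_pca(ref, k=3)
        empty = matrix.subset_samples([])
        labels = samples.set_index("sample_id").loc[
            matrix.sample_ids[:200], "population"
        ].tolist()
        assert project_and_classify(pca, empty, labels) == []

    def test_low_overlap_rejected(self, five_pop_panel):
        matrix, _, _ = five_pop_panel
        ref = matrix.subset_samples(matrix.sample_ids[:100])
        pca = fit_reference_pca(ref, k=3)
        # keep only 10% of markers in the study matrix
        study = matrix.subset_samples(matrix.sample_ids[100:110])
        keep = np.zeros(study.n_variants, dtype=bool)
        keep[: study.n_variants // 10] = True
        study = study.subset_variants(keep)
        with pytest.raises(ProjectionError):
            project_onto_pca(pca, study)
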