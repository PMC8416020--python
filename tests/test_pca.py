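"""Alignment mapping, curation rules, superposition, PCA and projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from aquaprobe.pca import (
    EnsemblePCA,
    StructureEntry,
    build_coordinate_table,
    count_retained,
    curate_ensemble,
    expand_interval_list,
    fit_pca,
    project_conformers,
    superpose_ensemble,
)
from aquaprobe.synthetic import (
    EnsembleTruth,
    gen_structure_ensemble,
    write_structure_ensemble,
)

from conftest import curation_oracle, optimal_rmsd_oracle


def entries_from_missing(missing, seed=0):
    """StructureEntries over a random base chain with a given missing matrix."""
    missing = np.asarray(missing, bool)
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 30, size=(missing.shape[1], 3))
    entries = []
    for s in range(missing.shape[0]):
        coords = base + rng.normal(scale=0.2, size=base.shape)
        coords[missing[s]] = np.nan
        entries.append(StructureEntry(id=f"S{s}", calpha=coords))
    return entries


class TestBuildCoordinateTable:
    def test_gapless_structures_fully_observed(self):
        aln = {f"S{i}": "A" * 10 for i in range(3)}
        coords = {
            f"S{i}": {c + 1: (float(c), float(i), 0.0) for c in range(10)}
            for i in range(3)
        }
        entries = build_coordinate_table(aln, coords)
        assert len(entries) == 3
        assert not any(e.missing_mask.any() for e in entries)

    def test_gap_maps_to_missing(self):
        aln = {"S0": "AAA-AAAAAA", "S1": "A" * 10}
        coords = {
            sid: {c + 1: (float(c), 0.0, 0.0) for c in range(10)} for sid in aln
        }
        entries = build_coordinate_table(aln, coords)
        by_id = {e.id: e for e in entries}
        assert by_id["S0"].missing_mask[3]
        assert not by_id["S1"].missing_mask.any()

    def test_absent_coordinate_row_maps_to_missing(self):
        aln = {"S0": "AAAAAAAAAA", "S1": "A" * 10}
        coords = {
            "S0": {c + 1: (float(c), 0.0, 0.0) for c in range(10) if c != 6},
            "S1": {c + 1: (float(c), 0.0, 0.0) for c in range(10)},
        }
        entries = build_coordinate_table(aln, coords)
        assert {e.id: e for e in entries}["S0"].missing_mask[6]

    def test_missing_id_rejected(self):
        aln = {"S0": "AAAA" * 3, "S1": "AAAA" * 3}
        with pytest.raises(ValueError, match="no coordinate table"):
            build_coordinate_table(aln, {"S0": {1: (0.0, 0.0, 0.0)}})

    def test_unequal_alignment_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_coordinate_table({"S0": "AAAA", "S1": "AAAAA"}, {})

    def test_file_round_trip(self, tmp_path):
        entries, _ = gen_structure_ensemble(
            EnsembleTruth(seed=2, missing=((1, 3),)), n_per_cluster=3, n_columns=12
        )
        aln_path, coords_dir = write_structure_ensemble(entries, tmp_path)
        loaded = build_coordinate_table(aln_path, coords_dir)
        assert [e.id for e in loaded] == [e.id for e in entries]
        for a, b in zip(loaded, entries):
            np.testing.assert_array_equal(a.missing_mask, b.missing_mask)
            np.testing.assert_allclose(
                a.calpha[~a.missing_mask], b.calpha[~b.missing_mask], atol=1e-5
            )


class TestCuration:
    def test_no_missing_keeps_everything(self):
        entries = entries_from_missing(np.zeros((4, 8), dtype=bool))
        cur = curate_ensemble(entries)
        assert cur.n_structures == 4 and cur.n_columns == 8
        assert cur.deleted_structure_ids == () and cur.deleted_columns == ()

    def test_column_missing_in_two_structures_is_dropped(self):
        missing = np.zeros((5, 8), dtype=bool)
        missing[1, 3] = missing[4, 3] = True
        cur = curate_ensemble(entries_from_missing(missing))
        assert 3 in cur.deleted_columns
        assert cur.n_structures == 5  # no structure deleted
        assert cur.n_columns == 7

    def test_sole_offender_structure_is_dropped_column_kept(self):
        missing = np.zeros((5, 8), dtype=bool)
        missing[3, 6] = True
        cur = curate_ensemble(entries_from_missing(missing))
        assert cur.deleted_structure_ids == ("S3",)
        assert 6 in cur.column_indices
        assert cur.n_columns == 8

    def test_curated_matrix_fully_observed(self, rng):
        missing = rng.random((6, 12)) < 0.15
        try:
            cur = curate_ensemble(entries_from_missing(missing, seed=3))
        except ValueError:
            return
        assert np.all(np.isfinite(cur.matrix))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_struct=st.integers(3, 9),
           n_cols=st.integers(4, 14), rate=st.sampled_from([0.05, 0.15, 0.3]))
    def test_matches_rule_oracle(self, seed, n_struct, n_cols, rate):
        rng = np.random.default_rng(seed)
        missing = rng.random((n_struct, n_cols)) < rate
        # Keep entries valid: no fully-missing structure.
        missing[missing.all(axis=1)] = False
        del_s, del_c = curation_oracle(missing)
        entries = entries_from_missing(missing, seed=seed)
        if n_struct - len(del_s) < 2 or n_cols - len(del_c) == 0:
            with pytest.raises(ValueError):
                curate_ensemble(entries)
            return
        cur = curate_ensemble(entries)
        assert set(cur.deleted_structure_ids) == {f"S{s}" for s in del_s}
        assert set(cur.deleted_columns) == del_c
        assert np.all(np.isfinite(cur.matrix))

    def test_fewer_than_two_structures_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            curate_ensemble(entries_from_missing(np.zeros((1, 5), bool)))


class TestSuperposeEnsemble:
    def make(self, coords_list):
        from aquaprobe.pca import CuratedEnsemble

        n_cols = coords_list[0].shape[0]
        return CuratedEnsemble(
            structure_ids=tuple(f"S{i}" for i in range(len(coords_list))),
            column_indices=tuple(range(n_cols)),
            matrix=np.stack([c.reshape(-1) for c in coords_list]),
        )

    def test_identical_structures_have_zero_rmsd(self, rng):
        base = rng.uniform(0, 10, size=(8, 3))
        aligned = superpose_ensemble(self.make([base, base.copy()]))
        a, b = aligned.reshape(2, 8, 3)
        assert np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))) < 1e-10

    def test_rigid_copies_collapse(self, rng):
        base = rng.uniform(0, 10, size=(8, 3))
        R = Rotation.from_euler("xyz", [0.5, 0.3, -0.8]).as_matrix()
        moved = base @ R.T + np.array([2.0, 3.0, 4.0])
        aligned = superpose_ensemble(self.make([base, moved]))
        a, b = aligned.reshape(2, 8, 3)
        assert np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))) < 1e-8

    @pytest.mark.parametrize("mode", ["reference", "iterative-mean"])
    def test_pairwise_rmsd_matches_oracle(self, mode, rng):
        coords = [rng.uniform(0, 10, size=(10, 3)) for _ in range(4)]
        aligned = superpose_ensemble(self.make(coords), mode=mode).reshape(4, 10, 3)
        # Superposition must not distort internal geometry: each aligned
        # structure still achieves the oracle RMSD to each other one.
        for i in range(4):
            for j in range(i + 1, 4):
                oracle = optimal_rmsd_oracle(coords[i], coords[j])
                achieved = optimal_rmsd_oracle(aligned[i], aligned[j])
                assert achieved == pytest.approx(oracle, abs=1e-8)

    def test_iterative_mean_converges(self, rng):
        coords = [rng.uniform(0, 10, size=(10, 3)) for _ in range(5)]
        aligned = superpose_ensemble(self.make(coords), mode="iterative-mean")
        coords3 = aligned.reshape(5, 10, 3)
        mean = coords3.mean(axis=0)
        # Each structure is already optimally superposed onto the mean.
        from aquaprobe.trajectory import kabsch

        for c in coords3:
            R, t = kabsch(c, mean)
            np.testing.assert_allclose(c @ R.T + t, c, atol=1e-4)

    def test_too_few_columns_rejected(self, rng):
        coords = [rng.uniform(0, 10, size=(2, 3)) for _ in range(3)]
        with pytest.raises(ValueError, match=">= 3"):
            superpose_ensemble(self.make(coords))


class TestEnsemblePCA:
    def test_two_points_give_pc1_along_difference(self):
        a = np.zeros(9)
        b = np.arange(9.0)
        model = fit_pca(np.stack([a, b]))
        direction = (b - a) / np.linalg.norm(b - a)
        cosine = abs(np.dot(model.components_[0], direction))
        assert cosine == pytest.approx(1.0, abs=1e-10)
        assert np.all(model.explained_variance_[1:] < 1e-12)

    def test_trace_conservation(self, rng):
        X = rng.normal(size=(12, 30))
        model = fit_pca(X)
        total = np.sum(np.var(X, axis=0, ddof=1))
        assert model.explained_variance_.sum() == pytest.approx(total, abs=1e-9)
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_orthonormality_and_ordering(self, rng):
        X = rng.normal(size=(15, 24))
        model = fit_pca(X)
        gram = model.components_ @ model.components_.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_) <= 1e-12)
        assert np.all(model.explained_variance_ >= 0)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(10, 12))
        m1, m2 = fit_pca(X.copy()), fit_pca(X.copy())
        np.testing.assert_array_equal(m1.components_, m2.components_)
        for row in m1.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_zero_rejected(self):
        X = np.tile(np.arange(6.0), (4, 1))
        with pytest.raises(ValueError, match="rank-0|identical"):
            fit_pca(X)

    def test_two_cluster_ensemble_separates_on_pc1(self):
        entries, truth = gen_structure_ensemble(
            EnsembleTruth(hinge_magnitude=10.0, noise_sd=0.5, seed=8),
            n_per_cluster=12, n_columns=40,
        )
        cur = curate_ensemble(entries)
        model = fit_pca(superpose_ensemble(cur))
        scores = model.transform(superpose_ensemble(cur))
        labels = np.array([l == "active-like" for l in truth.labels])
        pc1 = scores[:, 0]
        threshold = pc1.mean()
        acc = max(
            np.mean((pc1 > threshold) == labels),
            np.mean((pc1 <= threshold) == labels),
        )
        assert acc >= 0.95

    def test_pc1_dominates_when_hinge_dwarfs_noise(self):
        # Rigid superposition absorbs part of a terminal-segment displacement
        # into the fitted frame, so PC1's variance share crosses 90% only
        # once the hinge dwarfs the per-coordinate noise (here 40x).
        entries, _ = gen_structure_ensemble(
            EnsembleTruth(hinge_magnitude=10.0, noise_sd=0.25, seed=8),
            n_per_cluster=12, n_columns=40,
        )
        cur = curate_ensemble(entries)
        model = fit_pca(superpose_ensemble(cur))
        assert model.explained_variance_ratio_[0] >= 0.9


class TestProjection:
    def fitted(self, rng, n=10, d=18):
        X = rng.normal(size=(n, d))
        return X, fit_pca(X)

    def test_mean_projects_to_origin(self, rng):
        X, model = self.fitted(rng)
        proj = project_conformers(model, X.mean(axis=0), superpose=False)
        np.testing.assert_allclose(proj[0].scores, 0.0, atol=1e-10)

    def test_training_scores_consistent_with_transform(self, rng):
        X, model = self.fitted(rng)
        proj = project_conformers(model, X, superpose=False)
        np.testing.assert_allclose(
            np.stack([p.scores for p in proj]), model.transform(X), atol=1e-12
        )

    def test_reconstruction_residual_non_increasing_in_k(self, rng):
        X, model = self.fitted(rng, n=12, d=15)
        x = X[3]
        scores = model.transform(x[None, :])[0]
        residuals = []
        for k in range(1, scores.size + 1):
            recon = model.mean_ + scores[:k] @ model.components_[:k]
            residuals.append(np.linalg.norm(x - recon))
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))
        assert residuals[-1] < 1e-8  # full-rank round trip

    def test_column_mismatch_rejected(self, rng):
        _, model = self.fitted(rng)
        with pytest.raises(ValueError, match="mismatch"):
            project_conformers(model, np.zeros((2, 7)))

    def test_superposed_projection_ignores_rigid_motion(self, rng):
        entries, _ = gen_structure_ensemble(
            EnsembleTruth(hinge_magnitude=6.0, noise_sd=0.3, seed=5),
            n_per_cluster=5, n_columns=20,
        )
        cur = curate_ensemble(entries)
        aligned = superpose_ensemble(cur)
        model = fit_pca(aligned)
        conf = aligned[2].reshape(-1, 3)
        R = Rotation.from_euler("zxy", [1.0, 0.2, -0.4]).as_matrix()
        moved = (conf @ R.T + np.array([10.0, -5.0, 2.0])).reshape(-1)
        p_orig = project_conformers(model, aligned[2], superpose=True)[0].scores
        p_moved = project_conformers(model, moved, superpose=True)[0].scores
        np.testing.assert_allclose(p_orig, p_moved, atol=1e-6)


class TestIntervalList:
    def test_small_example(self):
        assert expand_interval_list("1-3, 5") == [1, 2, 3, 5]

    def test_empty_string(self):
        assert expand_interval_list("") == []

    def test_en_dash_ranges(self):
        assert expand_interval_list("48–50") == [48, 49, 50]

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError, match="reversed"):
            expand_interval_list("20-10")

    def test_non_numeric_token_rejected(self):
        with pytest.raises(ValueError, match="non-numeric"):
            expand_interval_list("1, two, 3")

    def test_overlapping_ranges_deduplicated(self):
        assert expand_interval_list("1-5, 3-7") == [1, 2, 3, 4, 5, 6, 7]


class TestCountRetained:
    def test_subtracts_unique_ids(self):
        assert count_retained(10, ("A", "B", "B")) == 8

    def test_over_deletion_rejected(self):
        with pytest.raises(ValueError):
            count_retained(2, ("A", "B", "C"))
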