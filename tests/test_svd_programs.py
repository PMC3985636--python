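"""SVD program extraction: spectra, scores, orientation, profile tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles

from marasvd import svd_programs as sp
from marasvd import synthetic_data as sd
from marasvd.data_io import SampleDesign
from marasvd.mara_core import ActivityTable


def _table(A):
    A = np.asarray(A, float)
    M, S = A.shape
    return ActivityTable([f"m{i}" for i in range(M)],
                         [f"s{j}" for j in range(S)], A, np.ones((M, S)))


def _centered_random(M, S, seed):
    A = np.random.default_rng(seed).normal(size=(M, S))
    return A - A.mean(axis=1, keepdims=True)


class TestDecompose:
    def test_rank_one_matrix(self):
        a = np.array([1.0, 2.0, -1.0])
        b = np.array([0.5, -0.5, 1.5, -1.5])
        d = sp.decompose_activities(_table(np.outer(a, b)))
        assert d.variance_fraction[0] == pytest.approx(1.0)
        assert d.n_components == 1    # below-tolerance components dropped

    def test_diagonal_closed_form(self):
        d = sp.decompose_activities(_table(np.diag([4.0, 3.0])))
        np.testing.assert_allclose(d.singular_values, [4.0, 3.0])
        np.testing.assert_allclose(d.variance_fraction, [0.64, 0.36])

    def test_reconstruction_and_orthonormality(self):
        A = _centered_random(50, 14, 0)
        d = sp.decompose_activities(_table(A))
        assert (np.linalg.norm(A - d.reconstruct())
                / np.linalg.norm(A)) <= 1e-10
        gram = d.V.T @ d.V
        np.testing.assert_allclose(gram, np.eye(d.n_components), atol=1e-10)
        # singular values non-increasing; fractions sum to 1
        assert np.all(np.diff(d.singular_values) <= 1e-12)
        assert abs(d.variance_fraction.sum() - 1.0) <= 1e-10
        # row-centered A makes every right singular vector mean-centered
        assert np.all(np.abs(d.V.mean(axis=0)) <= 1e-9)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sp.decompose_activities(_table(np.zeros((3, 4))))


class TestVarianceExplained:
    def test_full_rank_is_one(self):
        d = sp.decompose_activities(_table(_centered_random(10, 6, 1)))
        assert sp.variance_explained(d, d.n_components) == pytest.approx(1.0)

    def test_diagonal_first_component(self):
        d = sp.decompose_activities(_table(np.diag([4.0, 3.0])))
        assert sp.variance_explained(d, 1) == pytest.approx(0.64)

    def test_monotone_in_k(self):
        d = sp.decompose_activities(_table(_centered_random(20, 8, 2)))
        vals = [sp.variance_explained(d, k) for k in range(1, d.n_components + 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range(self):
        d = sp.decompose_activities(_table(np.diag([4.0, 3.0])))
        with pytest.raises(ValueError):
            sp.variance_explained(d, 0)
        with pytest.raises(ValueError):
            sp.variance_explained(d, 99)


class TestComponentScores:
    def test_profile_equal_to_scaled_singular_vector(self):
        A0 = _centered_random(6, 8, 3)
        d0 = sp.decompose_activities(_table(A0))
        v1 = d0.V[:, 0]
        A = np.vstack([A0, 5.0 * v1])      # extra motif = 5 x first program
        scores = sp.component_scores(sp.decompose_activities(_table(A)))
        # sign of v1 may flip in the new decomposition
        assert abs(scores.projections[-1, 0]) == pytest.approx(5.0, abs=1e-8)
        assert abs(scores.correlations[-1, 0]) == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.abs(scores.correlations[-1, 1:]) < 1e-8)

    def test_rho_identity_vs_direct_pearson(self):
        """The SVD-derived correlation equals the direct Pearson correlation
        between each (mean-centered) motif profile and each singular vector."""
        A = _centered_random(30, 10, 4)
        d = sp.decompose_activities(_table(A))
        scores = sp.component_scores(d)
        for i in range(30):
            for k in range(d.n_components):
                direct = np.corrcoef(A[i], d.V[:, k])[0, 1]
                assert scores.correlations[i, k] == pytest.approx(
                    direct, abs=1e-10)

    def test_rho_identity_breaks_without_row_centering(self):
        """Negative control: uncentered rows break the identity."""
        A = np.random.default_rng(5).normal(size=(15, 8)) + 3.0
        d = sp.decompose_activities(_table(A))
        scores = sp.component_scores(d)
        direct = np.array([[np.corrcoef(A[i], d.V[:, k])[0, 1]
                            for k in range(d.n_components)]
                           for i in range(15)])
        assert np.max(np.abs(direct - scores.correlations)) > 1e-3

    def test_quiet_motif_high_correlation_low_projection(self):
        """A motif with a tiny but shape-perfect profile correlates at 1
        while projecting weakly."""
        A0 = _centered_random(6, 8, 6)
        d0 = sp.decompose_activities(_table(A0))
        A = np.vstack([A0, 1e-3 * d0.V[:, 0]])
        scores = sp.component_scores(sp.decompose_activities(_table(A)))
        assert abs(scores.correlations[-1, 0]) > 0.999
        assert abs(scores.projections[-1, 0]) < 0.01


class TestOrientation:
    def test_idempotent(self):
        d = sp.decompose_activities(_table(_centered_random(12, 6, 7)))
        once = sp.orient_components(d)
        twice = sp.orient_components(once)
        np.testing.assert_array_equal(once.V, twice.V)
        np.testing.assert_array_equal(once.U, twice.U)

    def test_invariant_to_input_sign_flips(self):
        d = sp.decompose_activities(_table(_centered_random(12, 6, 8)))
        flipped = sp.ProgramDecomposition(
            d.motif_ids, d.sample_ids, -d.U, d.singular_values, -d.V,
            d.variance_fraction)
        np.testing.assert_allclose(sp.orient_components(d).V,
                                   sp.orient_components(flipped).V, atol=1e-12)

    def test_reconstruction_unchanged(self):
        d = sp.decompose_activities(_table(_centered_random(12, 6, 9)))
        oriented = sp.orient_components(d)
        np.testing.assert_allclose(d.reconstruct(), oriented.reconstruct(),
                                   atol=1e-12)

    def test_treatment_positive(self, default_study):
        st_ = default_study
        A = st_.truth.activities
        table = ActivityTable(st_.counts.motif_ids, st_.design.sample_ids,
                              A, np.ones_like(A))
        d = sp.orient_components(sp.decompose_activities(table),
                                 st_.design, "treatment_positive")
        cond = dict(zip(st_.design.table["sample_id"],
                        st_.design.table["condition"]))
        treated = [i for i, s in enumerate(d.sample_ids)
                   if cond[s] == "treated"]
        control = [i for i, s in enumerate(d.sample_ids)
                   if cond[s] == "control"]
        for k in range(d.n_components):
            assert d.V[treated, k].mean() >= d.V[control, k].mean() - 1e-12

    def test_treatment_positive_needs_labels(self):
        d = sp.decompose_activities(_table(_centered_random(5, 4, 10)))
        design = SampleDesign(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(4)], "dataset": ["d"] * 4,
            "condition": ["x"] * 4}))
        with pytest.raises(ValueError, match="treatment_positive"):
            sp.orient_components(d, design, "treatment_positive")


class TestProfileTable:
    def test_kinetic_table_matches_V(self, kinetic_design, tmp_path):
        A = _centered_random(10, 14, 11)
        table = ActivityTable([f"m{i}" for i in range(10)],
                              kinetic_design.sample_ids, A, np.ones_like(A))
        d = sp.decompose_activities(table)
        long = sp.component_profile_table(d, kinetic_design)
        assert len(long) == d.n_components * 14
        assert set(long["condition"]) == {"treated", "control"}
        for _, row in long.head(30).iterrows():
            i = d.sample_ids.index(row["sample_id"])
            assert row["v"] == d.V[i, int(row["component"]) - 1]
        # TSV round-trip
        p = tmp_path / "profiles.tsv"
        long.to_csv(p, sep="\t", index=False, float_format="%.17g")
        back = pd.read_csv(p, sep="\t")
        np.testing.assert_allclose(back["v"], long["v"], rtol=1e-12)

    def test_missing_time_error(self):
        design = SampleDesign(pd.DataFrame({
            "sample_id": ["a", "b"], "dataset": ["d"] * 2,
            "condition": ["x", "y"]}))
        A = _centered_random(4, 2, 12)
        d = sp.decompose_activities(
            ActivityTable([f"m{i}" for i in range(4)], ["a", "b"], A,
                          np.ones_like(A)))
        with pytest.raises(ValueError, match="time"):
            sp.component_profile_table(d, design)


def test_planted_program_subspace_recovery():
    """Four planted temporal programs with singular-value gaps and activity
    noise at SD 0.05 are recovered to < 5 degrees of principal angle."""
    config = sd.GeneratorConfig(seed=7, n_motifs=40,
                                program_scales=(8.0, 6.0, 4.0, 2.0),
                                activity_noise_sd=0.05,
                                noise_sd=0.0, noise_mode="absolute")
    study = sd.generate_study(config)
    A = study.truth.activities
    table = ActivityTable(study.counts.motif_ids, study.design.sample_ids,
                          A, np.ones_like(A))
    d = sp.decompose_activities(table)
    angles = np.degrees(subspace_angles(d.V[:, :4], study.truth.basis.T))
    assert np.all(angles < 5.0)
    assert np.all(np.diff(d.variance_fraction) <= 1e-12)
    assert abs(d.variance_fraction.sum() - 1.0) <= 1e-10
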