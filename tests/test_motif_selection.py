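"""Ranking, refinement filters and representative-motif selection."""

import numpy as np
import pandas as pd
import pytest

from marasvd import contrasts as ct
from marasvd import mara_core, motif_selection as ms
from marasvd import svd_programs as sp
from marasvd import synthetic_data as sd
from marasvd.data_io import MotifTFMap
from marasvd.mara_core import ActivityTable
from marasvd.svd_programs import ComponentScores


def _scores(P, rho=None):
    P = np.asarray(P, float)
    if rho is None:
        norms = np.sqrt((P ** 2).sum(axis=1, keepdims=True))
        rho = np.where(norms > 0, P / norms, 0.0)
    return ComponentScores([f"m{i}" for i in range(P.shape[0])], P,
                           np.asarray(rho, float))


class TestRankByComponent:
    def test_top_by_both_is_candidate(self):
        P = np.array([[5.0, 0.1], [1.0, 0.2], [-4.0, 0.0], [0.5, 3.0]])
        pos, neg = ms.rank_by_component(_scores(P), component=1, top_n=2)
        assert "m0" in pos
        assert "m2" in neg

    def test_projection_without_correlation_excluded(self):
        """A large-activity motif projecting strongly onto a profile it does
        not resemble must not be selected: both ranks are required."""
        # m0: huge projection, mediocre correlation; m1-m3 modest P, high rho
        P = np.array([[10.0], [2.0], [1.8], [1.6]])
        rho = np.array([[0.3], [0.95], [0.9], [0.85]])
        pos, _ = ms.rank_by_component(_scores(P, rho), component=1, top_n=2)
        assert "m0" not in pos        # top-2 by P but rank 4 by rho
        assert "m1" in pos

    def test_candidates_match_direct_pearson_ranks(self, fitted_default):
        """Ranking from SVD scores equals ranking from directly recomputed
        Pearson correlations with the singular vectors."""
        _, table = fitted_default
        d = sp.decompose_activities(table)
        scores = sp.component_scores(d)
        pos, neg = ms.rank_by_component(scores, 1, top_n=8)
        A = table.activities
        direct_rho = np.array([np.corrcoef(A[i], d.V[:, 0])[0, 1]
                               for i in range(A.shape[0])])
        direct = ComponentScores(scores.motif_ids, scores.projections,
                                 np.column_stack([direct_rho]
                                                 + [scores.correlations[:, k]
                                                    for k in range(1, d.n_components)]))
        pos2, neg2 = ms.rank_by_component(direct, 1, top_n=8)
        assert pos == pos2 and neg == neg2


class TestSignificanceFilter:
    def test_zero_threshold_identity(self):
        cands = ["a", "b"]
        assert ms.apply_significance_filter(cands, {"a": 0.1, "b": 5}, 0.0) == cands

    def test_boundary_removal_logged(self):
        audit = []
        kept = ms.apply_significance_filter(["a", "b"], {"a": 2.99, "b": 3.0},
                                            3.0, audit, "+")
        assert kept == ["b"]
        assert audit[0]["motif_id"] == "a"
        assert audit[0]["stage"] == "significance"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        z = {f"m{i}": float(rng.uniform(0, 5)) for i in range(30)}
        cands = list(z)
        previous = set(cands)
        for thr in (0.5, 1.5, 2.5, 3.5, 4.5):
            kept = set(ms.apply_significance_filter(cands, z, thr))
            assert kept <= previous
            previous = kept


class TestExpressionFilter:
    def _map(self, profiles):
        samples = [f"s{j}" for j in range(4)]
        expr = pd.DataFrame({tf: np.full(4, level)
                             for tf, level in profiles.items()}).T
        expr.columns = samples
        mapping = {}
        for tf in profiles:
            mapping.setdefault(tf.split("_")[0], []).append(tf)
        return MotifTFMap(mapping, expr)

    def test_below_threshold_removed(self):
        tf_map = self._map({"mA_tf1": 5.9})
        assert ms.apply_expression_filter(["mA"], tf_map, 6.0) == []

    def test_above_threshold_kept(self):
        tf_map = self._map({"mA_tf1": 6.1})
        assert ms.apply_expression_filter(["mA"], tf_map, 6.0) == ["mA"]

    def test_any_tf_rule(self):
        """One expressed family member suffices to keep the motif."""
        tf_map = self._map({"mA_tf1": 3.0, "mA_tf2": 7.0})
        assert ms.apply_expression_filter(["mA"], tf_map, 6.0) == ["mA"]

    def test_unmapped_motif_kept_with_note(self):
        audit = []
        kept = ms.apply_expression_filter(["zz"], self._map({"mA_tf1": 7.0}),
                                          6.0, audit, "+")
        assert kept == ["zz"]
        assert audit[0]["stage"] == "expression_unmapped"


class TestTimepointFilter:
    TIMES = [1.0, 3.0, 7.0, 14.0, 28.0, 57.0, 91.0]

    def _cz(self, zrow):
        return pd.DataFrame([zrow], index=["mA"], columns=self.TIMES)

    def test_sustained_four_of_seven_kept(self):
        cz = self._cz([2.5, -2.5, 2.5, 2.5, 0.0, 0.0, 0.0])
        config = ms.SelectionConfig(timepoint_rule="sustained",
                                    timepoint_z_threshold=2.0,
                                    min_timepoints_hit=4)
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config) == ["mA"]

    def test_sustained_three_of_seven_removed(self):
        cz = self._cz([2.5, 2.5, 2.5, 0.0, 0.0, 0.0, 0.0])
        config = ms.SelectionConfig(timepoint_rule="sustained",
                                    min_timepoints_hit=4)
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config) == []

    def test_day_first_needs_first_timepoint(self):
        cz = self._cz([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 5.0])
        config = ms.SelectionConfig(timepoint_rule="day_first")
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config) == []

    def test_day_last(self):
        cz = self._cz([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 5.0])
        config = ms.SelectionConfig(timepoint_rule="day_last")
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config) == ["mA"]

    def test_all_zero_removed_under_every_rule(self):
        cz = self._cz([0.0] * 7)
        for rule in ("sustained", "day_first", "day_last"):
            config = ms.SelectionConfig(timepoint_rule=rule)
            assert ms.apply_timepoint_pattern_filter(["mA"], cz, config) == []

    def test_direction_sign_respected(self):
        cz = self._cz([-3.0] * 7)
        config = ms.SelectionConfig(timepoint_rule="sustained",
                                    direction_sign=True)
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config,
                                                 direction="+") == []
        assert ms.apply_timepoint_pattern_filter(["mA"], cz, config,
                                                 direction="-") == ["mA"]


@pytest.fixture(scope="module")
def benchmark():
    config = sd.selection_benchmark_config(seed=1)
    study = sd.generate_study(config)
    table = mara_core.fit_activities(
        study.expression, study.counts,
        mara_core.FitConfig(ridge_penalty=1e-3, seed=1))
    decomp = sp.orient_components(sp.decompose_activities(table))
    scores = sp.component_scores(decomp)
    cz = ct.timepoint_contrast_table(table, study.design, "kinetic",
                                     "treated", "control")
    return study, table, scores, cz


class TestSelectRepresentatives:
    def test_planted_truth_recovered_exactly(self, benchmark):
        """3 sustained-program motifs with expressed TFs are selected; the
        2 unexpressed-TF loaders and 18 noise decoys are filtered out."""
        study, table, scores, cz = benchmark
        config = ms.SelectionConfig(component=1, top_n=10, min_motif_z=3.0,
                                    timepoint_rule="sustained",
                                    timepoint_z_threshold=2.0,
                                    min_timepoints_hit=4)
        sel = ms.select_representatives(
            scores, dict(zip(table.motif_ids, table.motif_z)),
            study.tf_map, cz, config)
        selected = set(sel.positive_cluster) | set(sel.negative_cluster)
        assert selected == {"motif_000", "motif_001", "motif_002"}

    def test_audit_attributes_each_removal(self, benchmark):
        study, table, scores, cz = benchmark
        config = ms.SelectionConfig(component=1, top_n=10, min_motif_z=3.0,
                                    timepoint_rule="sustained")
        sel = ms.select_representatives(
            scores, dict(zip(table.motif_ids, table.motif_z)),
            study.tf_map, cz, config)
        assert sel.removal_stage("motif_003") == "expression"
        assert sel.removal_stage("motif_004") == "expression"
        removed = sel.removals()
        noise = removed[~removed["motif_id"].isin(
            ["motif_003", "motif_004"])]
        assert (noise["stage"] == "significance").all()

    def test_disabling_filters_equals_ranking(self, benchmark):
        study, table, scores, _ = benchmark
        config = ms.SelectionConfig(component=1, top_n=10, min_motif_z=0.0,
                                    min_tf_log_expression=-np.inf,
                                    timepoint_rule="none")
        sel = ms.select_representatives(
            scores, dict(zip(table.motif_ids, table.motif_z)),
            study.tf_map, None, config)
        pos, neg = ms.rank_by_component(scores, 1, 10)
        assert sel.positive_cluster == pos
        assert sel.negative_cluster == neg

    def test_audit_length_counts_removals(self, benchmark):
        study, table, scores, cz = benchmark
        config = ms.SelectionConfig(component=1, top_n=10, min_motif_z=3.0,
                                    timepoint_rule="sustained")
        sel = ms.select_representatives(
            scores, dict(zip(table.motif_ids, table.motif_z)),
            study.tf_map, cz, config)
        pos, neg = ms.rank_by_component(scores, 1, 10)
        n_removed = (len(pos) + len(neg)
                     - len(sel.positive_cluster) - len(sel.negative_cluster))
        real_removals = [a for a in sel.audit
                         if a["stage"] != "expression_unmapped"]
        assert len(real_removals) == n_removed

    def test_deterministic(self, benchmark):
        study, table, scores, cz = benchmark
        config = ms.SelectionConfig(component=1, top_n=10, min_motif_z=3.0,
                                    timepoint_rule="sustained")
        args = (scores, dict(zip(table.motif_ids, table.motif_z)),
                study.tf_map, cz, config)
        s1 = ms.select_representatives(*args)
        s2 = ms.select_representatives(*args)
        assert s1.positive_cluster == s2.positive_cluster
        assert s1.negative_cluster == s2.negative_cluster
        assert s1.audit == s2.audit


class TestTFActivityCorrelation:
    def _setup(self, tf_profile, activity):
        samples = [f"s{j}" for j in range(len(activity))]
        table = ActivityTable(["mA"], samples,
                              np.array([activity], float),
                              np.ones((1, len(activity))))
        expr = pd.DataFrame([tf_profile], index=["tfX"], columns=samples)
        return table, MotifTFMap({"mA": ["tfX"]}, expr)

    def test_identical_profile_r_one(self):
        a = [1.0, -2.0, 0.5, 0.5]
        table, tf_map = self._setup(a, a)
        r = ms.tf_expression_activity_correlation(table, tf_map, "mA")
        assert r["tfX"] == pytest.approx(1.0)

    def test_constant_expression_undefined(self):
        table, tf_map = self._setup([3.0] * 4, [1.0, -2.0, 0.5, 0.5])
        r = ms.tf_expression_activity_correlation(table, tf_map, "mA")
        assert r["tfX"] is None

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=6)
        x = rng.normal(size=6)
        table, tf_map = self._setup(list(x), list(a))
        r = ms.tf_expression_activity_correlation(table, tf_map, "mA")
        expected = (np.mean((a - a.mean()) * (x - x.mean()))
                    / (a.std() * x.std()))
        assert r["tfX"] == pytest.approx(expected, abs=1e-12)

    def test_sample_mismatch_error(self):
        table, tf_map = self._setup([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        bad = MotifTFMap({"mA": ["tfX"]},
                         tf_map.tf_expression.rename(columns={"s0": "other"}))
        with pytest.raises(ValueError, match="lacks sample"):
            ms.tf_expression_activity_correlation(table, bad, "mA")
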