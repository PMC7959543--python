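"""Normalized front-distance statistics: distances, summaries, densities, tests."""

from itertools import product

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import LineString

from frontfish import (
    CellSummary,
    EdgeAnnotation,
    ValidationError,
    compare_groups,
    density_of_means,
    paired_shift_test,
    spot_edge_distances,
    summarize_cell,
)


def _summaries(values, species="t", prefix="c"):
    return [
        CellSummary(f"{prefix}{i}", species, 10, float(v)) for i, v in enumerate(values)
    ]


class TestSpotEdgeDistances:
    def test_boundary_anchors_and_midpoint(self, parallel_edges):
        pts = np.array([[0.0, 10.0], [10.0, 10.0], [5.0, 10.0]])
        recs = spot_edge_distances(pts, parallel_edges)
        assert [r.d for r in recs] == [0.0, 1.0, 0.5]
        for r in recs:
            assert r.L_um == r.Id_um + r.Nd_um

    def test_matches_dense_sampling_brute_force(self, rng):
        # oracle: nearest distance over 10^4 evenly spaced points per segment
        def brute(point, polyline):
            best = np.inf
            for a, b in zip(polyline[:-1], polyline[1:]):
                ts = np.linspace(0, 1, 10_000)[:, None]
                samples = np.asarray(a) + ts * (np.asarray(b) - np.asarray(a))
                best = min(best, np.hypot(*(samples - point).T).min())
            return best

        for _ in range(50):
            inv = np.cumsum(rng.uniform(-2, 2, (4, 2)), axis=0)
            nuc = np.cumsum(rng.uniform(-2, 2, (4, 2)), axis=0) + [12, 0]
            if not (LineString(inv).is_simple and LineString(nuc).is_simple):
                continue
            edges = EdgeAnnotation(invasive_edge=inv, nuclear_edge=nuc)
            pts = rng.uniform(-5, 15, (5, 2))
            recs = spot_edge_distances(pts, edges, min_length_um=0.0)
            for rec, pt in zip(recs, pts):
                assert rec.Id_um == pytest.approx(brute(pt, inv), abs=1e-6)
                assert rec.Nd_um == pytest.approx(brute(pt, nuc), abs=1e-6)

    def test_scale_invariance_of_d(self, parallel_edges, rng):
        pts = rng.uniform(1, 9, (20, 2))
        base = [r.d for r in spot_edge_distances(pts, parallel_edges)]
        scaled_edges = EdgeAnnotation(
            invasive_edge=parallel_edges.invasive_edge * 3.0,
            nuclear_edge=parallel_edges.nuclear_edge * 3.0,
        )
        scaled = [r.d for r in spot_edge_distances(pts * 3.0, scaled_edges)]
        assert np.allclose(base, scaled)

    def test_edge_swap_maps_d_to_one_minus_d(self, parallel_edges, rng):
        pts = rng.uniform(1, 9, (20, 2))
        base = np.array([r.d for r in spot_edge_distances(pts, parallel_edges)])
        swapped = np.array(
            [r.d for r in spot_edge_distances(pts, parallel_edges.swapped())]
        )
        assert np.allclose(swapped, 1.0 - base)

    def test_spot_on_both_edges_dropped(self):
        touching = EdgeAnnotation(
            invasive_edge=[[0.0, 0.0], [0.0, 10.0]],
            nuclear_edge=[[0.0, 10.0], [10.0, 10.0]],
        )
        recs = spot_edge_distances(np.array([[0.0, 10.0], [5.0, 5.0]]), touching)
        assert len(recs) == 1 and recs[0].spot_id == 1


class TestSummarizeCell:
    def test_extremes_average_to_half(self, parallel_edges):
        recs = spot_edge_distances(
            np.array([[0.0, 10.0], [10.0, 10.0]]), parallel_edges, species="t"
        )
        assert summarize_cell(recs, "c1", "t").mean_d == 0.5

    def test_single_record_identity(self, parallel_edges):
        recs = spot_edge_distances(np.array([[3.0, 10.0]]), parallel_edges, species="t")
        assert summarize_cell(recs, "c1", "t").mean_d == pytest.approx(0.3)

    def test_beta_draws_recover_analytic_mean(self, parallel_edges, rng):
        xs = 10.0 * rng.beta(1, 3, 10_000)
        pts = np.column_stack([xs, np.full_like(xs, 10.0)])
        recs = spot_edge_distances(pts, parallel_edges, species="t")
        assert summarize_cell(recs, "c1", "t").mean_d == pytest.approx(0.25, abs=0.02)

    def test_missing_species_returns_none(self, parallel_edges):
        recs = spot_edge_distances(np.array([[3.0, 10.0]]), parallel_edges, species="t")
        assert summarize_cell(recs, "c1", "other") is None

    def test_normalize_after_averaging_alternative(self, parallel_edges):
        recs = spot_edge_distances(
            np.array([[2.0, 10.0], [4.0, 10.0]]), parallel_edges, species="t"
        )
        alt = summarize_cell(recs, "c1", "t", per_spot_normalization=False)
        assert alt.mean_d == pytest.approx(3.0 / 10.0)


class TestDensityOfMeans:
    def test_integrates_to_one(self, rng):
        est = density_of_means(_summaries(rng.beta(2, 5, 30)))
        assert np.trapezoid(est.density, est.support) == pytest.approx(1.0, abs=1e-6)
        assert (est.density >= 0).all()

    def test_uniform_grid_of_means_gives_flat_density(self):
        est = density_of_means(_summaries(np.linspace(0.001, 0.999, 400)))
        interior = (est.support >= 0.1) & (est.support <= 0.9)
        assert np.all(np.abs(est.density[interior] - 1.0) < 0.1)

    def test_means_near_zero_put_mode_at_the_front(self, rng):
        est = density_of_means(_summaries(rng.uniform(0.0, 0.08, 40)))
        assert est.support[np.argmax(est.density)] <= 0.15

    def test_degenerate_identical_means_fall_back(self):
        est = density_of_means(_summaries([0.4] * 10))
        assert np.trapezoid(est.density, est.support) == pytest.approx(1.0, abs=1e-6)
        assert est.support[np.argmax(est.density)] == pytest.approx(0.4, abs=0.01)

    def test_fewer_than_three_cells_rejected(self):
        with pytest.raises(ValidationError):
            density_of_means(_summaries([0.2, 0.4]))


class TestPairedShiftTest:
    def test_identical_samples_give_p_one(self):
        target = _summaries([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        res = paired_shift_test(target, _summaries([0.2, 0.3, 0.4, 0.5, 0.6, 0.7], "c"))
        assert res.p_value == 1.0
        assert res.median_paired_difference == 0.0

    def test_statistic_and_p_match_sign_enumeration(self):
        diffs = np.array([0.12, -0.05, 0.33, 0.21, -0.4, 0.07, 0.15, -0.22])
        control = np.full(len(diffs), 0.4)
        res = paired_shift_test(_summaries(control + diffs), _summaries(control, "c"))
        ranks = stats.rankdata(np.abs(diffs))
        w_plus = ranks[diffs > 0].sum()
        w_minus = ranks[diffs < 0].sum()
        assert res.statistic == min(w_plus, w_minus)
        null = [
            sum(r for s, r in zip(signs, ranks) if s > 0)
            for signs in product([1, -1], repeat=len(diffs))
        ]
        p_enum = min(1.0, 2.0 * np.mean(np.asarray(null) <= res.statistic))
        assert res.p_value == pytest.approx(p_enum)

    def test_unmatched_ids_listed_in_error(self):
        target = _summaries([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        control = _summaries([0.2, 0.3, 0.4, 0.5, 0.6, 0.7], "c", prefix="x")
        with pytest.raises(ValidationError, match="x0"):
            paired_shift_test(target, control)

    def test_separated_biases_detected(self, rng):
        # 40 cells, front-biased target vs uniform internal control
        target = _summaries(rng.beta(2, 6, 40))
        control = _summaries(rng.beta(4, 4, 40), "c")
        assert paired_shift_test(target, control).p_value < 0.01


class TestCompareGroups:
    def test_two_identical_groups_dunn_p_is_one(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        table = compare_groups({"ref": vals, "x": vals}, "ref", "kruskal_dunn")
        assert table.p_adj.tolist() == [1.0]

    def test_shifted_group_flagged_by_both_methods(self, rng):
        groups = {
            "ref": rng.normal(0.3, 0.1, 30),
            "shifted": rng.normal(0.5, 0.1, 30),
            "same": rng.normal(0.3, 0.1, 30),
        }
        for method in ("anova_dunnett", "kruskal_dunn"):
            table = compare_groups(groups, "ref", method).set_index("condition")
            assert table.loc["shifted", "p_adj"] < 0.01
            assert table.loc["same", "p_adj"] > 0.05

    def test_undersized_condition_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            compare_groups({"ref": [0.1, 0.2], "x": [0.3]}, "ref")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            compare_groups({"a": [0.1, 0.2], "b": [0.3, 0.4]}, "ref")

    def test_dunnett_p_values_are_reproducible(self, rng):
        groups = {"ref": rng.normal(0, 1, 20), "a": rng.normal(0.5, 1, 20)}
        t1 = compare_groups(groups, "ref", "anova_dunnett")
        t2 = compare_groups(groups, "ref", "anova_dunnett")
        assert t1.p_adj.tolist() == t2.p_adj.tolist()
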