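"""Loss and evaluation metrics against brute-force and analytic oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coevodist.errors import DimensionError, UndefinedCorrelationError
from coevodist.metrics import (
    ContactMap,
    DistanceMap,
    EvalSpec,
    contacts_from_distances,
    distance_map_from_pdb,
    evaluate,
    inv_log_cosh_loss,
    lddt,
    mcc,
    mcc_from_counts,
    pearson_r,
    pixel_mae,
    scored_pair_indices,
    topk_mae,
    topk_precision,
)

# ---------------------------------------------------------------------------
# oracles (independent, loop-based)
# ---------------------------------------------------------------------------

def eligible_pairs(L: int, min_sep: int) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i >= max(min_sep, 1)
    ]


def oracle_topk(pred: np.ndarray, L: int, fraction: float, min_sep: int):
    pairs = eligible_pairs(L, min_sep)
    pairs.sort(key=lambda p: (pred[p], p[0], p[1]))
    K = min(math.ceil(fraction * L), len(pairs))
    return pairs[:K]


def oracle_precision(pred, truth, L, fraction, min_sep, thr=8.0):
    sel = oracle_topk(pred, L, fraction, min_sep)
    return sum(truth[p] < thr for p in sel) / len(sel)


def oracle_mae(pred, truth, L, fraction, min_sep):
    sel = oracle_topk(pred, L, fraction, min_sep)
    return sum(abs(pred[p] - truth[p]) for p in sel) / len(sel)


def oracle_pearson(pred, truth, L, min_sep):
    pairs = eligible_pairs(L, min_sep)
    xs = [pred[p] for p in pairs]
    ys = [truth[p] for p in pairs]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def oracle_lddt(pred, truth, L, min_sep, tols=(0.5, 1, 2, 4)):
    pairs = eligible_pairs(L, min_sep)
    total = 0.0
    for t in tols:
        total += sum(abs(pred[p] - truth[p]) < t for p in pairs) / len(pairs)
    return total / len(tols)


def oracle_mcc(pred, truth, L, min_sep, thr=8.0):
    tp = tn = fp = fn = 0
    for p in eligible_pairs(L, min_sep):
        pc, tc = pred[p] < thr, truth[p] < thr
        tp += pc and tc
        tn += (not pc) and (not tc)
        fp += pc and not tc
        fn += (not pc) and tc
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else (tp * tn - fp * fn) / den


def random_instance(rng, L):
    pred = rng.uniform(1.0, 20.0, size=(L, L))
    pred = (pred + pred.T) / 2
    truth = rng.uniform(0.5, 20.0, size=(L, L))
    truth = (truth + truth.T) / 2
    np.fill_diagonal(truth, 0.0)
    return DistanceMap(pred, "predicted"), DistanceMap(truth, "ground_truth")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

class TestLoss:
    def test_zero_for_identical_maps(self, rng):
        v = rng.uniform(1, 20, size=(6, 6))
        assert inv_log_cosh_loss(v, v) == 0.0

    def test_single_pair_spot_value(self):
        # u = 100/5 - 100/10 = 10 in the eps -> 0 limit
        import mpmath

        mpmath.mp.dps = 50
        expected = float(mpmath.log(mpmath.cosh(10)))
        got = inv_log_cosh_loss(np.array([[5.0]]), np.array([[10.0]]), eps=1e-12)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_symmetric_in_arguments(self, rng):
        a = rng.uniform(1, 20, size=(5, 5))
        b = rng.uniform(1, 20, size=(5, 5))
        assert inv_log_cosh_loss(a, b) == pytest.approx(inv_log_cosh_loss(b, a))

    def test_finite_for_extreme_distances(self):
        a = np.full((4, 4), 1e-6)
        b = np.full((4, 4), 1e3)
        val = inv_log_cosh_loss(a, b, eps=1e-8)
        assert np.isfinite(val) and val > 0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            inv_log_cosh_loss(np.ones((3, 3)), np.ones((4, 4)))

    def test_gradient_bounded_by_inverse_square(self):
        """|dL/dpred| <= 100/(pred+eps)^2 (the tanh envelope), numerically."""
        eps = 1e-8
        truth = 10.0
        for pred in [0.5, 2.0, 5.0, 9.9, 10.1, 50.0]:
            h = 1e-6
            lp = inv_log_cosh_loss(np.array([[pred + h]]), np.array([[truth]]), eps)
            lm = inv_log_cosh_loss(np.array([[pred - h]]), np.array([[truth]]), eps)
            grad = (lp - lm) / (2 * h)
            assert abs(grad) <= 100.0 / (pred + eps) ** 2 + 1e-6


# ---------------------------------------------------------------------------
# contacts and ranking metrics
# ---------------------------------------------------------------------------

class TestContacts:
    def test_no_contacts_at_20A(self):
        dm = DistanceMap(np.full((5, 5), 20.0) - 20 * np.eye(5), "ground_truth")
        assert not contacts_from_distances(dm).values.any()

    def test_boundary_is_strict(self):
        v = np.full((3, 3), 8.0)
        np.fill_diagonal(v, 0.0)
        cm = contacts_from_distances(DistanceMap(v, "ground_truth"))
        assert not cm.values.any()

    def test_matches_elementwise_oracle(self, rng):
        v = rng.uniform(4, 12, size=(6, 6))
        np.fill_diagonal(v, 0.0)
        cm = contacts_from_distances(DistanceMap(v, "ground_truth"))
        for i in range(6):
            for j in range(6):
                expected = (v[i, j] < 8.0) and i != j
                assert cm.values[i, j] == expected


class TestRankingMetrics:
    def test_perfect_prediction_full_scores(self, small_protein):
        truth = small_protein.truth
        pred = DistanceMap(np.maximum(truth.values, 1e-3), "predicted")
        spec = EvalSpec()
        assert topk_precision(pred, truth, 0.2, spec) == 1.0
        assert topk_mae(pred, truth, 0.2, spec) == pytest.approx(0.0, abs=1e-3)

    def test_anticorrelated_worst_case(self):
        L = 12
        truth = np.full((L, L), 20.0)
        pred = np.full((L, L), 10.0)
        # the K pairs ranked first by the prediction are all non-contacts
        ii, jj = scored_pair_indices(L, 6)
        truth[ii[:3], jj[:3]] = 4.0       # true contacts exist elsewhere
        pred[ii[:3], jj[:3]] = 1.0
        truth = np.minimum(truth, truth.T)
        pred = np.minimum(pred, pred.T)
        np.fill_diagonal(truth, 0)
        spec = EvalSpec()
        tm = DistanceMap(truth, "ground_truth")
        pm = DistanceMap(pred, "predicted")
        assert topk_precision(pm, tm, 0.2, spec) == 1.0
        # now invert the ranking: contacts ranked last
        pred2 = 30.0 - pred
        assert topk_precision(DistanceMap(pred2, "predicted"), tm, 0.2, spec) == 0.0

    def test_constant_offset_mae(self, small_protein):
        truth = small_protein.truth
        pred = DistanceMap(truth.values + 1.0, "predicted")
        assert topk_mae(pred, truth, 0.5, EvalSpec()) == pytest.approx(1.0)

    def test_precision_invariant_under_monotone_transform(self, rng):
        pred, truth = random_instance(rng, 20)
        spec = EvalSpec()
        cubed = DistanceMap(pred.values**3, "predicted")
        for frac in (0.2, 0.5, 1.0):
            assert topk_precision(pred, truth, frac, spec) == topk_precision(
                cubed, truth, frac, spec
            )

    def test_pearson_endpoints(self, rng):
        pred, truth = random_instance(rng, 10)
        same = DistanceMap(np.maximum(truth.values, 1e-3), "predicted")
        assert pearson_r(same, truth) == pytest.approx(1.0)
        anti = DistanceMap(30.0 - truth.values, "predicted")
        assert pearson_r(anti, truth) == pytest.approx(-1.0)

    def test_pearson_zero_variance_raises(self):
        truth = DistanceMap(np.zeros((10, 10)), "ground_truth")
        pred = DistanceMap(np.ones((10, 10)), "predicted")
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(pred, truth)

    def test_lddt_spot_value_3A_errors(self):
        L = 10
        truth = np.full((L, L), 12.0)
        np.fill_diagonal(truth, 0.0)
        pred = np.full((L, L), 15.0)      # every scored error exactly 3 A
        val = lddt(DistanceMap(pred, "predicted"), DistanceMap(truth, "ground_truth"))
        assert val == pytest.approx(0.25)

    def test_lddt_non_increasing_under_inflation(self, rng):
        pred, truth = random_instance(rng, 15)
        base = lddt(pred, truth)
        worse = DistanceMap(
            truth.values + np.abs(pred.values - truth.values) + 0.75, "predicted"
        )
        assert lddt(worse, truth) <= base

    def test_mcc_confusion_spot_value(self):
        assert mcc_from_counts(3, 5, 1, 1) == pytest.approx(14.0 / 24.0)

    def test_mcc_degenerate_all_positive(self):
        L = 12
        pred = ContactMap(np.ones((L, L), dtype=bool))
        truth_v = np.zeros((L, L), dtype=bool)
        truth_v[0, 7] = truth_v[7, 0] = True
        assert mcc(pred, ContactMap(truth_v)) == 0.0

    def test_mcc_perfect_agreement(self, small_protein):
        tc = contacts_from_distances(small_protein.truth)
        assert mcc(tc, tc) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# oracle sweeps and the combined report
# ---------------------------------------------------------------------------

class TestAgainstOracles:
    @pytest.mark.parametrize("min_sep", [1, 6])
    def test_all_metrics_match_bruteforce(self, rng, min_sep):
        for _ in range(40):
            L = int(rng.integers(8, 13))
            pred, truth = random_instance(rng, L)
            spec = EvalSpec(min_separation=min_sep)
            p, t = pred.values, truth.values
            for frac in (0.2, 0.5, 1.0):
                assert topk_precision(pred, truth, frac, spec) == pytest.approx(
                    oracle_precision(p, t, L, frac, min_sep), abs=1e-9
                )
                assert topk_mae(pred, truth, frac, spec) == pytest.approx(
                    oracle_mae(p, t, L, frac, min_sep), abs=1e-9
                )
            assert pearson_r(pred, truth, spec) == pytest.approx(
                oracle_pearson(p, t, L, min_sep), abs=1e-7
            )
            assert lddt(pred, truth, spec) == pytest.approx(
                oracle_lddt(p, t, L, min_sep), abs=1e-9
            )
            assert mcc(
                contacts_from_distances(pred), contacts_from_distances(truth), min_sep
            ) == pytest.approx(oracle_mcc(p, t, L, min_sep), abs=1e-9)

    def test_mcc_cross_checked_against_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(10):
            pred, truth = random_instance(rng, 12)
            ii, jj = scored_pair_indices(12, 6)
            ours = mcc(contacts_from_distances(pred), contacts_from_distances(truth))
            ref = matthews_corrcoef(
                truth.values[ii, jj] < 8.0, pred.values[ii, jj] < 8.0
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_evaluate_consistent_with_standalone_ops(self, rng):
        pred, truth = random_instance(rng, 16)
        spec = EvalSpec()
        rep = evaluate(pred, truth, spec)
        assert rep.precision["L/5"] == topk_precision(pred, truth, 0.2, spec)
        assert rep.mae["L"] == topk_mae(pred, truth, 1.0, spec)
        assert rep.pearson_r == pearson_r(pred, truth, spec)
        assert rep.lddt == lddt(pred, truth, spec)
        assert rep.n_pairs_scored == scored_pair_indices(16, 6)[0].size

    def test_report_ranges_on_random_instances(self, rng):
        for _ in range(25):
            pred, truth = random_instance(rng, int(rng.integers(10, 16)))
            rep = evaluate(pred, truth, EvalSpec())
            assert all(0 <= v <= 1 for v in rep.precision.values())
            assert all(v >= 0 for v in rep.mae.values())
            assert -1 <= rep.pearson_r <= 1
            assert 0 <= rep.lddt <= 1
            assert -1 <= rep.mcc <= 1
            assert rep.n_pairs_scored > 0

    def test_perfect_prediction_report(self, small_protein):
        truth = small_protein.truth
        pred = DistanceMap(np.maximum(truth.values, 1e-6), "predicted")
        rep = evaluate(pred, truth, EvalSpec())
        assert rep.precision["L/5"] == 1.0
        assert rep.mae["L"] == pytest.approx(0.0, abs=1e-6)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.lddt == 1.0
        assert rep.mcc == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# PDB ground truth
# ---------------------------------------------------------------------------

class TestPDB:
    def test_distance_map_from_minimal_pdb(self, tmp_path, small_protein):
        from coevodist.synthetic import write_minimal_pdb

        path = tmp_path / "model.pdb"
        write_minimal_pdb(path, small_protein.coords, small_protein.sequence)
        dm = distance_map_from_pdb(path)
        assert dm.length == small_protein.length
        # 3-decimal coordinate precision bounds the distance error
        assert np.abs(dm.values - small_protein.truth.values).max() < 2e-3

    def test_glycine_falls_back_to_ca(self, tmp_path):
        from coevodist.synthetic import write_minimal_pdb

        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        path = tmp_path / "g.pdb"
        write_minimal_pdb(path, coords, "AGA")
        assert "CA" in path.read_text()
        dm = distance_map_from_pdb(path)
        assert dm.values[0, 2] == pytest.approx(7.6, abs=1e-3)

    def test_pixel_mae_translation(self, small_protein):
        truth = small_protein.truth
        pred = DistanceMap(truth.values + 0.25, "predicted")
        assert pixel_mae(pred, truth) == pytest.approx(0.25)
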