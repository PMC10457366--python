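import itertools
import warnings

import numpy as np
import pytest

from plmgraph.errors import ShapeError, UndefinedMetricError, ValidationError
from plmgraph.metrics import (
    ComplexPair, RankingTable, auroc, docking_rmsds, first_rank_loss,
    interface_residues, kabsch, pk_from_affinity, rank_correlations, rmse,
)

from conftest import random_rigid_transform


def kendall_tau_bruteforce(x, y):
    """Concordant-minus-discordant pair counting (tau-a; valid for
    tie-free inputs)."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (n * (n - 1) / 2)


def auroc_bruteforce(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def make_table(rng, n_targets=4, max_models=6):
    rows = []
    for t in range(n_targets):
        for m in range(int(rng.integers(2, max_models + 1))):
            rows.append((f"T{t}", f"M{m}",
                         float(rng.normal()), float(rng.uniform())))
    return RankingTable.from_rows(rows)


class TestRankCorrelations:
    def test_perfect_agreement_gives_all_ones(self, rng):
        t = RankingTable.from_rows(
            [("T0", f"M{i}", v, v) for i, v in enumerate([0.1, 0.5, 0.9])]
            + [("T1", f"M{i}", v, v) for i, v in enumerate([0.3, 0.7])]
        )
        out = rank_correlations(t)
        for key, val in out.items():
            assert val == pytest.approx(1.0), key

    def test_anti_correlation(self):
        t = RankingTable.from_rows(
            [("T0", f"M{i}", -v, v) for i, v in enumerate([0.1, 0.5, 0.9])]
        )
        out = rank_correlations(t)
        assert out["global_RS"] == pytest.approx(-1.0)
        assert out["global_KR"] == pytest.approx(-1.0)

    def test_mean_is_per_target_average(self, rng):
        from scipy.stats import spearmanr
        t = make_table(rng)
        out = rank_correlations(t)
        per = [spearmanr(g["pred"], g["true"])[0]
               for _, g in t.df.groupby("target_id")]
        assert out["mean_RS"] == pytest.approx(np.mean(per))

    def test_zero_variance_target_contributes_zero(self):
        t = RankingTable.from_rows(
            [("T0", "M0", 0.5, 0.1), ("T0", "M1", 0.5, 0.9),
             ("T1", "M0", 0.1, 0.2), ("T1", "M1", 0.9, 0.8)]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = rank_correlations(t)
        assert out["mean_RS"] == pytest.approx(0.5)   # (0 + 1) / 2

    def test_single_model_target_excluded_with_warning(self):
        t = RankingTable.from_rows(
            [("T0", "M0", 0.5, 0.5),
             ("T1", "M0", 0.1, 0.2), ("T1", "M1", 0.9, 0.8)]
        )
        with pytest.warns(UserWarning, match="single model"):
            out = rank_correlations(t)
        assert out["mean_RS"] == pytest.approx(1.0)

    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValidationError):
            RankingTable.from_rows(
                [("T0", "M0", 0.5, 0.5), ("T0", "M0", 0.1, 0.2)])


class TestFirstRankLoss:
    def test_zero_when_top_pick_is_best(self):
        t = RankingTable.from_rows(
            [("T0", "M0", 0.9, 0.8), ("T0", "M1", 0.1, 0.2)])
        assert first_rank_loss(t) == 0.0

    def test_forced_arithmetic_example(self):
        t = RankingTable.from_rows(
            [("T0", "M0", 0.1, 0.9), ("T0", "M1", 0.9, 0.5)])
        assert first_rank_loss(t) == pytest.approx(0.4)

    def test_prediction_ties_break_to_smaller_model_id(self):
        t = RankingTable.from_rows(
            [("T0", "M1", 0.5, 0.2), ("T0", "M0", 0.5, 0.9)])
        assert first_rank_loss(t) == 0.0   # M0 chosen on the tie

    def test_matches_direct_definition_on_random_tables(self, rng):
        for _ in range(20):
            t = make_table(rng)
            expected = []
            for _, g in t.df.groupby("target_id"):
                g = g.sort_values(["pred", "model_id"],
                                  ascending=[False, True])
                rows = list(g.itertuples())
                expected.append(max(r.true for r in rows) - rows[0].true)
            assert first_rank_loss(t) == pytest.approx(np.mean(expected))


class TestAuroc:
    def test_separable_scores_give_one(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_complement_under_score_negation(self, rng):
        s = rng.normal(size=10)
        y = rng.integers(0, 2, size=10)
        y[0], y[1] = 0, 1
        assert auroc(y, s) + auroc(y, -s) == pytest.approx(1.0)

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, size=n)
            y[0], y[-1] = 0, 1
            s = rng.choice([0.1, 0.2, 0.3, 0.5], size=n)  # force ties
            assert auroc(y, s) == pytest.approx(auroc_bruteforce(y, s))

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            y[0], y[-1] = 0, 1
            s = rng.normal(size=n).round(1)
            assert auroc(y, s) == pytest.approx(sk.roc_auc_score(y, s))

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])


class TestPk:
    def test_nanomolar_is_nine(self):
        assert pk_from_affinity(1e-9) == 9.0

    def test_molar_is_zero(self):
        assert pk_from_affinity(1.0) == 0.0

    def test_strictly_decreasing(self, rng):
        ks = np.sort(10 ** rng.uniform(-12, 0, size=20))
        pks = [pk_from_affinity(k) for k in ks]
        assert all(a > b for a, b in zip(pks, pks[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            pk_from_affinity(0.0)


class TestKabsch:
    def test_recovers_rigid_transform(self, rng):
        P = rng.normal(size=(10, 3)) * 5
        R, t = random_rigid_transform(rng)
        _, _, r = kabsch(P, P @ R.T + t)
        assert r <= 1e-6

    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(6, 3))
        R, t, r = kabsch(P, P)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_always_proper(self, rng):
        for _ in range(20):
            P = rng.normal(size=(5, 3))
            Q = rng.normal(size=(5, 3))
            R, _, _ = kabsch(P, Q)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_among_random_rigid_transforms(self, rng):
        """Monte-Carlo lower bound: no random rigid placement of P beats
        the closed-form solution."""
        from plmgraph.metrics import rmse_coords
        P = rng.normal(size=(8, 3)) * 3
        Q = rng.normal(size=(8, 3)) * 3
        _, _, best = kabsch(P, Q)
        for _ in range(1000):
            R, t = random_rigid_transform(rng)
            assert best <= rmse_coords(P @ R.T + t, Q) + 1e-12

    def test_collinear_warns_but_solves(self):
        P = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, r = kabsch(P, P)
        assert r == pytest.approx(0.0, abs=1e-9)


class TestInterfaceAndDocking:
    def test_boundary_is_strict(self):
        rec = np.zeros((1, 3))
        ri, li = interface_residues(rec, np.array([[7.9, 0, 0]]))
        assert len(ri) == 1 and len(li) == 1
        ri, li = interface_residues(rec, np.array([[8.0, 0, 0]]))
        assert len(ri) == 0 and len(li) == 0

    def test_matches_bruteforce_all_pairs(self, rng):
        for _ in range(20):
            rec = rng.uniform(-10, 10, size=(rng.integers(2, 16), 3))
            lig = rng.uniform(-10, 10, size=(rng.integers(2, 16), 3))
            ri, li = interface_residues(rec, lig)
            exp_r = {i for i in range(len(rec)) for j in range(len(lig))
                     if np.linalg.norm(rec[i] - lig[j]) < 8.0}
            exp_l = {j for i in range(len(rec)) for j in range(len(lig))
                     if np.linalg.norm(rec[i] - lig[j]) < 8.0}
            assert set(ri) == exp_r and set(li) == exp_l

    def test_perfect_prediction_scores_zero_both_conventions(self, rng):
        rec = rng.normal(size=(6, 3)) * 4
        lig = rec.mean(axis=0) + rng.normal(size=(5, 3)) * 3
        c = ComplexPair(rec, lig, lig.copy())
        for conv in ("fixed_receptor", "kabsch"):
            out = docking_rmsds(c, convention=conv)
            for v in out.values():
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_translated_ligand_closed_form(self, rng):
        rec = rng.normal(size=(6, 3)) * 4
        lig = rec.mean(axis=0) + rng.normal(size=(5, 3)) * 3
        t = np.array([1.2, -0.5, 2.0])
        c = ComplexPair(rec, lig, lig + t)
        fixed = docking_rmsds(c, convention="fixed_receptor")
        assert fixed["ligand_rmsd"] == pytest.approx(np.linalg.norm(t),
                                                     abs=1e-9)
        sup = docking_rmsds(c, convention="kabsch")
        assert sup["ligand_rmsd"] == pytest.approx(0.0, abs=1e-6)

    def test_fixed_receptor_dominates_kabsch(self, rng):
        for _ in range(10):
            rec = rng.normal(size=(8, 3)) * 5
            lig = rec.mean(axis=0) + rng.normal(size=(6, 3)) * 4
            pred = lig + rng.normal(size=lig.shape)
            c = ComplexPair(rec, lig, pred)
            fixed = docking_rmsds(c, convention="fixed_receptor")
            sup = docking_rmsds(c, convention="kabsch")
            for key in fixed:
                assert fixed[key] >= sup[key] - 1e-9

    def test_interface_rmsd_ignores_distant_residues(self, rng):
        rec = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        lig = np.array([[4.0, 0, 0], [104.0, 100, 0]])
        pred = lig.copy()
        base = docking_rmsds(ComplexPair(rec, lig, pred))["interface_rmsd"]
        pred2 = lig.copy()
        pred2[1] += 50.0     # perturb the non-interface ligand residue
        out = docking_rmsds(ComplexPair(rec, lig, pred2))["interface_rmsd"]
        assert out == pytest.approx(base)

    def test_node_count_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ComplexPair(np.zeros((3, 3)), np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmse:
    def test_examples_and_bruteforce(self, rng):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)
        for _ in range(10):
            n = int(rng.integers(1, 11))
            p, y = rng.normal(size=n), rng.normal(size=n)
            assert rmse(p, y) == pytest.approx(
                np.sqrt(sum((a - b) ** 2 for a, b in zip(p, y)) / n))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            rmse([1, 2], [1, 2, 3])
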