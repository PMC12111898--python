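"""SDM engine: PA rule, metrics vs oracles, importance, pruning, ensemble."""

import numpy as np
import pandas as pd
import pytest

from rangeshift.geo_raster import GridSpec, RasterGrid
from rangeshift.occurrences import OccurrenceRecord, OccurrenceSet
from rangeshift.predictors import PredictorStack
from rangeshift.sdm_core import (EvalScores, SdmError, SdmMember,
                                 TrainingTable, auc, best_sss_threshold,
                                 build_ensemble, fit_members, gate_members,
                                 generate_pseudo_absences,
                                 permutation_importance, prune_collinear,
                                 pseudo_absence_count, tss_at_threshold)
from rangeshift.seeding import derive_seed


def flat_stack(n_rows=40, n_cols=50, n_layers=3, seed=0, lat_origin=20.0):
    rng = np.random.default_rng(seed)
    spec = GridSpec(n_rows, n_cols, 0.0, lat_origin, 0.5)
    layers = {f"x{i}": RasterGrid(grid=spec,
                                  values=rng.normal(size=spec.shape),
                                  name=f"x{i}")
              for i in range(n_layers)}
    return PredictorStack(layers=layers,
                          category={n: "climate" for n in layers})


def occ_at_cells(stack, flat_cells, species="sp"):
    g = stack.grid
    rows, cols = np.unravel_index(flat_cells, g.shape)
    records = [OccurrenceRecord(
        species,
        g.lon_origin + (c + 0.5) * g.cell_size,
        g.lat_origin - (r + 0.5) * g.cell_size, 1.0)
        for r, c in zip(rows, cols)]
    return OccurrenceSet(species, records)


class FixedModel:
    """Deterministic stand-in classifier: score = f(X)."""

    classes_ = [0, 1]

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, X):
        s = np.clip(self.fn(np.asarray(X)), 0, 1)
        return np.column_stack([1 - s, s])


def fixed_member(fn, tss=0.9, auc_=0.95):
    return SdmMember("fixed", 1, 1, FixedModel(fn),
                     EvalScores(auc=auc_, tss=tss, sensitivity=1.0,
                                specificity=tss, eval_threshold=0.5))


class TestPseudoAbsences:
    @pytest.mark.parametrize("n_pres,expected", [(500, 1000), (1500, 1500),
                                                 (1000, 1000)])
    def test_pa_count_rule(self, n_pres, expected):
        assert pseudo_absence_count(n_pres) == expected

    def test_table_structure_follows_rule(self):
        stack = flat_stack(n_rows=60, n_cols=60)
        pres = np.arange(500)
        tt = generate_pseudo_absences(occ_at_cells(stack, pres), stack,
                                      n_rounds=3, seed=1)
        for rnd in (1, 2, 3):
            sub = tt.round_subset(rnd)
            assert (sub.response == 0).sum() == 1000
            assert (sub.response == 1).sum() == 500
            # presences never sampled as pseudo-absences
            assert not np.isin(sub.cell_index[sub.response == 0], pres).any()
        # rounds draw independently
        pa1 = tt.round_subset(1).cell_index[tt.round_subset(1).response == 0]
        pa2 = tt.round_subset(2).cell_index[tt.round_subset(2).response == 0]
        assert not np.array_equal(np.sort(pa1), np.sort(pa2))

    def test_too_few_background_cells(self):
        stack = flat_stack(n_rows=10, n_cols=10)
        occ = occ_at_cells(stack, np.arange(95))
        with pytest.raises(SdmError, match="eligible"):
            generate_pseudo_absences(occ, stack, seed=0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_matches_quadratic_concordance_oracle(self, rng):
        for _ in range(30):
            sp = rng.choice(np.round(rng.random(10), 2), size=20)
            sa = rng.choice(np.round(rng.random(10), 2), size=20)
            conc = sum((p > a) + 0.5 * (p == a) for p in sp for a in sa)
            assert auc(sp, sa) == pytest.approx(conc / (20 * 20), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(SdmError):
            auc([], [0.5])


class TestTss:
    def test_constructed_sens_spec(self):
        # 9/10 presences above 0.5, 8/10 absences at or below
        sp = [0.6] * 9 + [0.4]
        sa = [0.4] * 8 + [0.6] * 2
        ev = tss_at_threshold(sp, sa, 0.5)
        assert ev.sensitivity == pytest.approx(0.9)
        assert ev.specificity == pytest.approx(0.8)
        assert ev.tss == pytest.approx(0.7)

    def test_threshold_above_all_scores(self):
        ev = tss_at_threshold([0.3, 0.4], [0.1, 0.2], 0.99)
        assert (ev.sensitivity, ev.specificity, ev.tss) == (0.0, 1.0, 0.0)

    def test_perfect_classifier(self):
        ev = tss_at_threshold([0.9, 0.95], [0.1, 0.05], 0.5)
        assert ev.tss == 1.0


class TestFitMembers:
    def _table(self, rng, n=400, separable=True):
        y = np.repeat([1, 0], n // 2)
        x0 = np.where(y == 1, 1.0, -1.0) + (0.0 if separable else 0.0) * y
        if not separable:
            x0 = rng.normal(size=n)
        X = np.column_stack([x0, rng.normal(size=n)])
        return TrainingTable(
            feature_names=["x0", "x1"], cell_index=np.arange(n), features=X,
            response=y, pa_round=np.ones(n, int), weight=np.ones(n))

    def test_member_count_is_product(self, small_world):
        from rangeshift.pipeline import PipelineConfig, clean_occurrences
        cfg = PipelineConfig(seed=11)
        occ = clean_occurrences(dict(small_world["occ_sets"]), cfg)
        tt = generate_pseudo_absences(next(iter(occ.values())),
                                      small_world["stacks"]["current"],
                                      n_rounds=3, seed=1)
        members = fit_members(tt, n_cv=5, seed=1)
        assert len(members) == 3 * 3 * 5
        combos = {(m.algorithm_id, m.pa_round, m.cv_rep) for m in members}
        assert len(combos) == 45

    def test_separable_table_scores_perfectly(self, rng):
        tt = self._table(rng, separable=True)
        members = fit_members(tt, algorithms=["glm"], n_cv=2, seed=0)
        for m in members:
            assert m.eval.auc == 1.0
            assert m.eval.tss == 1.0

    def test_permuted_labels_give_chance_auc(self, rng):
        n = 2000
        X = rng.normal(size=(n, 2))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        tt = TrainingTable(feature_names=["x0", "x1"],
                           cell_index=np.arange(n), features=X, response=y,
                           pa_round=np.ones(n, int), weight=np.ones(n))
        members = fit_members(tt, algorithms=["glm"], n_cv=5, seed=0)
        mean_auc = np.mean([m.eval.auc for m in members])
        assert abs(mean_auc - 0.5) < 0.05


class TestBestThreshold:
    def test_midpoint_rule_smallest_optimum(self):
        assert best_sss_threshold([0.9, 0.8], [0.1, 0.2]) == pytest.approx(0.5)

    def test_all_identical_scores_degenerate(self):
        t = best_sss_threshold([0.5, 0.5], [0.5, 0.5])
        assert t < 0.5  # below the common score: sens 1, spec 0
        ev = tss_at_threshold([0.5, 0.5], [0.5, 0.5], t)
        assert (ev.sensitivity, ev.specificity) == (1.0, 0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            sp = rng.random(40)
            sa = rng.random(40) * 0.9
            t = best_sss_threshold(sp, sa)
            best = max(
                tss_at_threshold(sp, sa, c).tss
                for c in np.concatenate([[0, 1], sp, sa]))
            assert tss_at_threshold(sp, sa, t).tss >= best - 1e-12


class TestPermutationImportance:
    def _table(self, X):
        n = len(X)
        return TrainingTable(
            feature_names=[f"x{i}" for i in range(X.shape[1])],
            cell_index=np.arange(n), features=X,
            response=np.tile([0, 1], n // 2), pa_round=np.ones(n, int),
            weight=np.ones(n))

    def test_unused_predictor_scores_zero(self, rng):
        X = rng.normal(size=(200, 2))
        member = fixed_member(lambda A: 1 / (1 + np.exp(-A[:, 0])))
        s = permutation_importance(member, self._table(X), seed=1)
        assert s["x1"] == pytest.approx(0.0, abs=1e-12)
        assert s["x0"] > 0.1

    def test_is_bounded_by_two(self, rng):
        X = rng.normal(size=(100, 3))
        member = fixed_member(lambda A: 1 / (1 + np.exp(-A.sum(axis=1))))
        s = permutation_importance(member, self._table(X), n_shuffles=3, seed=2)
        assert np.all((s.values >= 0) | np.isclose(s.values, 0, atol=1e-9))
        assert np.all(s.values <= 2)

    def test_matches_independent_shuffle_loop(self, rng):
        """Linear scorer: IS must equal a hand-rolled loop replaying the
        same seed stream."""
        X = rng.normal(size=(150, 2))
        fn = lambda A: 1 / (1 + np.exp(-(2 * A[:, 0] + 0.3 * A[:, 1])))
        member = fixed_member(fn)
        table = self._table(X)
        got = permutation_importance(member, table, n_shuffles=2, seed=9)
        base = fn(X)
        for j, name in enumerate(table.feature_names):
            vals = []
            for k in range(2):
                r = np.random.default_rng(derive_seed(9, "shuffle", name, k))
                Xs = X.copy()
                Xs[:, j] = r.permutation(Xs[:, j])
                vals.append(1 - np.corrcoef(base, fn(Xs))[0, 1])
            assert got[name] == pytest.approx(np.mean(vals), abs=1e-12)
        assert got["x0"] > got["x1"]


class TestPruneCollinear:
    def _table(self, cols: dict):
        names = list(cols)
        X = np.column_stack([cols[n] for n in names])
        n = len(X)
        return TrainingTable(feature_names=names, cell_index=np.arange(n),
                             features=X, response=np.tile([0, 1], n // 2),
                             pa_round=np.ones(n, int), weight=np.ones(n))

    def _imp(self, scores: dict):
        df = pd.DataFrame({"is_score": pd.Series(scores)})
        df["rank"] = df["is_score"].rank(ascending=False).astype(int)
        return df

    def test_identical_columns_lower_is_dropped(self, rng):
        x = rng.normal(size=100)
        tt = self._table({"a": x, "b": x.copy()})
        out = prune_collinear(tt, self._imp({"a": 0.3, "b": 0.1}))
        assert out == ["a"]

    def test_uncorrelated_all_retained(self, rng):
        tt = self._table({f"c{i}": rng.normal(size=400) for i in range(5)})
        out = prune_collinear(tt, self._imp({f"c{i}": 0.1 * i
                                             for i in range(5)}))
        assert len(out) == 5

    def test_constant_column_dropped(self, rng):
        tt = self._table({"a": rng.normal(size=50), "k": np.ones(50)})
        assert prune_collinear(tt, self._imp({"a": 0.2, "k": 0.9})) == ["a"]

    def test_matches_greedy_oracle_on_constructed_case(self, rng):
        base = rng.normal(size=600)
        cols = {
            "a": base,
            "b": base + 0.1 * rng.normal(size=600),   # |r|~0.99 with a
            "c": base + 0.8 * rng.normal(size=600),   # |r|~0.78 with a
            "d": rng.normal(size=600),
            "e": -base + 0.05 * rng.normal(size=600),  # strong negative r
        }
        imp = {"a": 0.5, "b": 0.4, "c": 0.45, "d": 0.1, "e": 0.48}
        tt = self._table(cols)
        got = set(prune_collinear(tt, self._imp(imp)))

        # exhaustive greedy oracle on the spearman/pearson matrix
        from rangeshift.sdm_core import _pair_correlation
        names = list(cols)
        r = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r[(a, b)] = abs(_pair_correlation(cols[a], cols[b]))
        kept = set(names)
        while True:
            worst = sorted(((v, p) for p, v in r.items()
                            if v > 0.7 and p[0] in kept and p[1] in kept),
                           key=lambda t: (-t[0], t[1]))
            if not worst:
                break
            a, b = worst[0][1]
            kept.discard(a if imp[a] <= imp[b] else b)
        assert got == kept
        for i, a in enumerate(sorted(got)):
            for b in sorted(got)[i + 1:]:
                key = (a, b) if (a, b) in r else (b, a)
                assert r[key] <= 0.7


class TestEnsemble:
    def test_gate_rule_and_monotonicity(self):
        evs = [(0.65, 0.7), (0.5, 0.85), (0.5, 0.7), (0.61, 0.79)]
        members = [fixed_member(lambda A: A[:, 0], tss=t, auc_=a)
                   for t, a in evs]
        passing = gate_members(members)
        assert [(m.eval.tss, m.eval.auc) for m in passing] == [
            (0.65, 0.7), (0.5, 0.85), (0.61, 0.79)]
        stricter = gate_members(members, gate_tss=0.8, gate_auc=0.9)
        assert set(id(m) for m in stricter) <= set(id(m) for m in passing)

    def test_single_passing_member_is_identity(self):
        stack = flat_stack(n_rows=6, n_cols=6, n_layers=1, seed=2)
        fn = lambda A: 1 / (1 + np.exp(-A[:, 0]))
        members = [fixed_member(fn, tss=0.9),
                   fixed_member(fn, tss=0.3, auc_=0.5)]  # fails gate
        res = build_ensemble(members, stack, species="s")
        X = stack.feature_matrix(stack.land_indices())
        np.testing.assert_allclose(
            res.hsi.values.ravel()[stack.land_indices()], fn(X))

    def test_equal_tss_gives_unweighted_mean(self):
        stack = flat_stack(n_rows=5, n_cols=5, n_layers=1, seed=3)
        f1 = lambda A: np.full(len(A), 0.2)
        f2 = lambda A: np.full(len(A), 0.6)
        res = build_ensemble([fixed_member(f1, tss=0.8),
                              fixed_member(f2, tss=0.8)], stack)
        np.testing.assert_allclose(res.hsi.unmasked_values(), 0.4)

    def test_hand_computed_tss_weights(self):
        stack = flat_stack(n_rows=4, n_cols=4, n_layers=1, seed=4)
        p1, p3 = 0.9, 0.1
        members = [
            fixed_member(lambda A: np.full(len(A), p1), tss=0.9),
            fixed_member(lambda A: np.full(len(A), 0.5), tss=0.6, auc_=0.7),
            fixed_member(lambda A: np.full(len(A), p3), tss=0.8),
        ]
        res = build_ensemble(members, stack)
        expected = (0.9 * p1 + 0.8 * p3) / 1.7
        np.testing.assert_allclose(res.hsi.unmasked_values(), expected)
        assert len(res.members_used) == 2

    def test_convex_combination_bounds(self, rng):
        stack = flat_stack(n_rows=8, n_cols=8, n_layers=2, seed=5)
        fns = [lambda A: 1 / (1 + np.exp(-A[:, 0])),
               lambda A: 1 / (1 + np.exp(-A[:, 1])),
               lambda A: np.full(len(A), 0.5)]
        members = [fixed_member(f, tss=t) for f, t in zip(fns, (0.7, 0.9, 0.65))]
        res = build_ensemble(members, stack)
        X = stack.feature_matrix(stack.land_indices())
        preds = np.stack([f(X) for f in fns])
        hsi = res.hsi.values.ravel()[stack.land_indices()]
        assert np.all(hsi >= preds.min(axis=0) - 1e-12)
        assert np.all(hsi <= preds.max(axis=0) + 1e-12)

    def test_no_passing_member_is_explicit_failure(self):
        stack = flat_stack(n_rows=4, n_cols=4, n_layers=1)
        with pytest.raises(SdmError, match="gate.*aegypti"):
            build_ensemble([fixed_member(lambda A: A[:, 0], tss=0.1,
                                         auc_=0.5)],
                           stack, species="aegypti")
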