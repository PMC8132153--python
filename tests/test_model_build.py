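"""Greedy AUC model build, risk scoring, Youden cutoff, clinical classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from nactrisk import (CohortSpec, GreedyConfig, MutationMatrix, RiskModel,
                      cooccurrence_prune, fit_clinical_classifier,
                      generate_cohort, greedy_forward_auc,
                      published_c_classifier, youden_cutoff)

NR, R = "non_responder", "responder"


class TestRiskScore:
    def test_published_model_all_zero_profile(self):
        model = published_c_classifier()
        assert model.risk_score({}) == pytest.approx(-1.9)
        assert len(model.coefficients) == 15
        assert model.cutoff == 8.4

    def test_single_gene_profiles_are_intercept_plus_coefficient(self):
        model = published_c_classifier()
        assert model.risk_score({"ST6GAL2": 1}) == pytest.approx(19.9)
        assert model.risk_score({"VPS13C": 1}) == pytest.approx(-0.6)

    def test_classification_at_published_cutoff(self):
        model = published_c_classifier()
        assert model.classify({"ST6GAL2": 1}) == NR     # 19.9 >= 8.4
        assert model.classify({"VPS13C": 1}) == R       # -0.6 < 8.4
        # exact-boundary convention: score == cutoff -> non-responder
        boundary = RiskModel(8.4, {"g": 1.0}, cutoff=8.4)
        assert boundary.classify({"g": 0}) == NR

    def test_small_coefficient_profiles_all_respond(self):
        """All 2^4 combinations of the four small-coefficient genes stay
        below the cutoff when the eleven large-coefficient genes are 0."""
        model = published_c_classifier()
        small = ["SALL3", "ANKDD1B", "BCL9L", "VPS13C"]
        scores = []
        for bits in itertools.product([0, 1], repeat=4):
            profile = dict(zip(small, bits))
            s = model.risk_score(profile)
            scores.append(s)
            assert model.classify(profile) == R
        assert min(scores) == pytest.approx(-1.9)
        assert max(scores) == pytest.approx(8.1)

    def test_monotone_in_positive_coefficients(self):
        model = published_c_classifier()
        profile = {g: 0 for g in model.genes}
        base = model.risk_score(profile)
        for g in model.genes:
            flipped = dict(profile, **{g: 1})
            assert model.risk_score(flipped) >= base

    def test_unknown_gene_warns_and_is_ignored(self):
        model = RiskModel(0.0, {"a": 1.0}, cutoff=0.5)
        with pytest.warns(UserWarning, match="not in model"):
            s = model.risk_score({"a": 1, "zzz": 1})
        assert s == pytest.approx(1.0)

    def test_any_mutation_rule(self):
        model = published_c_classifier()
        assert model.classify({"VPS13C": 1}, any_mutation=True) == NR
        assert model.classify({}, any_mutation=True) == R

    def test_serialization_round_trip(self, tmp_path):
        model = RiskModel(-1.5, {"a": 2.0, "b": -0.25}, cutoff=1.0,
                          provenance={"seed": 3})
        path = tmp_path / "m.json"
        model.save(path)
        loaded = RiskModel.load(path)
        assert loaded.to_dict() == model.to_dict()


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff([1, 2, 10, 11], [R, R, NR, NR])
        assert res.youden_j == pytest.approx(1.0)
        assert 2 < res.cutoff < 10

    def test_all_identical_scores(self):
        res = youden_cutoff([5, 5, 5, 5], [R, R, NR, NR])
        assert res.youden_j == 0.0

    def test_derived_example(self):
        res = youden_cutoff([1, 2, 3, 4], [R, R, NR, NR])
        assert res.cutoff == pytest.approx(2.5)
        assert res.youden_j == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([1, 2], [R, R])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=60), 1)  # force ties
        y = rng.integers(0, 2, 60)
        if y.sum() in (0, 60):
            y[0] = 1 - y[0]
        labels = np.where(y == 1, NR, R)
        res = youden_cutoff(scores, labels)

        best_j = -2
        for t in np.unique(np.concatenate([scores - 1e-6, scores + 1e-6])):
            call = scores >= t
            sens = (call & (y == 1)).sum() / (y == 1).sum()
            spec = (~call & (y == 0)).sum() / (y == 0).sum()
            best_j = max(best_j, sens + spec - 1)
        assert res.youden_j == pytest.approx(best_j, abs=1e-12)


def matrix_from(X: pd.DataFrame, y) -> MutationMatrix:
    labels = pd.Series(np.where(np.asarray(y) == 1, NR, R), index=X.index)
    return MutationMatrix(X.astype(int), labels)


class TestGreedy:
    def _instance(self, seed, n=80, p=6):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        probs = np.where(y[:, None] == 1,
                         rng.uniform(0.15, 0.5, p),
                         rng.uniform(0.02, 0.2, p))
        X = pd.DataFrame((rng.random((n, p)) < probs).astype(int),
                         columns=[f"g{i}" for i in range(p)],
                         index=[f"s{i}" for i in range(n)])
        return matrix_from(X, y), y

    def test_stop_rule_keeps_only_fixed_pair(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 30)
        X = pd.DataFrame({"top1": y, "top2": y ^ (rng.random(60) < 0.05),
                          "noise1": rng.integers(0, 2, 60),
                          "noise2": rng.integers(0, 2, 60)})
        X.index = [f"s{i}" for i in range(60)]
        model = greedy_forward_auc(matrix_from(X, y), None,
                                   ["top1", "top2", "noise1", "noise2"],
                                   GreedyConfig(cv_folds=5, seed=0))
        assert model.genes[:2] == ["top1", "top2"]
        assert len(model.genes) <= 3  # noise cannot beat a perfect pair

    def test_perfect_candidate_reaches_unit_auc(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 25 + [0] * 25)
        X = pd.DataFrame({"w1": rng.integers(0, 2, 50),
                          "w2": rng.integers(0, 2, 50),
                          "perfect": y})
        X.index = [f"s{i}" for i in range(50)]
        model = greedy_forward_auc(matrix_from(X, y), None,
                                   ["w1", "w2", "perfect"],
                                   GreedyConfig(cv_folds=5, seed=1))
        assert "perfect" in model.genes
        assert model.provenance["cv_auc"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_path_matches_brute_force_greedy_oracle(self, seed):
        matrix, y = self._instance(seed)
        cfg = GreedyConfig(cv_folds=5, seed=7)
        candidates = list(matrix.genes)
        model = greedy_forward_auc(matrix, None, candidates, cfg)

        # independent oracle: same folds, naive exhaustive refits each step
        X = matrix.data.to_numpy(dtype=float)
        idx = {g: i for i, g in enumerate(candidates)}
        folds = list(StratifiedKFold(5, shuffle=True,
                                     random_state=cfg.seed).split(X, y))

        def cv_auc(genes):
            pred = np.empty(len(y), dtype=float)
            for tr, te in folds:
                est = LogisticRegression(C=1e6, max_iter=1000)
                est.fit(X[tr][:, [idx[g] for g in genes]], y[tr])
                pred[te] = est.predict_proba(X[te][:, [idx[g] for g in genes]])[:, 1]
            return roc_auc_score(y, pred)

        selected = candidates[:2]
        remaining = candidates[2:]
        current = cv_auc(selected)
        while remaining:
            aucs = [(cv_auc(selected + [g]), -candidates.index(g), g)
                    for g in remaining]
            best_auc, _, best_g = max(aucs, key=lambda t: (t[0], t[1]))
            # ties resolved toward the better (earlier) candidate rank
            tied = [g for a, _, g in aucs if a >= best_auc - 1e-12]
            best_g = min(tied, key=candidates.index)
            if best_auc <= current + 1e-12:
                break
            selected.append(best_g)
            current = best_auc
            remaining = [g for g in remaining if g not in tied]

        assert model.genes == selected

    def test_needs_two_candidates(self, tiny_matrix):
        with pytest.raises(ValueError):
            greedy_forward_auc(tiny_matrix, None, ["GA"])


class TestCooccurrence:
    def test_uncorrelated_candidates_unchanged(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.integers(0, 2, size=(200, 4)), columns=list("abcd"))
        scores = pd.Series(1.0, index=list("abcd"))
        kept, log = cooccurrence_prune(X, list("abcd"), scores)
        assert kept == list("abcd") and log.empty

    def test_duplicate_column_removed_then_idempotent(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 2, 50)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.integers(0, 2, 50)})
        scores = pd.Series({"a": 2.0, "dup": 1.0, "b": 1.0})
        kept, log = cooccurrence_prune(X, ["a", "dup", "b"], scores, rounds=2)
        assert kept == ["a", "b"]
        assert len(log) == 1  # second round found nothing

    def test_planted_correlated_block_removed(self):
        rng = np.random.default_rng(12)
        base = rng.integers(0, 2, size=(300, 27))
        X = pd.DataFrame(base, columns=[f"g{i}" for i in range(27)])
        for k in range(5):  # five genes shadowing g0..g4
            X[f"dup{k}"] = X[f"g{k}"]
        genes = list(X.columns)
        scores = pd.Series(np.linspace(2, 1, len(genes)), index=genes)
        kept, _ = cooccurrence_prune(X, genes, scores)
        assert set(genes) - set(kept) == {f"dup{k}" for k in range(5)}


class TestClinicalClassifier:
    def _clinical(self, n, y, rng, age_shift=0.0):
        age = rng.normal(50, 8, n) + age_shift * y
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "age": np.round(age),
            "stage": rng.choice(["IB1", "IIB"], n),
            "differentiation": rng.choice(["well", "poor"], n),
            "scc_ag": np.round(np.exp(rng.normal(1, 0.5, n)), 2),
        })

    def test_constant_covariates_give_chance_auc(self):
        y = pd.Series([NR] * 20 + [R] * 20)
        clin = pd.DataFrame({"age": 50, "stage": "IB1",
                             "differentiation": "well", "scc_ag": 1.0},
                            index=range(40))
        with pytest.warns(UserWarning, match="constant covariates"):
            model = fit_clinical_classifier(clin, y)
        assert model.auc == pytest.approx(0.5)

    def test_planted_age_effect_recovered(self):
        rng = np.random.default_rng(30)
        n = 400
        age_old = rng.integers(0, 2, n)
        logit = -1.0 + 2.0 * age_old
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        clin = pd.DataFrame({
            "age": np.where(age_old, 60, 40) + rng.integers(-3, 4, n),
            "stage": rng.choice(["IB1", "IIB"], n),
            "differentiation": rng.choice(["well", "poor"], n),
            "scc_ag": np.round(np.exp(rng.normal(1, 0.5, n)), 2),
        })
        labels = pd.Series(np.where(y == 1, NR, R))
        model = fit_clinical_classifier(clin, labels)
        assert model.params["age_old"] == pytest.approx(2.0, abs=0.3)

    def test_missing_values_excluded(self):
        rng = np.random.default_rng(31)
        y = pd.Series([NR, R] * 20)
        clin = self._clinical(40, (y == NR).astype(int), rng)
        clin.loc[0, "scc_ag"] = "."
        model = fit_clinical_classifier(clin, y)
        assert model.n_excluded == 1
        assert model.n_used == 39
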