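"""Feature assembly, training, selection, metrics and leakage-safe CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abddg.dataset import AffinityRecord, CuratedDataset, augment_reverse, ddg_of
from abddg.model import (
    Featurizer,
    cross_validate,
    feature_schema,
    greedy_select,
    metrics,
    predict,
    schema_hash,
    train,
)
from abddg.structure_io import MultiMutation, MutationSpec, parse_mutation_list


def _random_X(n_rows, n_cols, seed, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"f{i}" for i in range(n_cols)]
    return pd.DataFrame(rng.normal(size=(n_rows, n_cols)), columns=names)


class TestFeaturize:
    def test_vector_matches_schema_length_and_order(self, toy_complex, featurizer):
        res = toy_complex.residues[2]
        mt = "M" if res.aa1 != "M" else "L"
        fv = featurizer.featurize(
            toy_complex,
            MultiMutation((MutationSpec(res.chain_id, res.aa1, res.number, res.icode, mt),)),
        )
        schema = feature_schema(featurizer.config)
        assert fv.names == [n for n, _ in schema]
        assert fv.families == [f for _, f in schema]
        assert len(fv.values) == len(schema)

    def test_single_site_uses_zero_intermutation_sentinel(self, toy_complex, featurizer):
        res = toy_complex.residues[2]
        mt = "M" if res.aa1 != "M" else "L"
        fv = featurizer.featurize(
            toy_complex,
            MultiMutation((MutationSpec(res.chain_id, res.aa1, res.number, res.icode, mt),)),
        )
        s = fv.as_series()
        assert (s["dist_inter_min"], s["dist_inter_mean"], s["dist_inter_max"]) == (0, 0, 0)
        assert s["n_sites"] == 1

    def test_missing_pssm_only_touches_evolutionary_columns(self, toy_complex):
        """PSSM availability must not leak into non-evolutionary features."""
        from abddg.conservation import PssmProfile

        res = toy_complex.residues[2]
        chain = res.chain_id
        seq = "".join(r.aa1 for r in toy_complex.chain_residues(chain))
        rng = np.random.default_rng(5)
        profile = PssmProfile(list(seq), rng.integers(-8, 10, size=(len(seq), 20)))
        mt = "M" if res.aa1 != "M" else "L"
        mut = MultiMutation(
            (MutationSpec(chain, res.aa1, res.number, res.icode, mt),)
        )
        without = Featurizer().featurize(toy_complex, mut)
        with_pssm = Featurizer(pssms={chain: profile}).featurize(toy_complex, mut)
        evo = [i for i, f in enumerate(without.families) if f == "evolutionary"]
        non_evo = [i for i in range(len(without.values)) if i not in evo]
        assert np.array_equal(without.values[non_evo], with_pssm.values[non_evo])
        assert without.values[without.names.index("evo_pssm_missing")] == 1.0
        assert with_pssm.values[without.names.index("evo_pssm_missing")] == 0.0


class TestTrain:
    def test_memorizes_noiseless_synthetic_data(self):
        X = _random_X(200, 12, seed=0)
        y = 2.0 * X["f3"].to_numpy() - 0.5 * X["f7"].to_numpy()
        model = train(X, y, seed=0)
        r = stats.pearsonr(y, model.predict_matrix(X))[0]
        assert r >= 0.99

    def test_same_seed_same_predictions_bitwise(self):
        X = _random_X(60, 8, seed=1)
        y = X["f0"].to_numpy() + 0.1
        p1 = train(X, y, seed=42).predict_matrix(X)
        p2 = train(X, y, seed=42).predict_matrix(X)
        assert np.array_equal(p1, p2)

    def test_permuted_targets_have_no_held_out_signal(self):
        rng = np.random.default_rng(3)
        X = _random_X(300, 10, seed=3)
        y = 2.0 * X["f2"].to_numpy() + rng.normal(0, 0.2, 300)
        y_perm = rng.permutation(y)
        model = train(X.iloc[:200], y_perm[:200], seed=0)
        r = stats.pearsonr(y[200:], model.predict_matrix(X.iloc[200:]))[0]
        assert abs(r) < 0.2

    def test_degenerate_targets_rejected(self):
        X = _random_X(20, 4, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            train(X, np.ones(20), seed=0)

    def test_schema_hash_guards_prediction(self, toy_complex, featurizer):
        X = _random_X(30, len(featurizer.names), seed=0, names=featurizer.names)
        y = X.iloc[:, 0].to_numpy()
        model = train(X, y, seed=0, config=featurizer.config)
        model.schema = "deadbeef"
        res = toy_complex.residues[2]
        mt = "M" if res.aa1 != "M" else "L"
        with pytest.raises(ValueError, match="schema"):
            predict(
                model, featurizer, toy_complex,
                MultiMutation((MutationSpec(res.chain_id, res.aa1, res.number,
                                            res.icode, mt),)),
            )


class TestGreedySelect:
    def test_single_informative_feature_found_first(self):
        rng = np.random.default_rng(0)
        X = _random_X(120, 6, seed=0)
        y = 2.0 * X["f3"].to_numpy() + rng.normal(0, 0.1, 120)
        selected = greedy_select(X, y, seed=0)
        assert selected[0] == "f3"

    def test_noise_columns_rarely_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = _random_X(90, 6, seed=seed,
                          names=["signal", "n1", "n2", "n3", "n4", "n5"])
            y = 1.5 * X["signal"].to_numpy() + rng.normal(0, 0.2, 90)
            selected = greedy_select(X, y, seed=seed, n_estimators=30, epsilon=0.01)
            if set(selected) == {"signal"}:
                hits += 1
        assert hits >= 8

    def test_infinite_epsilon_selects_exactly_one(self):
        X = _random_X(80, 5, seed=2)
        y = X["f1"].to_numpy()
        assert len(greedy_select(X, y, seed=0, epsilon=np.inf)) == 1


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([-2.0, -1.0, 0.7, 1.5, 3.0])
        rep = metrics(y, y.copy())
        assert rep.pearson == pytest.approx(1.0)
        assert rep.spearman == pytest.approx(1.0)
        assert rep.kendall == pytest.approx(1.0)
        assert rep.rmse == 0.0

    def test_rmse_on_constant_vectors(self):
        rep = metrics([0.0, 0.0], [1.0, 1.0])
        assert rep.rmse == 1.0
        assert np.isnan(rep.pearson)

    def test_mcc_matches_hand_computed_contingency(self):
        y_true = np.array([1.0, 2.0, -1.0, -2.0, 0.8, -0.8])
        y_pred = np.array([1.5, -0.3, -1.2, -0.9, 0.6, 0.4])
        rep = metrics(y_true, y_pred)
        # contingency by hand: TP=2, FN=1, TN=2, FP=1
        tp, fn, tn, fp = 2, 1, 2, 1
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert rep.mcc == pytest.approx(mcc)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0], [1.0, 2.0])


def _cv_dataset(toy_complexes, per_complex=6, with_reverses=True, seed=0):
    """Small affinity dataset over real toy complexes with dummy features."""
    rng = np.random.default_rng(seed)
    records = []
    for cid, cx in toy_complexes.items():
        candidates = [r for r in cx.residues if r.aa1 is not None]
        chosen = rng.choice(len(candidates), size=per_complex, replace=False)
        for i in chosen:
            res = candidates[int(i)]
            mt = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != res.aa1])
            records.append(
                AffinityRecord(
                    complex_id=cid,
                    mutation=MultiMutation(
                        (MutationSpec(res.chain_id, res.aa1, res.number,
                                      res.icode, str(mt)),)
                    ),
                    ddg=float(rng.normal(-1, 1.5)),
                )
            )
    if with_reverses:
        records = augment_reverse(records, threshold_kcal=2.0)
    return CuratedDataset(records)


class TestCrossValidate:
    def test_loco_gives_one_fold_per_complex(self, toy_complexes, featurizer):
        ds = _cv_dataset(toy_complexes, with_reverses=False)
        X = _random_X(len(ds.train), 5, seed=0)
        rep = cross_validate(ds, toy_complexes, featurizer, "loco", seed=0,
                             n_estimators=20, X=X)
        assert len(rep.per_fold) == len(toy_complexes)
        for entry in rep.per_fold:
            assert len(entry["test_complexes"]) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_no_leakage_under_either_scheme(self, toy_complexes, featurizer, seed):
        """A complex never splits across LOCO folds, and every reverse sits in
        the same k-fold side as its forward record."""
        from sklearn.model_selection import StratifiedGroupKFold

        ds = _cv_dataset(toy_complexes, with_reverses=True, seed=seed)
        records = ds.train
        y = np.array([ddg_of(r) for r in records])
        from abddg.model import _fold_groups

        groups = _fold_groups(records)
        quartiles = pd.qcut(y, q=4, labels=False, duplicates="drop")
        skf = StratifiedGroupKFold(n_splits=3, shuffle=True, random_state=seed)
        for tr, te in skf.split(np.zeros((len(y), 1)), quartiles, groups=groups):
            assert set(groups[tr]) & set(groups[te]) == set()
        # LOCO partitioning keeps complexes whole
        from sklearn.model_selection import LeaveOneGroupOut

        cids = np.array([r.complex_id for r in records])
        for tr, te in LeaveOneGroupOut().split(np.zeros((len(y), 1)), groups=cids):
            assert set(cids[tr]) & set(cids[te]) == set()

    def test_kfold_equal_to_group_count_runs(self, toy_complexes, featurizer):
        """k = number of leakage groups degenerates to leave-one-out and runs."""
        ds = _cv_dataset(toy_complexes, per_complex=3, with_reverses=False)
        n = len(ds.train)
        X = _random_X(n, 4, seed=1)
        rep = cross_validate(ds, toy_complexes, featurizer, f"kfold:{n}", seed=0,
                             n_estimators=10, X=X)
        assert len(rep.per_fold) == n

    def test_k_above_group_count_rejected(self, toy_complexes, featurizer):
        ds = _cv_dataset(toy_complexes, per_complex=2, with_reverses=False)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(ds, toy_complexes, featurizer, "kfold:99", seed=0,
                           X=_random_X(len(ds.train), 3, seed=0))


class TestPredictInvariance:
    def test_prediction_invariant_under_translation(self, toy_complex, featurizer):
        res = toy_complex.residues[2]
        mt = "M" if res.aa1 != "M" else "L"
        mut = MultiMutation(
            (MutationSpec(res.chain_id, res.aa1, res.number, res.icode, mt),)
        )
        fv = featurizer.featurize(toy_complex, mut)
        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(40, len(fv.values))),
            columns=fv.names,
        )
        y = X.iloc[:, 0].to_numpy()
        model = train(X, y, seed=0, config=featurizer.config)
        p0 = predict(model, featurizer, toy_complex, mut)
        moved = toy_complex.copy()
        for r in moved.residues:
            for a in r.atoms:
                a.position = a.position + np.array([13.0, -4.0, 8.0])
        fz2 = Featurizer(featurizer.config)
        assert predict(model, fz2, moved, mut) == p0
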