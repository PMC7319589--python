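"""Feature assembly, ensemble-tree regression and evaluation.

For each (complex, multi-mutation) pair the featurizer builds the mutant
structure (incremental side-chain grafting), then emits, in a versioned
schema order:

* cutoff-scanning-matrix signature of the union environment of the mutated
  sites (wild-type structure);
* summed pharmacophore-change counts over sites;
* mutant − wild-type contact-count deltas per type in three scopes;
* mutant − wild-type SASA deltas (sites / total / interface-buried);
* mutation geometry: min/mean/max pairwise inter-site distance (0 sentinel
  for single sites), min/mean distance to the binding partner, site count;
* evolutionary scores: PAM30 sum/min over sites and, when PSSMs are given,
  wild-type/mutant/delta log-odds (sum and min) with a missingness flag.

The regressor is an ensemble of extremely randomized trees (ExtraTrees);
feature selection is incremental stepwise greedy forward selection on
cross-validated Pearson correlation. Cross-validation never splits a complex
across folds in leave-one-complex-out mode, and hypothetical reverse records
always travel with their forward record.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score
from sklearn.model_selection import (
    KFold,
    LeaveOneGroupOut,
    StratifiedGroupKFold,
)

from .conservation import PssmProfile, load_pam30, map_profile_to_chain, pam30_score, pssm_features
from .dataset import AffinityRecord, CuratedDataset, classify_ddg, ddg_of
from .interactions import (
    CONTACT_TYPES,
    ContactConfig,
    buried_area,
    delta_contacts,
    detect_contacts,
    delta_sasa,
    sasa,
)
from .signatures import (
    GraphSignature,
    PharmacophoreChange,
    SignatureParams,
    csm_signature,
    load_pharmacophore_table,
    pharmacophore_change,
)
from .structure_io import (
    Complex,
    MultiMutation,
    StructureError,
    build_mutant,
    distance_to_partner,
    min_heavy_distance,
)

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "Featurizer",
    "feature_schema",
    "schema_hash",
    "TrainedModel",
    "train",
    "predict",
    "greedy_select",
    "EvalReport",
    "metrics",
    "cross_validate",
]

SCHEMA_VERSION = "1"

FEATURE_FAMILIES = (
    "signature",
    "pharmacophore-change",
    "contacts",
    "sasa",
    "distances",
    "evolutionary",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Every tunable of the feature extractors, in one place."""

    signature: SignatureParams = SignatureParams()
    contacts: ContactConfig = ContactConfig()
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    interface_cutoff: float = 5.0


def feature_schema(config: FeatureConfig | None = None) -> list[tuple[str, str]]:
    """Ordered (feature name, family) pairs — the model's input contract."""
    config = config or FeatureConfig()
    schema: list[tuple[str, str]] = []
    for name in GraphSignature.feature_names(config.signature):
        schema.append((name, "signature"))
    for name in PharmacophoreChange.feature_names():
        schema.append((name, "pharmacophore-change"))
    for scope in ("all", "interfacial", "sites"):
        for t in CONTACT_TYPES:
            schema.append((f"contacts_delta_{scope}_{t}", "contacts"))
    for name in ("sasa_delta_sites", "sasa_delta_total", "sasa_delta_buried"):
        schema.append((name, "sasa"))
    for name in (
        "dist_inter_min",
        "dist_inter_mean",
        "dist_inter_max",
        "dist_partner_min",
        "dist_partner_mean",
        "n_sites",
    ):
        schema.append((name, "distances"))
    for name in (
        "evo_pam30_sum",
        "evo_pam30_min",
        "evo_pssm_wt_sum",
        "evo_pssm_mt_sum",
        "evo_pssm_delta_sum",
        "evo_pssm_delta_min",
        "evo_pssm_missing",
    ):
        schema.append((name, "evolutionary"))
    return schema


def schema_hash(config: FeatureConfig | None = None) -> str:
    names = ",".join(n for n, _ in feature_schema(config))
    return hashlib.sha256(f"v{SCHEMA_VERSION}:{names}".encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    names: list[str]
    families: list[str]
    values: np.ndarray
    missing: np.ndarray  # boolean mask: value is a placeholder awaiting imputation

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


class Featurizer:
    """Computes feature vectors; caches per-complex wild-type quantities
    (contacts, SASA, buried area) so batches over one structure stay cheap."""

    def __init__(
        self,
        config: FeatureConfig | None = None,
        pssms: dict[str, PssmProfile] | None = None,
    ):
        self.config = config or FeatureConfig()
        self.schema = feature_schema(self.config)
        self.names = [n for n, _ in self.schema]
        self.families = [f for _, f in self.schema]
        self.pssms = pssms or {}
        self._wt_cache: dict[int, dict] = {}
        self._pssm_maps: dict[tuple[int, str], dict] = {}
        self._table = load_pharmacophore_table()

    def _wt_state(self, complex_: Complex) -> dict:
        key = id(complex_)
        if key not in self._wt_cache:
            cfg = self.config
            self._wt_cache[key] = {
                "contacts": detect_contacts(complex_, cfg.contacts),
                "sasa": sasa(complex_, cfg.sasa_probe_radius, cfg.sasa_n_points),
                "buried": buried_area(complex_, cfg.sasa_probe_radius, cfg.sasa_n_points),
            }
        return self._wt_cache[key]

    def _pssm_lookup(self, complex_: Complex, chain_id: str):
        if chain_id not in self.pssms:
            return None, None
        key = (id(complex_), chain_id)
        if key not in self._pssm_maps:
            self._pssm_maps[key] = map_profile_to_chain(
                self.pssms[chain_id], complex_, chain_id
            )
        return self.pssms[chain_id], self._pssm_maps[key]

    def featurize(self, complex_: Complex, mutation: MultiMutation) -> FeatureVector:
        cfg = self.config
        sites = mutation.sites
        for spec in mutation:
            res = complex_.residue(spec.site)
            if res.aa1 != spec.wt_aa:
                raise StructureError(
                    f"wild-type mismatch at {spec.site}: expected {spec.wt_aa}, found {res.aa1}"
                )

        mutant = build_mutant(complex_, mutation)
        wt_state = self._wt_state(complex_)

        sig = csm_signature(complex_, sites, cfg.signature, self._table)

        pharm = pharmacophore_change(mutation.specs[0].wt_aa, mutation.specs[0].mt_aa, self._table)
        for spec in mutation.specs[1:]:
            pharm = pharm + pharmacophore_change(spec.wt_aa, spec.mt_aa, self._table)

        dcon = delta_contacts(
            complex_, mutant, sites, cfg.contacts, wt_contacts=wt_state["contacts"]
        )
        ds_sites, ds_total, ds_buried = delta_sasa(
            complex_,
            mutant,
            sites,
            cfg.sasa_probe_radius,
            cfg.sasa_n_points,
            wt_sasa=wt_state["sasa"],
            wt_buried=wt_state["buried"],
        )

        if len(sites) >= 2:
            pairwise = [
                min_heavy_distance(complex_, a, b)
                for i, a in enumerate(sites)
                for b in sites[i + 1:]
            ]
            d_inter = (min(pairwise), float(np.mean(pairwise)), max(pairwise))
        else:
            d_inter = (0.0, 0.0, 0.0)  # single-site sentinel; n_sites disambiguates
        d_partner = [distance_to_partner(complex_, s) for s in sites]

        pam = [pam30_score(s.wt_aa, s.mt_aa) for s in mutation]
        pssm_rows = []
        pssm_missing = False
        for spec in mutation:
            profile, pmap = self._pssm_lookup(complex_, spec.chain_id)
            if profile is None:
                pssm_missing = True
                pssm_rows.append((np.nan, np.nan, np.nan))
            else:
                pssm_rows.append(pssm_features(profile, spec, pmap))
        pssm_arr = np.array(pssm_rows, dtype=float)

        values: list[float] = []
        values.extend(sig.flatten())
        values.extend(pharm.as_array())
        for scope in ("all", "interfacial", "sites"):
            values.extend(float(dcon[scope][t]) for t in CONTACT_TYPES)
        values.extend([ds_sites, ds_total, ds_buried])
        values.extend(d_inter)
        values.extend([min(d_partner), float(np.mean(d_partner)), float(len(sites))])
        if pssm_missing:
            pssm_block = [np.nan, np.nan, np.nan, np.nan, 1.0]
        else:
            pssm_block = [
                float(pssm_arr[:, 0].sum()),
                float(pssm_arr[:, 1].sum()),
                float(pssm_arr[:, 2].sum()),
                float(pssm_arr[:, 2].min()),
                0.0,
            ]
        values.extend([float(sum(pam)), float(min(pam))])
        values.extend(pssm_block)

        arr = np.array(values, dtype=float)
        if len(arr) != len(self.names):
            raise RuntimeError(
                f"feature count {len(arr)} does not match schema length {len(self.names)}"
            )
        missing = np.isnan(arr)
        return FeatureVector(self.names, self.families, arr, missing)

    def feature_table(
        self, complexes: dict[str, Complex], records: list[AffinityRecord]
    ) -> pd.DataFrame:
        """Feature matrix for affinity records (rows aligned with `records`).

        Reverse records are featurized on the modelled mutant structure as the
        new wild-type context, not by negating forward features.
        """
        rows = []
        for rec in records:
            cx = complexes[rec.complex_id]
            if rec.is_reverse:
                forward = MultiMutation(
                    tuple(
                        type(s)(s.chain_id, s.mt_aa, s.number, s.icode, s.wt_aa)
                        for s in rec.mutation
                    )
                )
                cx = self._reverse_context(cx, forward)
            rows.append(self.featurize(cx, rec.mutation).values)
        return pd.DataFrame(np.vstack(rows), columns=self.names)

    def _reverse_context(self, complex_: Complex, forward: MultiMutation) -> Complex:
        key = (id(complex_), str(forward))
        cache = self._wt_cache.setdefault("reverse_contexts", {})
        if key not in cache:
            cache[key] = build_mutant(complex_, forward)
        return cache[key]


def impute_missing(X: pd.DataFrame, medians: pd.Series | None = None):
    """Median-impute NaN columns; returns (imputed matrix, medians used)."""
    if medians is None:
        medians = X.median(numeric_only=True).fillna(0.0)
    return X.fillna(medians), medians


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    estimator: ExtraTreesRegressor
    selected_features: list[str]
    schema: str
    seed: int
    medians: pd.Series
    fingerprint: str

    def predict_matrix(self, X: pd.DataFrame) -> np.ndarray:
        Xi, _ = impute_missing(X, self.medians)
        return self.estimator.predict(Xi[self.selected_features].to_numpy())


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int,
    n_estimators: int = 300,
    selected_features: list[str] | None = None,
    config: FeatureConfig | None = None,
) -> TrainedModel:
    """Fit the extremely-randomized-trees ensemble.

    Deterministic given (data, seed); refuses degenerate targets.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 training rows")
    if float(np.var(y)) == 0.0:
        raise ValueError("degenerate targets: zero variance")
    selected = selected_features or list(X.columns)
    Xi, medians = impute_missing(X)
    est = ExtraTreesRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    est.fit(Xi[selected].to_numpy(), y)
    fingerprint = hashlib.sha256(
        np.ascontiguousarray(Xi[selected].to_numpy()).tobytes() + y.tobytes()
    ).hexdigest()[:16]
    return TrainedModel(est, selected, schema_hash(config), seed, medians, fingerprint)


def predict(
    model: TrainedModel,
    featurizer: Featurizer,
    complex_: Complex,
    mutation: MultiMutation,
) -> float:
    """Predicted ΔΔG (kcal/mol) for one multi-mutation."""
    if model.schema != schema_hash(featurizer.config):
        raise ValueError(
            "feature schema mismatch: the model was trained under a different schema"
        )
    fv = featurizer.featurize(complex_, mutation)
    X = pd.DataFrame([fv.values], columns=fv.names)
    return float(model.predict_matrix(X)[0])


# ---------------------------------------------------------------------------
# Greedy forward feature selection
# ---------------------------------------------------------------------------

def _cv_pearson(X: np.ndarray, y: np.ndarray, seed: int, n_splits: int, n_estimators: int) -> float:
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for tr, te in kf.split(X):
        est = ExtraTreesRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        est.fit(X[tr], y[tr])
        preds[te] = est.predict(X[te])
    if np.std(preds) == 0:
        return -1.0
    return float(stats.pearsonr(y, preds)[0])


def greedy_select(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int,
    epsilon: float = 1e-3,
    n_splits: int = 5,
    n_estimators: int = 50,
    max_features: int | None = None,
) -> list[str]:
    """Incremental stepwise greedy forward selection.

    At each step the candidate whose addition maximizes cross-validated
    Pearson correlation joins the set; selection stops when no candidate
    improves the score by more than `epsilon`. Ties break on schema order.
    """
    if X.shape[1] < 2:
        raise ValueError("greedy selection needs at least 2 candidate features")
    y = np.asarray(y, dtype=float)
    Xi, _ = impute_missing(X)
    cols = list(Xi.columns)
    selected: list[str] = []
    best_score = -np.inf
    limit = max_features or len(cols)
    while len(selected) < limit:
        best_candidate, best_candidate_score = None, -np.inf
        for c in cols:  # schema order; ties keep the first (strict > below)
            if c in selected:
                continue
            score = _cv_pearson(
                Xi[selected + [c]].to_numpy(), y, seed, n_splits, n_estimators
            )
            if score > best_candidate_score:
                best_candidate, best_candidate_score = c, score
        if best_candidate is None:
            break
        if selected and best_candidate_score - best_score <= epsilon:
            break
        selected.append(best_candidate)
        best_score = best_candidate_score
    return selected


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    pearson: float
    spearman: float
    kendall: float
    rmse: float
    mcc: float | None
    f1: float | None
    auc: float | None
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "kendall": self.kendall,
            "rmse": self.rmse,
            "mcc": self.mcc,
            "f1": self.f1,
            "auc": self.auc,
            "per_fold": self.per_fold,
        }


def metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    binarize_at_zero: bool = False,
) -> EvalReport:
    """Regression and classification metrics.

    Classification applies the ±0.5 kcal/mol thresholds to both vectors
    (positive class = increasing). Neutral-band true values are dropped by
    default or pushed to the outer classes with ``binarize_at_zero``;
    predictions are binarized at 0 for MCC/F1 and ranked by raw value for AUC.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        # correlations are undefined on constant input; RMSE still is not
        pearson = spearman = kendall = float("nan")
    else:
        pearson = float(stats.pearsonr(y_true, y_pred)[0])
        spearman = float(stats.spearmanr(y_true, y_pred)[0])
        kendall = float(stats.kendalltau(y_true, y_pred)[0])  # tau-b
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))

    true_cls = np.array([classify_ddg(v, binarize_at_zero) for v in y_true])
    keep = true_cls != "neutral"
    mcc = f1 = auc = None
    if keep.sum() >= 2 and len(set(true_cls[keep])) == 2:
        t = (true_cls[keep] == "increasing").astype(int)
        p = (y_pred[keep] > 0).astype(int)
        mcc = float(matthews_corrcoef(t, p))
        f1 = float(f1_score(t, p))
        auc = float(roc_auc_score(t, y_pred[keep]))
    return EvalReport(pearson, spearman, kendall, rmse, mcc, f1, auc)


def _fold_groups(records: list[AffinityRecord]) -> np.ndarray:
    """Group key that keeps a reverse with its forward record: the forward
    mutation identity within the complex."""
    keys = []
    for r in records:
        specs = []
        for s in r.mutation:
            wt, mt = (s.mt_aa, s.wt_aa) if r.is_reverse else (s.wt_aa, s.mt_aa)
            specs.append((s.chain_id, wt, s.number, s.icode, mt))
        keys.append((r.complex_id, tuple(sorted(specs))))
    uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    return np.array([uniq[k] for k in keys])


def cross_validate(
    dataset: CuratedDataset,
    complexes: dict[str, Complex],
    featurizer: Featurizer,
    scheme: str,
    seed: int,
    n_estimators: int = 300,
    selected_features: list[str] | None = None,
    X: pd.DataFrame | None = None,
) -> EvalReport:
    """Cross-validated evaluation on the training partition.

    `scheme` is ``"kfold:<k>"`` (stratified by ΔΔG quartile, grouped so that
    forward/reverse pairs co-travel) or ``"loco"`` (leave-one-complex-out:
    every record of a complex, including reverses, sits in the same fold).
    A precomputed feature matrix `X` aligned with the training records may be
    passed to avoid re-featurizing.
    """
    records = dataset.train
    y = np.array([ddg_of(r) for r in records])
    if X is None:
        X = featurizer.feature_table(complexes, records)
    complex_ids = np.array([r.complex_id for r in records])

    if scheme == "loco":
        splitter = LeaveOneGroupOut()
        groups = complex_ids
        split_iter = splitter.split(X, y, groups=groups)
    elif scheme.startswith("kfold:"):
        k = int(scheme.split(":", 1)[1])
        n_groups = len(np.unique(_fold_groups(records)))
        if k > n_groups:
            raise ValueError(f"k={k} exceeds the {n_groups} leakage groups")
        quartiles = np.asarray(pd.qcut(y, q=4, labels=False, duplicates="drop"))
        groups_arr = _fold_groups(records)
        counts = np.bincount(quartiles)
        if k <= counts.min():
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            split_iter = splitter.split(X, quartiles, groups=groups_arr)
        else:
            # stratification cannot support this k (e.g. leave-one-out);
            # keep only the grouping constraint
            from sklearn.model_selection import GroupKFold

            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(np.unique(groups_arr))
            remap = {g: i for i, g in enumerate(shuffled)}
            split_iter = GroupKFold(n_splits=k).split(
                X, y, groups=np.array([remap[g] for g in groups_arr])
            )
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    preds = np.full(len(y), np.nan)
    per_fold = []
    for fold, (tr, te) in enumerate(split_iter):
        model = train(
            X.iloc[tr], y[tr], seed=seed, n_estimators=n_estimators,
            selected_features=selected_features,
        )
        preds[te] = model.predict_matrix(X.iloc[te])
        entry = {
            "fold": fold,
            "n_test": int(len(te)),
            "test_complexes": sorted(set(complex_ids[te])),
        }
        if len(te) >= 2 and np.std(y[te]) > 0 and np.std(preds[te]) > 0:
            entry["pearson"] = float(stats.pearsonr(y[te], preds[te])[0])
            entry["rmse"] = float(np.sqrt(np.mean((y[te] - preds[te]) ** 2)))
        per_fold.append(entry)
    report = metrics(y, preds)
    report.per_fold = per_fold
    return report
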