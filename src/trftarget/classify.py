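"""Site classifier: SVM with genetic-algorithm feature selection under
stratified fivefold cross-validation, plus transcript-level aggregation
and evaluation metrics.

The model object / results object split follows the statsmodels
convention: :class:`TargetSiteClassifier` holds the data and design
(feature matrix, labels, fold assignment), ``fit()`` runs GA feature
selection and per-fold SVM training and returns a
:class:`TargetSiteClassifierResults` carrying the selected feature mask,
the five fitted fold models, held-out probabilities, per-fold AUCs and a
``summary()`` table.  Prediction for new sites averages the five
calibrated fold probabilities, and per-transcript probabilities combine
sites as independent events (noisy-OR):

    P = 1 - prod_i (1 - p_i),     target <=> P > 0.5.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .chimera import InteractionPair
from .features import FeatureRegistry, default_registry

#: negative:positive ratio used when sampling the negative group
NEGATIVE_RATIO = 5

DEFAULT_PARAM_GRID = {
    "C": [2.0**e for e in range(-3, 8)],
    "gamma": [2.0**e for e in range(-7, 4)],
}


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm knobs; defaults follow the published settings."""

    iterations: int = 10_000
    crossover_prob: float = 0.10
    mutation_prob: float = 0.30
    population_size: int = 50
    tournament_size: int = 3
    elitism: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int


@dataclass(frozen=True)
class EvaluationMetrics:
    """Sensitivity, specificity and MCC; undefined values are NaN."""

    sensitivity: float
    specificity: float
    mcc: float


@dataclass(frozen=True)
class SitePrediction:
    trf_id: str
    transcript_id: str
    start: int
    end: int
    p_site: float


@dataclass(frozen=True)
class TranscriptPrediction:
    trf_id: str
    transcript_id: str
    n_sites: int
    P: float
    is_target: bool


@dataclass
class _FoldModel:
    medians: np.ndarray  # training-partition medians for imputation
    scaler: StandardScaler
    svc: SVC


@dataclass
class TrainedModel:
    """Everything needed to score new sites: mask + five fold pipelines."""

    feature_names: list[str]
    selected_mask: np.ndarray  # bool over feature_names
    fold_models: list[_FoldModel]
    registry_version: str
    fold_auc_train: list[float] = field(default_factory=list)
    fold_auc_test: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format": "trftarget-model-v1", "model": self}, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "trftarget-model-v1":
            raise ValueError("not a trftarget model archive")
        return payload["model"]


# ---------------------------------------------------------------------------
# training-set assembly


def sample_negatives(
    background: list[InteractionPair],
    tag_counts: dict[str, int],
    n_positives: int,
    ratio: int = NEGATIVE_RATIO,
    rng_seed: int = 0,
) -> list[InteractionPair]:
    """Negatives: uniform sample from the most 3P-seq-supported background.

    Background pairs are ranked by host-transcript tag count descending;
    the top pool (twice the requested size, extended through rank ties)
    is sampled uniformly without replacement.  A background smaller than
    the request is returned whole.
    """
    n = ratio * n_positives
    ranked = sorted(
        background,
        key=lambda p: (-tag_counts.get(p.transcript_id, 0), p.key),
    )
    if len(ranked) <= n:
        return [replace(p, label="negative") for p in ranked]
    pool_size = min(len(ranked), max(2 * n, n))
    # extend the pool through ties at the boundary tag count
    boundary = tag_counts.get(ranked[pool_size - 1].transcript_id, 0)
    while pool_size < len(ranked) and tag_counts.get(ranked[pool_size].transcript_id, 0) == boundary:
        pool_size += 1
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(pool_size, size=n, replace=False)
    return [replace(ranked[i], label="negative") for i in sorted(chosen)]


def make_folds(labels: np.ndarray, k: int = 5, rng_seed: int = 0) -> np.ndarray:
    """Label-stratified fold assignment, sizes differing by at most 1."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError("fewer rows than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels), start=1):
        assignment[test_idx] = fold
    return assignment


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(medians, np.nonzero(nan_mask)[1])
    return X


def _train_medians(X_train: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns are legal
        med = np.nanmedian(X_train, axis=0)
    return np.where(np.isnan(med), 0.0, med)


# ---------------------------------------------------------------------------
# GA feature selection


def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    mask: np.ndarray,
    svm_params: dict,
) -> float:
    """Mean held-out AUC of an SVM over the precomputed folds.

    Uses the decision function (not calibrated probabilities), which is
    rank-equivalent for AUC and much cheaper inside the GA loop.
    """
    Xm = X[:, mask]
    aucs = []
    for fold in np.unique(folds):
        tr, te = folds != fold, folds == fold
        med = _train_medians(Xm[tr])
        Xtr, Xte = _impute(Xm[tr], med), _impute(Xm[te], med)
        scaler = StandardScaler().fit(Xtr)
        svc = SVC(**svm_params).fit(scaler.transform(Xtr), y[tr])
        score = svc.decision_function(scaler.transform(Xte))
        aucs.append(roc_auc_score(y[te], score))
    return float(np.mean(aucs))


def ga_select_features(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    cfg: GaConfig,
    svm_params: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Evolve a feature bitmask maximizing mean held-out CV AUC.

    Canonical GA: tournament selection, uniform crossover applied with
    probability ``crossover_prob``, per-bit mutation at
    ``mutation_prob``, one elite carried over each generation.  The
    all-features mask is seeded into the initial population, so the
    returned fitness is never below it.  All-zero candidates are
    repaired by switching one random bit on.
    """
    n_features = X.shape[1]
    if n_features < 1:
        raise ValueError("no features")
    if n_features == 1:
        mask = np.ones(1, dtype=bool)
        return mask, _cv_auc(X, y, folds, mask, svm_params or {"C": 1.0, "gamma": "scale"})
    svm_params = svm_params or {"C": 1.0, "gamma": "scale"}
    rng = np.random.default_rng(cfg.rng_seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _cv_auc(X, y, folds, mask, svm_params)
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(n_features)] = True
        return mask

    pop = [repair(rng.random(n_features) < 0.5) for _ in range(cfg.population_size)]
    pop[0] = np.ones(n_features, dtype=bool)
    fits = [fitness(m) for m in pop]
    best_idx = int(np.argmax(fits))
    best_mask, best_fit = pop[best_idx].copy(), fits[best_idx]

    for _ in range(cfg.iterations):
        new_pop = [best_mask.copy()]  # elite
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
                winner = max(contenders, key=lambda i: fits[i])
                parents.append(pop[winner])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.crossover_prob:
                swap = rng.random(n_features) < 0.5
                a[swap], b[swap] = parents[1][swap], parents[0][swap]
            for child in (a, b):
                flip = rng.random(n_features) < cfg.mutation_prob
                child ^= flip
                new_pop.append(repair(child))
        pop = new_pop[: cfg.population_size]
        fits = [fitness(m) for m in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_mask = pop[gen_best].copy()
    return best_mask, best_fit


# ---------------------------------------------------------------------------
# SVM training and prediction


def train_cv_svm(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    mask: np.ndarray,
    feature_names: list[str],
    registry_version: str = "",
    svm_params: dict | None = None,
    param_grid: dict | None = None,
    grid_cv: int = 3,
) -> tuple[TrainedModel, np.ndarray]:
    """Fit one probability-calibrated SVM per fold on its training split.

    Imputation medians and scaling are fitted on training rows only.
    With ``param_grid`` given, an inner grid search on the training
    split picks C and gamma per fold.  Returns the model and the
    held-out probability of every row (each row scored exactly once, by
    the model whose test fold it sits in).
    """
    if not mask.any():
        raise ValueError("empty feature mask")
    Xm = X[:, mask]
    heldout = np.full(len(y), np.nan)
    fold_models, auc_train, auc_test = [], [], []
    for fold in np.unique(folds):
        tr, te = folds != fold, folds == fold
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {fold} is single-class")
        med = _train_medians(Xm[tr])
        Xtr, Xte = _impute(Xm[tr], med), _impute(Xm[te], med)
        scaler = StandardScaler().fit(Xtr)
        Str, Ste = scaler.transform(Xtr), scaler.transform(Xte)
        params = dict(svm_params or {"C": 1.0, "gamma": "scale"})
        if param_grid:
            search = GridSearchCV(
                SVC(), param_grid, cv=grid_cv, scoring="roc_auc", n_jobs=1
            ).fit(Str, y[tr])
            params.update(search.best_params_)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)  # SVC(probability=True) deprecation
            svc = SVC(probability=True, random_state=0, **params).fit(Str, y[tr])
        p_tr = svc.predict_proba(Str)[:, 1]
        p_te = svc.predict_proba(Ste)[:, 1]
        heldout[te] = p_te
        auc_train.append(float(roc_auc_score(y[tr], p_tr)))
        auc_test.append(float(roc_auc_score(y[te], p_te)))
        fold_models.append(_FoldModel(med, scaler, svc))
    model = TrainedModel(
        feature_names=list(feature_names),
        selected_mask=np.asarray(mask, dtype=bool),
        fold_models=fold_models,
        registry_version=registry_version,
        fold_auc_train=auc_train,
        fold_auc_test=auc_test,
    )
    return model, heldout


def predict_site_matrix(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Mean of the five calibrated fold probabilities for each row."""
    Xm = X[:, model.selected_mask]
    probs = np.zeros((len(Xm), len(model.fold_models)))
    for k, fm in enumerate(model.fold_models):
        Xi = fm.scaler.transform(_impute(Xm, fm.medians))
        probs[:, k] = fm.svc.predict_proba(Xi)[:, 1]
    return probs.mean(axis=1)


def aggregate_transcript(sites: list[SitePrediction]) -> TranscriptPrediction:
    """Noisy-OR combination of a transcript's independent site probabilities."""
    if not sites:
        raise ValueError("no sites to aggregate")
    miss = 1.0
    for s in sites:
        if not 0.0 <= s.p_site <= 1.0:
            raise ValueError("site probability outside [0, 1]")
        miss *= 1.0 - s.p_site
    P = 1.0 - miss
    first = sites[0]
    return TranscriptPrediction(
        trf_id=first.trf_id,
        transcript_id=first.transcript_id,
        n_sites=len(sites),
        P=float(P),
        is_target=P > 0.5,
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate(cm: ConfusionMatrix) -> EvaluationMetrics:
    """Sensitivity, specificity and Matthews correlation coefficient.

    Any zero denominator yields NaN for that metric rather than an error.
    """
    sens = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else math.nan
    spec = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP else math.nan
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(denom) if denom else math.nan
    return EvaluationMetrics(sens, spec, mcc)


def compare_feature_distributions(
    positives: pd.DataFrame,
    background: pd.DataFrame,
    registry: FeatureRegistry | None = None,
) -> pd.DataFrame:
    """Two-sided Student's t-test per feature, positives vs background.

    Output is sorted by feature family (category) then registry order;
    zero-pooled-variance features get a NaN p-value.
    """
    registry = registry or default_registry()
    rows = []
    for name in registry.names:
        if name not in positives.columns:
            continue
        a = positives[name].dropna().to_numpy()
        b = background[name].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            t, p = math.nan, math.nan
        else:
            import warnings

            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=True)
            if not np.isfinite(t):
                t, p = math.nan, math.nan
        rows.append(
            {
                "feature": name,
                "category": registry.family(name),
                "mean_positive": float(np.mean(a)) if len(a) else math.nan,
                "mean_background": float(np.mean(b)) if len(b) else math.nan,
                "t": float(t) if t == t else math.nan,
                "p_value": float(p) if p == p else math.nan,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["category", "feature"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model / Results objects


class TargetSiteClassifier:
    """SVM-GA site classifier bound to a feature matrix and labels.

    Parameters
    ----------
    X : pandas.DataFrame
        Feature matrix from :func:`trftarget.features.assemble_feature_matrix`
        (rows indexed by (trf_id, transcript_id, start, end)).
    y : array-like of {0, 1}
        1 for positive (chimera-supported) pairs, 0 for negatives.
    registry : FeatureRegistry, optional
    k_folds, rng_seed : fold construction (stratified, deterministic).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        registry: FeatureRegistry | None = None,
        k_folds: int = 5,
        rng_seed: int = 0,
    ) -> None:
        self.X = X
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        self.registry = registry or default_registry()
        self.k_folds = k_folds
        self.rng_seed = rng_seed
        self.fold_assignment = make_folds(self.y, k=k_folds, rng_seed=rng_seed)

    @classmethod
    def from_pairs(
        cls,
        positives: list[InteractionPair],
        negatives: list[InteractionPair],
        trfs,
        transcripts,
        model=None,
        registry: FeatureRegistry | None = None,
        **kwargs,
    ) -> "TargetSiteClassifier":
        from .features import assemble_feature_matrix

        pairs = list(positives) + list(negatives)
        X = assemble_feature_matrix(pairs, trfs, transcripts, model=model, registry=registry)
        labels = [1] * len(positives) + [0] * len(negatives)
        # rows can be dropped during assembly; realign labels by pair key
        label_by_key = {p.key: l for p, l in zip(pairs, labels)}
        y = [label_by_key[k] for k in X.index]
        return cls(X, y, registry=registry, **kwargs)

    def fit(
        self,
        ga: GaConfig | None = None,
        svm_params: dict | None = None,
        param_grid: dict | None = None,
    ) -> "TargetSiteClassifierResults":
        """GA feature selection (optional) then per-fold SVM training."""
        Xv = self.X.to_numpy(dtype=float)
        if ga is not None:
            mask, ga_fitness = ga_select_features(
                Xv, self.y, self.fold_assignment, ga, svm_params
            )
        else:
            mask, ga_fitness = np.ones(Xv.shape[1], dtype=bool), math.nan
        model, heldout = train_cv_svm(
            Xv,
            self.y,
            self.fold_assignment,
            mask,
            feature_names=list(self.X.columns),
            registry_version=self.registry.version,
            svm_params=svm_params,
            param_grid=param_grid,
        )
        return TargetSiteClassifierResults(self, model, heldout, ga_fitness)


class TargetSiteClassifierResults:
    """Fitted SVM-GA classifier: mask, fold models, AUCs, predictions."""

    def __init__(
        self,
        model_spec: TargetSiteClassifier,
        trained: TrainedModel,
        heldout_probs: np.ndarray,
        ga_fitness: float,
    ) -> None:
        self.model = model_spec
        self.trained = trained
        self.heldout_probs = heldout_probs
        self.ga_fitness = ga_fitness

    @property
    def selected_features(self) -> list[str]:
        return [n for n, m in zip(self.trained.feature_names, self.trained.selected_mask) if m]

    @property
    def heldout_auc(self) -> float:
        return float(roc_auc_score(self.model.y, self.heldout_probs))

    def predict_sites(self, X: pd.DataFrame) -> list[SitePrediction]:
        probs = predict_site_matrix(self.trained, X.to_numpy(dtype=float))
        out = []
        for (trf_id, transcript_id, start, end), p in zip(X.index, probs):
            out.append(SitePrediction(trf_id, transcript_id, start, end, float(p)))
        return out

    def predict_transcripts(self, X: pd.DataFrame) -> list[TranscriptPrediction]:
        sites = self.predict_sites(X)
        grouped: dict[tuple[str, str], list[SitePrediction]] = {}
        for s in sites:
            grouped.setdefault((s.trf_id, s.transcript_id), []).append(s)
        return [aggregate_transcript(v) for v in grouped.values()]

    def save(self, path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        t = self.trained
        lines = [
            "SVM-GA target site classifier",
            "=" * 46,
            f"observations:        {len(self.model.y)}",
            f"positives:           {int(self.model.y.sum())}",
            f"features (registry): {len(t.feature_names)}",
            f"features (selected): {int(t.selected_mask.sum())}",
            f"folds:               {self.model.k_folds}",
            f"GA fitness (CV AUC): {self.ga_fitness:.4f}"
            if self.ga_fitness == self.ga_fitness
            else "GA:                  not used",
            "-" * 46,
            "fold   AUC(train)   AUC(held-out)",
        ]
        for k, (a, b) in enumerate(zip(t.fold_auc_train, t.fold_auc_test), start=1):
            lines.append(f"{k:>4}   {a:10.4f}   {b:13.4f}")
        lines.append("-" * 46)
        lines.append(f"pooled held-out AUC: {self.heldout_auc:.4f}")
        return "\n".join(lines)
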