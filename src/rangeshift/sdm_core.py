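"""The SDM engine: pseudo-absences, member fitting, evaluation, ensembling.

One species' model is an ensemble of members, one per (algorithm ×
pseudo-absence round × cross-validation repetition).  Pseudo-absences are
drawn in three independent rounds — 1000 background cells per round, or as
many as there are presences once a species has ≥1000 records.  Each member
is trained on a stratified random 70% of its round's table and evaluated on
the held-out 30% (AUC, and TSS at the hold-out's max sens+spec threshold).
Members with TSS > 0.6 or AUC > 0.8 enter the ensemble; the ensemble HSI is
their TSS-weighted mean prediction, a convex combination in [0, 1].

Variable screening works the same way practitioners use biomod2: an initial
model on the full stack yields permutation importance scores (1 − the
correlation between predictions before and after shuffling one predictor),
then collinear pairs (|r| > 0.7, Pearson when both columns look normal,
Spearman otherwise) are resolved by dropping the lower-importance variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .geo_raster import RasterGrid
from .occurrences import OccurrenceSet
from .predictors import PredictorStack
from .seeding import derive_seed

log = logging.getLogger(__name__)

DEFAULT_GATE_TSS = 0.6
DEFAULT_GATE_AUC = 0.8
DEFAULT_R_THRESHOLD = 0.7


class SdmError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Learner families
# ---------------------------------------------------------------------------

def _make_glm(seed: int):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0, max_iter=1000, random_state=seed),
    )


def _make_rf(seed: int):
    return RandomForestClassifier(
        n_estimators=80, min_samples_leaf=3, n_jobs=1, random_state=seed
    )


def _make_gbm(seed: int):
    return LGBMClassifier(
        n_estimators=80, num_leaves=15, learning_rate=0.1,
        n_jobs=1, random_state=seed, verbose=-1,
    )


#: pluggable learner registry: id -> factory(seed) -> sklearn classifier
ALGORITHMS = {"glm": _make_glm, "rf": _make_rf, "gbm": _make_gbm}
DEFAULT_ALGORITHMS = ["glm", "rf", "gbm"]


# ---------------------------------------------------------------------------
# Training table
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Presences + pseudo-absences with features, by PA round.

    ``cell_index`` are flat indices into the predictor grid; ``response``
    is 1 for presence, 0 for pseudo-absence; presences are shared across
    rounds, pseudo-absences differ per round.
    """

    feature_names: list[str]
    cell_index: np.ndarray
    features: np.ndarray
    response: np.ndarray
    pa_round: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cell_index)
        if not (self.features.shape == (n, len(self.feature_names))
                and len(self.response) == n and len(self.pa_round) == n
                and len(self.weight) == n):
            raise SdmError("inconsistent training-table shapes")
        if not np.isfinite(self.features).all():
            raise SdmError("non-finite features in training table")

    @property
    def n_rounds(self) -> int:
        return int(self.pa_round.max())

    def round_subset(self, pa_round: int) -> "TrainingTable":
        sel = self.pa_round == pa_round
        return TrainingTable(
            feature_names=self.feature_names,
            cell_index=self.cell_index[sel],
            features=self.features[sel],
            response=self.response[sel],
            pa_round=self.pa_round[sel],
            weight=self.weight[sel],
        )

    def subset_features(self, names: list[str]) -> "TrainingTable":
        cols = [self.feature_names.index(n) for n in names]
        return TrainingTable(
            feature_names=list(names),
            cell_index=self.cell_index,
            features=self.features[:, cols],
            response=self.response,
            pa_round=self.pa_round,
            weight=self.weight,
        )


def presence_cells(occ: OccurrenceSet, stack: PredictorStack) -> np.ndarray:
    """Unique, unmasked flat cell indices occupied by the species."""
    pts = occ.lonlat()
    if len(pts) == 0:
        raise SdmError(f"no occurrence records for {occ.species}")
    row, col = stack.grid.cell_of(pts[:, 0], pts[:, 1])
    ok = (row >= 0) & (col >= 0)
    flat = np.unique(row[ok] * stack.grid.n_cols + col[ok])
    mask = stack.combined_mask().ravel()
    return flat[~mask[flat]]


def pseudo_absence_count(n_presences: int, floor: int = 1000) -> int:
    """The background-sample size rule: 1000 below 1000 presences, else
    one pseudo-absence per presence."""
    return floor if n_presences < floor else n_presences


def generate_pseudo_absences(occ: OccurrenceSet, stack: PredictorStack,
                             n_rounds: int = 3, seed: int = 0) -> TrainingTable:
    """Build the training table: presences + ``n_rounds`` independent
    random background draws from unmasked non-presence cells."""
    pres = presence_cells(occ, stack)
    if len(pres) == 0:
        raise SdmError(f"no presence cells on the grid for {occ.species}")
    land = stack.land_indices()
    eligible = np.setdiff1d(land, pres, assume_unique=True)
    n_pa = pseudo_absence_count(len(pres))
    if len(eligible) < n_pa:
        raise SdmError(
            f"only {len(eligible)} eligible background cells for {n_pa} "
            f"pseudo-absences ({occ.species})"
        )
    cell_idx: list[np.ndarray] = []
    resp: list[np.ndarray] = []
    rounds: list[np.ndarray] = []
    for rnd in range(1, n_rounds + 1):
        rng = np.random.default_rng(derive_seed(seed, "pa", occ.species, rnd))
        pa = rng.choice(eligible, size=n_pa, replace=False)
        cell_idx.append(np.concatenate([pres, pa]))
        resp.append(np.concatenate([np.ones(len(pres)), np.zeros(n_pa)]))
        rounds.append(np.full(len(pres) + n_pa, rnd))
    cells = np.concatenate(cell_idx)
    response = np.concatenate(resp).astype(int)
    pa_round = np.concatenate(rounds).astype(int)
    # class-balancing weights: presences and pseudo-absences contribute
    # equally within each round
    weight = np.where(response == 1, n_pa / len(pres), 1.0)
    return TrainingTable(
        feature_names=stack.names,
        cell_index=cells,
        features=stack.feature_matrix(cells),
        response=response,
        pa_round=pa_round,
        weight=weight,
    )


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def auc(scores_presence, scores_absence) -> float:
    """Rank-based AUC: P(random presence outscores random absence), ties ½.

    The Mann–Whitney U form via midranks, exact including ties.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if len(sp) == 0 or len(sa) == 0:
        raise SdmError("auc requires non-empty presence and absence scores")
    ranks = stats.rankdata(np.concatenate([sp, sa]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sa)))


@dataclass(frozen=True)
class EvalScores:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    eval_threshold: float


def tss_at_threshold(scores_p, scores_a, threshold: float) -> EvalScores:
    """Sensitivity/specificity/TSS at one cut: presences count as predicted
    present when score > threshold, absences as predicted absent when
    score <= threshold."""
    sp = np.asarray(scores_p, dtype=float)
    sa = np.asarray(scores_a, dtype=float)
    if len(sp) == 0 or len(sa) == 0:
        raise SdmError("tss requires non-empty presence and absence scores")
    sens = float((sp > threshold).mean())
    spec = float((sa <= threshold).mean())
    return EvalScores(
        auc=auc(sp, sa), tss=sens + spec - 1.0,
        sensitivity=sens, specificity=spec, eval_threshold=float(threshold),
    )


def _sss_candidates(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    lo = min(0.0, float(uniq[0]) - 1e-9)
    hi = max(1.0, float(uniq[-1]))
    return np.unique(np.concatenate([[lo], mids, [hi]]))


def best_sss_threshold(scores_p, scores_a) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between consecutive sorted unique scores
    plus the extremes 0 and 1; ties are broken by the smallest optimal
    threshold, making the result exactly reproducible.
    """
    sp = np.asarray(scores_p, dtype=float)
    sa = np.asarray(scores_a, dtype=float)
    if len(sp) == 0 or len(sa) == 0:
        raise SdmError("threshold selection requires both classes")
    cands = _sss_candidates(np.concatenate([sp, sa]))
    sens = (sp[None, :] > cands[:, None]).mean(axis=1)
    spec = (sa[None, :] <= cands[:, None]).mean(axis=1)
    sss = sens + spec
    best = np.flatnonzero(sss == sss.max())[0]  # smallest optimal threshold
    return float(cands[best])


def evaluate_member(scores_p, scores_a) -> EvalScores:
    """Hold-out evaluation at the max sens+spec threshold."""
    thr = best_sss_threshold(scores_p, scores_a)
    return tss_at_threshold(scores_p, scores_a, thr)


# ---------------------------------------------------------------------------
# Member fitting
# ---------------------------------------------------------------------------

@dataclass
class SdmMember:
    algorithm_id: str
    pa_round: int
    cv_rep: int
    fitted_model: object
    eval: EvalScores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability scores in [0, 1] (positive-class probability)."""
        return _predict_proba1(self.fitted_model, X)


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = max(1, int(round(train_frac * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train[idx[:n_train]] = True
    return train


def fit_members(tt: TrainingTable, algorithms: list[str] | None = None,
                n_cv: int = 5, train_frac: float = 0.7,
                seed: int = 0) -> list[SdmMember]:
    """Fit one member per (algorithm × PA round × CV repetition).

    Each repetition draws a stratified random 70/30 split of that round's
    table; the member is trained with class-balancing sample weights on the
    70% and evaluated (AUC, max-SSS TSS) on the 30% hold-out.
    """
    algorithms = algorithms if algorithms is not None else DEFAULT_ALGORITHMS
    members: list[SdmMember] = []
    for rnd in range(1, tt.n_rounds + 1):
        sub = tt.round_subset(rnd)
        if len(np.unique(sub.response)) < 2:
            raise SdmError(f"PA round {rnd} lacks both classes")
        for rep in range(1, n_cv + 1):
            split_seed = derive_seed(seed, "split", rnd, rep)
            rng = np.random.default_rng(split_seed)
            for _attempt in range(10):
                train = _stratified_split(sub.response, train_frac, rng)
                hold = ~train
                if len(np.unique(sub.response[hold])) == 2:
                    break
                log.warning("degenerate hold-out, re-drawing split")
            else:
                raise SdmError("could not draw a two-class hold-out split")
            for algo in algorithms:
                model = ALGORITHMS[algo](derive_seed(seed, "fit", algo, rnd, rep))
                model.fit(sub.features[train], sub.response[train],
                          **_weight_kw(model, sub.weight[train]))
                scores = _predict_proba1(model, sub.features[hold])
                ev = evaluate_member(scores[sub.response[hold] == 1],
                                     scores[sub.response[hold] == 0])
                members.append(SdmMember(
                    algorithm_id=algo, pa_round=rnd, cv_rep=rep,
                    fitted_model=model, eval=ev,
                ))
    return members


def _weight_kw(model, w: np.ndarray) -> dict:
    if hasattr(model, "steps"):  # sklearn Pipeline
        final = model.steps[-1][0]
        return {f"{final}__sample_weight": w}
    return {"sample_weight": w}


def _predict_proba1(model, X: np.ndarray) -> np.ndarray:
    import warnings
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper records auto-generated feature names
        # at fit and sklearn warns when predicting from plain arrays;
        # feature order is fixed by the TrainingTable contract
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names")
        proba = model.predict_proba(X)
    cls = list(model.classes_)
    return proba[:, cls.index(1)]


def members_table(members: list[SdmMember]) -> pd.DataFrame:
    return pd.DataFrame([
        {"algorithm": m.algorithm_id, "pa_round": m.pa_round, "cv_rep": m.cv_rep,
         "auc": m.eval.auc, "tss": m.eval.tss,
         "sensitivity": m.eval.sensitivity, "specificity": m.eval.specificity,
         "eval_threshold": m.eval.eval_threshold}
        for m in members
    ])


# ---------------------------------------------------------------------------
# Permutation importance and collinearity pruning
# ---------------------------------------------------------------------------

def permutation_importance(member: SdmMember, table: TrainingTable,
                           n_shuffles: int = 1, seed: int = 0) -> pd.Series:
    """Importance of each predictor to one member.

    IS = 1 − Pearson correlation between the member's predictions on the
    original table and on the table with that one column shuffled, averaged
    over ``n_shuffles`` seeded shuffles.  An unused predictor leaves the
    predictions unchanged (correlation 1, IS 0); the theoretical upper
    bound is 2 (perfect anticorrelation).  Zero-variance prediction vectors
    give IS 0 for that shuffle (flagged in the log).
    """
    base = member.predict(table.features)
    scores = np.zeros(len(table.feature_names))
    for j, name in enumerate(table.feature_names):
        vals = []
        for k in range(n_shuffles):
            rng = np.random.default_rng(derive_seed(seed, "shuffle", name, k))
            X = table.features.copy()
            X[:, j] = rng.permutation(X[:, j])
            pred = member.predict(X)
            if np.std(pred) == 0 or np.std(base) == 0:
                log.warning("zero-variance predictions for %s; IS set to 0", name)
                vals.append(0.0)
            else:
                vals.append(1.0 - float(np.corrcoef(base, pred)[0, 1]))
        scores[j] = np.mean(vals)
    return pd.Series(scores, index=table.feature_names, name="is_score")


def aggregate_importance(members: list[SdmMember], table: TrainingTable,
                         n_shuffles: int = 1, seed: int = 0) -> pd.DataFrame:
    """Mean IS over members, with ranks (1 = most important)."""
    total = None
    for i, m in enumerate(members):
        s = permutation_importance(m, table, n_shuffles=n_shuffles,
                                   seed=derive_seed(seed, "member", i))
        total = s if total is None else total + s
    mean = total / len(members)
    out = pd.DataFrame({"is_score": mean})
    out["rank"] = out["is_score"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank")


def _pair_correlation(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> float:
    """Pearson r when both columns pass Shapiro–Wilk normality at alpha,
    Spearman otherwise.  Columns are subsampled to 5000 for the test."""
    def normal(v: np.ndarray) -> bool:
        v = v[:5000]
        if np.std(v) == 0:
            return False
        return stats.shapiro(v).pvalue > alpha
    if normal(x) and normal(y):
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def prune_collinear(table: TrainingTable, importance: pd.DataFrame,
                    r_threshold: float = DEFAULT_R_THRESHOLD) -> list[str]:
    """Greedy collinearity pruning.

    While any retained pair exceeds |r| > r_threshold, drop the lower-IS
    member of the worst-offending pair (pairs ordered by |r| descending,
    ties by name).  Constant columns are dropped up front (undefined r).
    The returned set is audited: no remaining pair exceeds the threshold.
    """
    names = list(table.feature_names)
    X = {n: table.features[:, i] for i, n in enumerate(names)}
    retained = []
    for n in names:
        if np.std(X[n]) == 0:
            log.warning("dropping constant predictor %s", n)
        else:
            retained.append(n)
    corr = {}
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            corr[(a, b)] = abs(_pair_correlation(X[a], X[b]))
    while True:
        offending = [(r, pair) for pair, r in corr.items()
                     if r > r_threshold and pair[0] in retained and pair[1] in retained]
        if not offending:
            break
        offending.sort(key=lambda t: (-t[0], t[1]))
        _, (a, b) = offending[0]
        drop = a if importance.loc[a, "is_score"] <= importance.loc[b, "is_score"] else b
        retained.remove(drop)
    for i, a in enumerate(retained):  # post-condition audit
        for b in retained[i + 1:]:
            assert corr[(a, b)] <= r_threshold
    return retained


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    species: str
    scenario_id: str
    hsi: RasterGrid
    members_used: list[SdmMember]
    weights: np.ndarray


def gate_members(members: list[SdmMember], gate_tss: float = DEFAULT_GATE_TSS,
                 gate_auc: float = DEFAULT_GATE_AUC) -> list[SdmMember]:
    """Members entering the ensemble: TSS > gate_tss OR AUC > gate_auc."""
    return [m for m in members
            if m.eval.tss > gate_tss or m.eval.auc > gate_auc]


def build_ensemble(members: list[SdmMember], stack: PredictorStack,
                   species: str = "", gate_tss: float = DEFAULT_GATE_TSS,
                   gate_auc: float = DEFAULT_GATE_AUC,
                   feature_names: list[str] | None = None) -> EnsembleResult:
    """Project the gated, TSS-weighted ensemble HSI onto a scenario stack.

    Weights are proportional to max(TSS, 0), normalised to sum to 1 (equal
    weights if every passing member has non-positive TSS).  The HSI is a
    convex combination of member predictions, hence in [0, 1].
    """
    passing = gate_members(members, gate_tss, gate_auc)
    if not passing:
        raise SdmError(
            f"no ensemble member passed the gate (TSS>{gate_tss} or "
            f"AUC>{gate_auc}) for species {species!r}"
        )
    w = np.array([max(m.eval.tss, 0.0) for m in passing])
    w = np.full(len(passing), 1.0 / len(passing)) if w.sum() == 0 else w / w.sum()

    names = feature_names if feature_names is not None else stack.names
    land = stack.land_indices()
    X = stack.feature_matrix(land, names)
    hsi_flat = np.zeros(len(land))
    for wi, m in zip(w, passing):
        hsi_flat += wi * m.predict(X)
    vals = np.full(stack.grid.shape, np.nan).ravel()
    vals[land] = hsi_flat
    hsi = RasterGrid(grid=stack.grid, values=vals.reshape(stack.grid.shape),
                     nodata_mask=stack.combined_mask().copy(),
                     name=f"hsi_{species}_{stack.scenario_id}")
    return EnsembleResult(species=species, scenario_id=stack.scenario_id,
                          hsi=hsi, members_used=passing, weights=w)


def ensemble_scores_at(result: EnsembleResult, cell_index: np.ndarray) -> np.ndarray:
    """Ensemble HSI values at flat cell indices (for thresholding)."""
    return result.hsi.values.ravel()[cell_index]
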