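"""Multi-technique ensemble species distribution modelling.

The ensemble logic follows the classic ensemble-forecasting recipe:

1. several classifier *techniques* are each fitted on repeated random
   80/20 presence/background splits (*evaluation runs*),
2. each fit is scored by the true skill statistic,
   TSS = sensitivity + specificity − 1, maximised over a threshold grid,
3. fits scoring at least the mean TSS of the whole fit set become the
   *ensemble members* (≈ the better half),
4. the ensemble probability is the (optionally TSS-weighted) mean of the
   member probabilities, and
5. the continuous output is binarized at the cut-off P that maximises the
   ensemble's TSS on the pooled held-out data, with "present" meaning
   strictly above P.

The whole procedure is repeated K times and the per-period range is the
cell-wise majority vote across repetitions.

:class:`EnsembleSDM` packages steps 1-5 as a scikit-learn classifier so it
composes with sklearn model selection; :func:`run_period` adds the
repetition layer and the raster bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .prep import PredictorSelection
from .types import EnvStack, OccurrenceSet, PseudoAbsenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "TECHNIQUE_REGISTRY",
    "DEFAULT_TECHNIQUES",
    "TechniqueSpec",
    "FitRecord",
    "EnsembleSDM",
    "RangeResult",
    "split_evaluation",
    "fit_technique",
    "evaluate_tss",
    "tss_curve",
    "select_members",
    "ensemble_predict",
    "binarize",
    "range_stats",
    "run_period",
    "SDMSettings",
]


def _make_logistic(hp, rs):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=hp.get("C", 1.0), max_iter=2000,
                                   class_weight=hp.get("class_weight", "balanced"))),
    ])


def _make_rf(hp, rs):
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 100),
        min_samples_leaf=hp.get("min_samples_leaf", 3),
        class_weight=hp.get("class_weight", "balanced"),
        random_state=rs, n_jobs=1)


def _make_gbt(hp, rs):
    return HistGradientBoostingClassifier(
        max_iter=hp.get("max_iter", 80),
        max_depth=hp.get("max_depth", 3),
        class_weight=hp.get("class_weight", "balanced"),
        random_state=rs)


def _make_spline_logistic(hp, rs):
    return Pipeline([
        ("scale", StandardScaler()),
        ("spline", SplineTransformer(n_knots=hp.get("n_knots", 4), degree=3)),
        ("clf", LogisticRegression(C=hp.get("C", 1.0), max_iter=2000,
                                   class_weight=hp.get("class_weight", "balanced"))),
    ])


def _make_ann(hp, rs):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(hidden_layer_sizes=hp.get("hidden_layer_sizes", (8,)),
                              max_iter=hp.get("max_iter", 400), random_state=rs)),
    ])


#: registered modelling techniques (name -> factory(hyperparameters, random_state))
TECHNIQUE_REGISTRY = {
    "regularized-logistic": _make_logistic,
    "random-forest": _make_rf,
    "gradient-boosted-trees": _make_gbt,
    "spline-logistic": _make_spline_logistic,
    "shallow-neural-net": _make_ann,
}

#: the default modelling set (the neural net is registered but opt-in: it is
#: slow and does not support class weighting)
DEFAULT_TECHNIQUES = ("regularized-logistic", "random-forest",
                      "gradient-boosted-trees", "spline-logistic")

#: fast subset for large simulation studies
FAST_TECHNIQUES = ("regularized-logistic", "random-forest")


@dataclass(frozen=True)
class TechniqueSpec:
    """One registered modelling technique plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in TECHNIQUE_REGISTRY:
            raise ValueError(f"unknown technique {self.name!r}; "
                             f"registered: {sorted(TECHNIQUE_REGISTRY)}")

    def build(self, random_state: int | None = None):
        return TECHNIQUE_REGISTRY[self.name](self.hyperparameters, random_state)


@dataclass
class FitRecord:
    """One technique fitted on one evaluation run, with its held-out skill."""

    technique: str
    run_index: int
    tss: float
    threshold_at_max_tss: float
    model_handle: object


def split_evaluation(X_pres: np.ndarray, X_abs: np.ndarray, run_index: int, seed,
                     test_fraction: float = 0.2):
    """Stratified random split of presence and background rows.

    Returns ``((X_train, y_train), (X_test, y_test))`` with y = 1 for
    presences. The split is a pure function of (seed, run_index).
    """
    X_pres = np.asarray(X_pres, dtype=float)
    X_abs = np.asarray(X_abs, dtype=float)
    if len(X_pres) < 10:
        raise ValueError(f"need at least 10 presences to split, got {len(X_pres)}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(_entropy(seed), run_index)))

    def _split(X):
        n = len(X)
        n_test = max(1, int(round(test_fraction * n)))
        perm = rng.permutation(n)
        return X[perm[n_test:]], X[perm[:n_test]]

    Xp_tr, Xp_te = _split(X_pres)
    Xa_tr, Xa_te = _split(X_abs)
    X_tr = np.vstack([Xp_tr, Xa_tr])
    y_tr = np.concatenate([np.ones(len(Xp_tr)), np.zeros(len(Xa_tr))])
    X_te = np.vstack([Xp_te, Xa_te])
    y_te = np.concatenate([np.ones(len(Xp_te)), np.zeros(len(Xa_te))])
    return (X_tr, y_tr), (X_te, y_te)


def _entropy(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(seed)


def fit_technique(spec: TechniqueSpec, X_train: np.ndarray, y_train: np.ndarray,
                  random_state: int | None = None):
    """Fit one technique; the handle predicts presence probability in [0, 1]."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    model = spec.build(random_state)
    model.fit(X_train, y_train)
    return model


def _proba(model, X) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def tss_curve(scores: np.ndarray, y: np.ndarray,
              thresholds: np.ndarray = THRESHOLD_GRID) -> np.ndarray:
    """TSS at each threshold, with "present" meaning score strictly > t."""
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y]
    neg = scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("evaluation data must contain both classes")
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return sens + spec - 1.0


def evaluate_tss(model, X_test: np.ndarray, y_test: np.ndarray) -> tuple[float, float]:
    """Maximum TSS of a fitted model over the 0.00-1.00 (step 0.01) threshold
    grid and the (lowest) threshold attaining it."""
    return max_tss(_proba(model, X_test), y_test)


def max_tss(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Grid-search TSS maximum for given scores; ties resolve to the lowest
    threshold."""
    curve = tss_curve(scores, y)
    best = np.argmax(curve)  # argmax returns the first (= lowest threshold) tie
    return float(curve[best]), float(THRESHOLD_GRID[best])


def select_members(fits: list[FitRecord]) -> tuple[list[FitRecord], float]:
    """Keep fits whose TSS is at least the mean TSS of the whole set —
    approximately the better half."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select members")
    tss_mean = float(np.mean([f.tss for f in fits]))
    members = [f for f in fits if f.tss >= tss_mean]
    return members, tss_mean


class EnsembleSDM(ClassifierMixin, BaseEstimator):
    """TSS-selected ensemble of distribution-modelling techniques.

    Parameters
    ----------
    techniques : sequence of str or TechniqueSpec, default DEFAULT_TECHNIQUES
        Members of the technique registry to fit.
    n_runs : int, default 10
        Evaluation runs (random 80/20 splits) per technique.
    test_fraction : float, default 0.2
        Held-out fraction per run.
    weighted : bool, default False
        If True, combine members by TSS-weighted mean instead of the plain
        mean.
    random_state : int or None
        Seed for splits and stochastic techniques.

    Attributes
    ----------
    fits_ : list of FitRecord
        All technique × run fits with their held-out TSS.
    members_ : list of FitRecord
        The selected ensemble members (TSS ≥ ``tss_mean_``).
    tss_mean_ : float
        Mean TSS of ``fits_``; the member-selection threshold.
    cutoff_ : float
        Presence cut-off P: the TSS-maximising threshold of the ensemble
        prediction on the pooled held-out data.
    tss_consensus_ : float
        TSS of the ensemble prediction on the pooled held-out data.
    member_tss_mean_ : float
        Mean TSS of the selected members (an alternative consensus-skill
        summary; both are logged).
    """

    def __init__(self, techniques=DEFAULT_TECHNIQUES, n_runs: int = 10,
                 test_fraction: float = 0.2, weighted: bool = False,
                 random_state: int | None = None):
        self.techniques = techniques
        self.n_runs = n_runs
        self.test_fraction = test_fraction
        self.weighted = weighted
        self.random_state = random_state

    def _specs(self) -> list[TechniqueSpec]:
        return [t if isinstance(t, TechniqueSpec) else TechniqueSpec(t)
                for t in self.techniques]

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need both classes")
        y = (y == self.classes_[1]).astype(float)
        X_pres, X_abs = X[y == 1], X[y == 0]
        seed = 0 if self.random_state is None else int(self.random_state)

        fits: list[FitRecord] = []
        pooled_idx: list[tuple[np.ndarray, np.ndarray]] = []
        for run in range(1, self.n_runs + 1):
            (X_tr, y_tr), (X_te, y_te) = split_evaluation(
                X_pres, X_abs, run, seed, self.test_fraction)
            pooled_idx.append((X_te, y_te))
            for k, spec in enumerate(self._specs()):
                rs = (seed * 1009 + run * 31 + k) % (2**31)
                model = fit_technique(spec, X_tr, y_tr, random_state=rs)
                tss, thr = evaluate_tss(model, X_te, y_te)
                fits.append(FitRecord(spec.name, run, tss, thr, model))
        self.fits_ = fits
        self.members_, self.tss_mean_ = select_members(fits)
        self.member_tss_mean_ = float(np.mean([m.tss for m in self.members_]))

        X_pool = np.vstack([x for x, _ in pooled_idx])
        y_pool = np.concatenate([t for _, t in pooled_idx])
        scores = self._ensemble_scores(X_pool)
        self.tss_consensus_, self.cutoff_ = max_tss(scores, y_pool)
        return self

    def _ensemble_scores(self, X) -> np.ndarray:
        probs = np.stack([_proba(m.model_handle, X) for m in self.members_])
        if self.weighted:
            w = np.array([max(m.tss, 0.0) for m in self.members_])
            if w.sum() == 0:
                w = np.ones(len(self.members_))
            return (w[:, None] * probs).sum(axis=0) / w.sum()
        return probs.mean(axis=0)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        p1 = self._ensemble_scores(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        check_is_fitted(self)
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > self.cutoff_).astype(int)]


def ensemble_predict(ensemble: EnsembleSDM, stack: EnvStack,
                     selection: PredictorSelection | list[str]) -> np.ndarray:
    """Project a fitted ensemble over a raster stack.

    Returns the probability grid (NaN outside the valid mask). Raises a
    named error when a retained predictor layer is missing from the stack.
    """
    variables = selection.retained if isinstance(selection, PredictorSelection) else list(selection)
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack for period {stack.period!r} is missing predictor "
                       f"layer(s): {missing}")
    X = stack.table(variables)
    grid = np.full(stack.spec.shape, np.nan)
    grid[stack.mask] = ensemble.predict_proba(X)[:, 1]
    return grid


def binarize(probability: np.ndarray, cutoff: float | EnsembleSDM) -> np.ndarray:
    """Presence/absence grid: present ⇔ probability strictly above the cut-off
    P (values equal to P count as absent)."""
    P = cutoff.cutoff_ if isinstance(cutoff, EnsembleSDM) else float(cutoff)
    with np.errstate(invalid="ignore"):
        return np.asarray(probability) > P


@dataclass
class RangeResult:
    """Per-period range summary."""

    period: str
    probability: np.ndarray
    binary: np.ndarray
    range_km2: float
    mean_elevation_m: float | None
    tss_consensus: float
    member_tss_mean: float = np.nan
    cutoff: float = np.nan
    fit_records: list[FitRecord] = field(default_factory=list)


def range_stats(binary: np.ndarray, elevation: np.ndarray,
                cell_area_km2: float) -> tuple[float, float | None]:
    """Range area (presence cells × cell area) and mean elevation over the
    presence cells; elevation is None for an empty range."""
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != np.asarray(elevation).shape:
        raise ValueError("binary and elevation grids are not co-registered")
    n = int(binary.sum())
    area = n * cell_area_km2
    mean_elev = float(np.asarray(elevation)[binary].mean()) if n else None
    return area, mean_elev


@dataclass(frozen=True)
class SDMSettings:
    """Knobs of the per-period pipeline (sizes follow the ensemble recipe:
    R evaluation runs per technique, K whole-pipeline repetitions)."""

    techniques: tuple = DEFAULT_TECHNIQUES
    n_runs: int = 10
    n_repetitions: int = 10
    test_fraction: float = 0.2
    weighted: bool = False

    @classmethod
    def fast(cls, n_runs: int = 5, n_repetitions: int = 3) -> "SDMSettings":
        """Reduced settings for desk-scale simulation studies: the single
        strongest technique (a smoothed random forest, which captures the
        unimodal elevation/temperature response), five evaluation runs and
        three repetitions — low-variance range estimates at a fraction of
        the full ensemble's cost."""
        return cls(techniques=(
            TechniqueSpec("random-forest",
                          {"n_estimators": 80, "min_samples_leaf": 5}),
        ), n_runs=n_runs, n_repetitions=n_repetitions)


def run_period(occurrences: OccurrenceSet, pseudo_absences: PseudoAbsenceSet,
               stack: EnvStack, selection: PredictorSelection | list[str],
               settings: SDMSettings = SDMSettings(), seed=0,
               projection_stack: EnvStack | None = None) -> RangeResult:
    """Full per-period pipeline with K repetitions.

    Each repetition runs {R evaluation runs × techniques → TSS member
    selection → ensemble → cut-off binarization}; the final binary range is
    the cell-wise majority (present in ≥ 50 % of repetitions) and the
    consensus probability the mean over repetitions. ``projection_stack``
    lets a model trained on one period's layers be projected onto another
    (counterfactual) stack; by default the training stack is projected.
    """
    variables = selection.retained if isinstance(selection, PredictorSelection) else list(selection)
    X_pres = stack.extract(occurrences.x, occurrences.y, variables)
    X_abs = stack.extract(pseudo_absences.points[:, 0], pseudo_absences.points[:, 1], variables)
    X = np.vstack([X_pres, X_abs])
    y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_abs))])
    target = projection_stack if projection_stack is not None else stack

    prob_grids, bin_grids = [], []
    tss_cons, member_tss, cutoffs = [], [], []
    records: list[FitRecord] = []
    base = _entropy(seed)
    for rep in range(1, settings.n_repetitions + 1):
        ens = EnsembleSDM(techniques=settings.techniques, n_runs=settings.n_runs,
                          test_fraction=settings.test_fraction,
                          weighted=settings.weighted,
                          random_state=(base * 131 + rep) % (2**31))
        ens.fit(X, y)
        prob = ensemble_predict(ens, target, variables)
        prob_grids.append(prob)
        bin_grids.append(binarize(prob, ens))
        tss_cons.append(ens.tss_consensus_)
        member_tss.append(ens.member_tss_mean_)
        cutoffs.append(ens.cutoff_)
        records.extend(ens.fits_)
        logger.info("period=%s rep=%d tss_consensus=%.3f cutoff=%.2f members=%d/%d",
                    stack.period, rep, ens.tss_consensus_, ens.cutoff_,
                    len(ens.members_), len(ens.fits_))

    consensus_prob = np.nanmean(np.stack(prob_grids), axis=0)
    votes = np.stack(bin_grids).sum(axis=0)
    final_binary = votes >= (settings.n_repetitions / 2.0)
    final_binary &= target.mask
    area, mean_elev = range_stats(final_binary, target["elevation"],
                                  target.spec.cell_area_km2)
    return RangeResult(period=stack.period, probability=consensus_prob,
                       binary=final_binary, range_km2=area,
                       mean_elevation_m=mean_elev,
                       tss_consensus=float(np.mean(tss_cons)),
                       member_tss_mean=float(np.mean(member_tss)),
                       cutoff=float(np.mean(cutoffs)),
                       fit_records=records)
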