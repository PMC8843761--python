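"""Equal-sampling multiscale random-forest habitat model.

The model follows a two-step multiscale optimization.  Step one selects,
for every scalable covariate, the spatial scale at which a univariate
random forest discriminates presences from pseudo-absences with the lowest
out-of-bag (OOB) error; the modal best scale across the replicate
presence/pseudo-absence datasets becomes that covariate's scale.  Step two
screens the scale-optimized covariates for collinearity (|Pearson r| above
a threshold drops the less predictive member of the pair), then fits, for
each replicate dataset, a forest pruned by the Model Improvement Ratio
(MIR): permutation importances are normalized by their maximum, candidate
subsets are nominated at thresholds 0.0, 0.1, ..., 0.9 against the *full*
model's importances, and the subset model with the lowest OOB error wins.

Predictions of the ten per-replicate models (one per pseudo-absence set,
each trained on an exactly 1:1 class balance — "equal sampling") are
averaged into the habitat-suitability surface.

The public surface is statsmodels-like: build a
:class:`HabitatSelectionModel` from the data, call :meth:`fit`, and read
estimates and diagnostics off the returned :class:`HabitatSelectionResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .covariates import CovariateStack, split_layer_name
from .raster import RasterGrid

__all__ = [
    "ScaleProfile",
    "EnsembleMember",
    "HabitatSelectionModel",
    "HabitatSelectionResults",
    "univariate_scale_selection",
    "collinearity_screen",
    "mir_model_selection",
    "ensemble_predict",
    "evaluate_auc",
    "partial_dependence",
    "rank_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_TREES = 500
DEFAULT_COR_THRESHOLD = 0.85
DEFAULT_MIR_STEP = 0.1


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _fit_forest(X: np.ndarray, y: np.ndarray, trees: int, seed: int
                ) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=trees, oob_score=True, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-data OOB coverage warnings
        clf.fit(X, y)
    return clf


def _oob_error(clf: RandomForestClassifier) -> float:
    return 1.0 - float(clf.oob_score_)


def _check_balanced(y: np.ndarray) -> None:
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 != n0:
        raise ValueError(
            f"equal-sampling contract violated: {n1} presences vs {n0} "
            "pseudo-absences")


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability that a presence outranks a pseudo-absence
    (Mann-Whitney statistic scaled to [0, 1]; ties share ranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the validation fold")
    r = rankdata(scores)
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ----------------------------------------------------------------------
# step 1: univariate scale optimization
# ----------------------------------------------------------------------
@dataclass
class ScaleProfile:
    """Per-variable scale optimization result.

    ``oob_errors``: tidy frame (dataset, variable, scale, oob_error).
    ``chosen``: variable -> modal best scale (m).
    ``frequency``: variable -> number of replicate datasets whose best
    scale equals the chosen scale.
    """

    oob_errors: pd.DataFrame
    chosen: dict[str, int]
    frequency: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "optimal_scale_m": s,
                 "selection_frequency": self.frequency[v]}
                for v, s in self.chosen.items()]
        return pd.DataFrame(rows)


def univariate_scale_selection(
    datasets: Sequence[pd.DataFrame],
    stack: CovariateStack,
    variables: Sequence[str] | None = None,
    trees: int = DEFAULT_TREES,
    seed: int = 0,
) -> ScaleProfile:
    """Choose each scalable variable's scale by univariate forest OOB error.

    For every replicate dataset and every available scale, a univariate
    forest is fit; each dataset votes for its lowest-OOB-error scale (ties
    broken toward the finest scale), and the modal scale across datasets
    wins (mode ties also break to the finest scale).
    """
    if len(datasets) == 0:
        raise ValueError("at least one presence/pseudo-absence dataset needed")
    var_scales = {v: s for v, s in stack.variables().items() if s}
    if variables is not None:
        missing = [v for v in variables if v not in var_scales]
        if missing:
            raise KeyError(f"variables missing from stack: {missing}")
        var_scales = {v: var_scales[v] for v in variables}

    rng = np.random.default_rng(seed)
    records = []
    votes: dict[str, list[int]] = {v: [] for v in var_scales}
    for d_idx, ds in enumerate(datasets, start=1):
        y = (ds["label"] == "presence").to_numpy().astype(int)
        _check_balanced(y)
        for var, scales in var_scales.items():
            errs = []
            for s in scales:
                layer = stack.layer_for(var, s)
                X = layer.sample(ds["x"].to_numpy(), ds["y"].to_numpy())
                X = np.nan_to_num(X, nan=np.nanmean(X)).reshape(-1, 1)
                clf = _fit_forest(X, y, trees, int(rng.integers(2 ** 31)))
                err = _oob_error(clf)
                errs.append(err)
                records.append({"dataset": d_idx, "variable": var,
                                "scale": s, "oob_error": err})
            best = scales[int(np.argmin(errs))]  # argmin: finest on ties
            votes[var].append(best)

    chosen: dict[str, int] = {}
    freq: dict[str, int] = {}
    for var, vs in votes.items():
        scales, counts = np.unique(vs, return_counts=True)
        top = counts.max()
        chosen[var] = int(scales[counts == top].min())  # finest modal scale
        freq[var] = int(top)
    return ScaleProfile(pd.DataFrame(records), chosen, freq)


# ----------------------------------------------------------------------
# collinearity screen
# ----------------------------------------------------------------------
def collinearity_screen(
    stack: CovariateStack,
    layer_names: Sequence[str],
    threshold: float = DEFAULT_COR_THRESHOLD,
    ranking: dict[str, float] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of every pair of layers with |Pearson r| > threshold.

    ``ranking`` maps layer name to a badness score (e.g. mean univariate OOB
    error); on a correlated pair the higher-scored (less predictive) layer
    is removed.  Without a ranking the later-listed layer is removed.
    Constant layers have undefined correlation and are retained with a
    warning.

    Returns (retained names, removals) where each removal is
    (removed, surviving partner, r).
    """
    names = list(layer_names)
    if len(names) < 2:
        return names, []
    tmpl = stack.template
    valid = np.ones(tmpl.shape, dtype=bool)
    for n in names:
        valid &= stack[n].mask
    data = {n: stack[n].values[valid] for n in names}

    constant = [n for n in names if np.nanstd(data[n]) == 0]
    for n in constant:
        warnings.warn(f"layer {n!r} is constant; correlation undefined, "
                      "retained")
    active = [n for n in names if n not in constant]
    removals: list[tuple[str, str, float]] = []

    def corr(a: str, b: str) -> float:
        return float(np.corrcoef(data[a], data[b])[0, 1])

    while True:
        worst: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r = corr(a, b)
                if abs(r) > threshold and (worst is None or abs(r) > abs(worst[0])):
                    worst = (r, a, b)
        if worst is None:
            break
        r, a, b = worst
        if ranking is not None:
            drop = a if ranking.get(a, 0.0) >= ranking.get(b, 0.0) else b
        else:
            drop = b
        keep = b if drop == a else a
        removals.append((drop, keep, r))
        active.remove(drop)

    retained = [n for n in names if n in active or n in constant]
    return retained, removals


# ----------------------------------------------------------------------
# step 2: MIR model selection
# ----------------------------------------------------------------------
@dataclass
class EnsembleMember:
    """One fitted forest of the equal-sampling ensemble."""

    forest: RandomForestClassifier
    variables: list[str]
    mir_table: pd.DataFrame
    oob_error: float
    training_means: pd.Series
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)


def mir_subsets(mir: pd.Series, step: float = DEFAULT_MIR_STEP
                ) -> dict[float, list[str]]:
    """Candidate variable subsets at MIR thresholds 0, step, ..., 1-step."""
    thresholds = np.round(np.arange(0.0, 1.0, step), 10)
    return {float(t): list(mir.index[mir >= t]) for t in thresholds}


def mir_model_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    trees: int = DEFAULT_TREES,
    mir_step: float = DEFAULT_MIR_STEP,
    seed: int = 0,
    importance_repeats: int = 5,
) -> EnsembleMember:
    """Fit the full forest, rank variables by MIR, and keep the
    lowest-OOB-error thresholded subset.

    MIR_i = permutation importance_i / max importance, computed once on the
    full model; subsets at thresholds 0.0, 0.1, ..., 0.9 are each refit and
    compared by OOB error (ties go to the smaller subset).
    """
    y = np.asarray(y).astype(int)
    _check_balanced(y)
    rng = np.random.default_rng(seed)
    full = _fit_forest(X.to_numpy(), y, trees, int(rng.integers(2 ** 31)))
    imp = permutation_importance(
        full, X.to_numpy(), y, n_repeats=importance_repeats,
        random_state=int(rng.integers(2 ** 31)), n_jobs=1)
    raw = pd.Series(imp.importances_mean, index=X.columns)
    max_imp = raw.max()
    if max_imp <= 0:
        raise ValueError("degenerate fit: no variable has positive "
                         "permutation importance")
    mir = (raw / max_imp).clip(lower=0.0)

    candidates = mir_subsets(mir, mir_step)
    best: tuple[float, int, float, list[str], RandomForestClassifier] | None = None
    tried: dict[tuple[str, ...], tuple[float, RandomForestClassifier]] = {}
    rows = []
    for t, subset in sorted(candidates.items()):
        if not subset:
            continue
        key = tuple(subset)
        if key in tried:
            err, clf = tried[key]
        else:
            clf = _fit_forest(X[subset].to_numpy(), y, trees,
                              int(rng.integers(2 ** 31)))
            err = _oob_error(clf)
            tried[key] = (err, clf)
        rows.append({"threshold": t, "n_variables": len(subset),
                     "oob_error": err})
        cand = (err, len(subset), t, subset, clf)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    assert best is not None
    err, _, t, subset, clf = best
    table = pd.DataFrame({"variable": X.columns, "importance": raw.values,
                          "mir": mir.values})
    table = table.sort_values("mir", ascending=False).reset_index(drop=True)
    logger.info("MIR selection: threshold %.1f, %d variables, OOB error %.4f",
                t, len(subset), err)
    return EnsembleMember(forest=clf, variables=list(subset),
                          mir_table=table, oob_error=err,
                          training_means=X.mean(), X=X, y=y)


# ----------------------------------------------------------------------
# ensemble prediction
# ----------------------------------------------------------------------
def ensemble_predict(members: Sequence[EnsembleMember],
                     stack: CovariateStack) -> RasterGrid:
    """Habitat suitability: per-cell mean over members of the fraction of
    trees voting presence."""
    if len(members) == 0:
        raise ValueError("empty ensemble")
    tmpl = stack.template
    needed = sorted({v for m in members for v in m.variables})
    for v in needed:
        if v not in stack:
            raise KeyError(f"covariate layer {v!r} missing from stack")
    valid = np.ones(tmpl.shape, dtype=bool)
    for v in needed:
        valid &= stack[v].mask
    cols = {v: stack[v].values[valid] for v in needed}
    out = np.zeros(int(valid.sum()))
    for m in members:
        X = np.column_stack([cols[v] for v in m.variables])
        proba = m.forest.predict_proba(X)
        idx = list(m.forest.classes_).index(1)
        out += proba[:, idx]
    out /= len(members)
    surface = np.full(tmpl.shape, np.nan)
    surface[valid] = out
    return tmpl.like(surface)


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------
def evaluate_auc(
    X_sets: Sequence[pd.DataFrame],
    y_sets: Sequence[np.ndarray],
    split: float = 0.7,
    reps: int = 10,
    trees: int = DEFAULT_TREES,
    seed: int = 0,
    variable_sets: Sequence[Sequence[str]] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of rank AUC over repeated 70/30 refits.

    Each repetition splits every replicate dataset into a stratified
    training fraction ``split`` and validation remainder, refits the forest
    on the training part (optionally restricted to that member's selected
    variables) and scores the held-out points; the repetition's AUC is the
    mean over replicate datasets.  A single-class validation fold is redrawn
    with a fresh sub-seed (and logged).
    """
    if not (0 < split < 1):
        raise ValueError("split must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_aucs = []
    for rep in range(reps):
        aucs = []
        for i, (X, y) in enumerate(zip(X_sets, y_sets)):
            cols = (list(variable_sets[i]) if variable_sets is not None
                    else list(X.columns))
            Xi = X[cols].to_numpy()
            yi = np.asarray(y).astype(int)
            for attempt in range(10):
                rs = int(rng.integers(2 ** 31))
                Xtr, Xva, ytr, yva = train_test_split(
                    Xi, yi, train_size=split, random_state=rs, stratify=yi)
                if len(np.unique(yva)) == 2:
                    break
                logger.warning("single-class validation fold redrawn "
                               "(rep %d, dataset %d)", rep, i)
            clf = _fit_forest(Xtr, ytr, trees, int(rng.integers(2 ** 31)))
            idx = list(clf.classes_).index(1)
            scores = clf.predict_proba(Xva)[:, idx]
            aucs.append(rank_auc(scores, yva))
        rep_aucs.append(float(np.mean(aucs)))
    rep_aucs = np.asarray(rep_aucs)
    return float(rep_aucs.mean()), float(rep_aucs.std(ddof=1)) if reps > 1 else 0.0, rep_aucs


# ----------------------------------------------------------------------
# partial dependence
# ----------------------------------------------------------------------
def partial_dependence(
    members: Sequence[EnsembleMember],
    variable: str,
    grid_points: int = 50,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marginal response curve: probability of presence as the variable
    sweeps its training range with all other variables at their training
    mean.

    Returns a frame with columns ``value``, ``model_1..model_k`` (members
    whose subset contains the variable), ``mean``, ``lo``, ``hi`` (95%
    normal band across members).
    """
    use = [m for m in members if variable in m.variables]
    if not use:
        raise KeyError(f"variable {variable!r} is in no member's subset")
    if grid is None:
        lo = min(m.X[variable].min() for m in use)
        hi = max(m.X[variable].max() for m in use)
        grid = np.linspace(lo, hi, grid_points)
    curves = {}
    for k, m in enumerate(use, start=1):
        X = pd.DataFrame(
            {v: np.full(len(grid), m.training_means[v]) for v in m.variables})
        X[variable] = grid
        proba = m.forest.predict_proba(X[m.variables].to_numpy())
        idx = list(m.forest.classes_).index(1)
        curves[f"model_{k}"] = proba[:, idx]
    df = pd.DataFrame({"value": grid, **curves})
    mat = df[[c for c in df.columns if c.startswith("model_")]].to_numpy()
    df["mean"] = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else np.zeros(len(grid))
    df["lo"] = df["mean"] - 1.96 * sd
    df["hi"] = df["mean"] + 1.96 * sd
    return df


# ----------------------------------------------------------------------
# the Model / Results pair
# ----------------------------------------------------------------------
class HabitatSelectionModel:
    """Equal-sampling multiscale random-forest habitat model.

    Parameters
    ----------
    presences : DataFrame with x, y (projected meters) — thinned presences.
    absence_sets : sequence of DataFrames with x, y — one pseudo-absence
        replicate per ensemble member, each the same size as ``presences``.
    stack : CovariateStack holding every candidate variable at every scale.
    trees : forest size (default 500).
    cor_threshold : collinearity screen cutoff on |Pearson r| (default 0.85).
    mir_step : MIR threshold increment (default 0.1).
    """

    def __init__(self, presences: pd.DataFrame,
                 absence_sets: Sequence[pd.DataFrame],
                 stack: CovariateStack,
                 trees: int = DEFAULT_TREES,
                 cor_threshold: float = DEFAULT_COR_THRESHOLD,
                 mir_step: float = DEFAULT_MIR_STEP):
        self.presences = presences.reset_index(drop=True)
        self.absence_sets = [a.reset_index(drop=True) for a in absence_sets]
        self.stack = stack
        self.trees = trees
        self.cor_threshold = cor_threshold
        self.mir_step = mir_step
        for a in self.absence_sets:
            if len(a) != len(self.presences):
                raise ValueError("equal-sampling contract: every "
                                 "pseudo-absence set must match the presence "
                                 "count")

    # ------------------------------------------------------------------
    def datasets(self) -> list[pd.DataFrame]:
        """Replicate presence/pseudo-absence point sets with labels."""
        out = []
        pres = self.presences[["x", "y"]].assign(label="presence")
        for a in self.absence_sets:
            ab = a[["x", "y"]].assign(label="pseudo_absence")
            out.append(pd.concat([pres, ab], ignore_index=True))
        return out

    def fit(self, seed: int = 0,
            variables: Sequence[str] | None = None) -> "HabitatSelectionResults":
        """Run scale optimization, the collinearity screen and per-replicate
        MIR model selection; returns the fitted results object."""
        rng = np.random.default_rng(seed)
        datasets = self.datasets()

        profile = univariate_scale_selection(
            datasets, self.stack, variables=variables, trees=self.trees,
            seed=int(rng.integers(2 ** 31)))

        # layer names at the chosen scales, plus unscaled (distance) layers
        layer_names = [f"{v}_{s}" for v, s in profile.chosen.items()]
        unscaled = [v for v, s in self.stack.variables().items() if not s]
        if variables is None:
            layer_names += unscaled

        # badness ranking for the screen: mean univariate OOB error
        mean_err = (profile.oob_errors
                    .groupby(["variable", "scale"])["oob_error"].mean())
        ranking = {}
        for v, s in profile.chosen.items():
            ranking[f"{v}_{s}"] = float(mean_err.loc[(v, s)])
        retained, removals = collinearity_screen(
            self.stack, layer_names, self.cor_threshold, ranking)

        members = []
        for ds in datasets:
            X = self.stack.sample(ds["x"].to_numpy(), ds["y"].to_numpy(),
                                  names=retained)
            X = X.fillna(X.mean())
            y = (ds["label"] == "presence").to_numpy().astype(int)
            members.append(mir_model_selection(
                X, y, trees=self.trees, mir_step=self.mir_step,
                seed=int(rng.integers(2 ** 31))))

        return HabitatSelectionResults(
            model=self, scale_profile=profile, retained_variables=retained,
            removals=removals, members=members, seed=seed)


@dataclass
class HabitatSelectionResults:
    """Fitted equal-sampling multiscale random-forest ensemble."""

    model: HabitatSelectionModel
    scale_profile: ScaleProfile
    retained_variables: list[str]
    removals: list[tuple[str, str, float]]
    members: list[EnsembleMember]
    seed: int
    _auc: tuple[float, float, np.ndarray] | None = None

    @property
    def oob_errors(self) -> list[float]:
        return [m.oob_error for m in self.members]

    def predict(self, stack: CovariateStack | None = None) -> RasterGrid:
        """Habitat-suitability surface (ensemble-mean vote fraction)."""
        return ensemble_predict(self.members, stack or self.model.stack)

    def evaluate_auc(self, split: float = 0.7, reps: int = 10,
                     seed: int | None = None) -> tuple[float, float]:
        seed = self.seed + 1 if seed is None else seed
        mean, sd, per_rep = evaluate_auc(
            [m.X for m in self.members], [m.y for m in self.members],
            split=split, reps=reps, trees=self.model.trees, seed=seed,
            variable_sets=[m.variables for m in self.members])
        self._auc = (mean, sd, per_rep)
        return mean, sd

    def partial_dependence(self, variable: str, grid_points: int = 50
                           ) -> pd.DataFrame:
        return partial_dependence(self.members, variable, grid_points)

    def summary(self) -> str:
        """Human-readable fit summary (scales, screen, subsets, OOB, AUC)."""
        lines = ["Equal-sampling multiscale random-forest habitat model",
                 "=" * 56,
                 f"ensemble members: {len(self.members)}   trees per forest: "
                 f"{self.model.trees}",
                 "",
                 "Optimal scales (modal over replicate datasets):"]
        for _, row in self.scale_profile.to_frame().iterrows():
            lines.append(f"  {row['variable']:<12} {row['optimal_scale_m']:>6} m"
                         f"   (chosen by {row['selection_frequency']}/"
                         f"{len(self.members)} datasets)")
        if self.removals:
            lines.append("")
            lines.append("Collinearity screen (|r| > "
                         f"{self.model.cor_threshold}):")
            for drop, keep, r in self.removals:
                lines.append(f"  removed {drop} (r = {r:+.3f} with {keep})")
        lines.append("")
        lines.append("Per-member MIR-selected subsets and OOB error:")
        for i, m in enumerate(self.members, 1):
            lines.append(f"  model {i:>2}: OOB {m.oob_error:.4f}  "
                         f"[{', '.join(m.variables)}]")
        if self._auc is not None:
            mean, sd, _ = self._auc
            lines.append("")
            lines.append(f"Validation AUC (70/30 x {len(self._auc[2])}): "
                         f"{mean:.3f} (SD = {sd:.3f})")
        return "\n".join(lines)
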