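"""Presence–background niche models.

The model is an L1-regularized logistic regression of presence cells against
background cells on standardized linear and quadratic terms of every
environmental layer — the convex presence–background analogue of
maximum-entropy niche modelling. The penalty is
``lambda * betamultiplier * sum|coef|`` with ``lambda = 1/n_presence`` by
default, so ``betamultiplier`` plays its usual smoothing role: larger values
shrink the response surface toward a constant.

Workflow: :func:`sample_background` draws background points from valid cell
centres outside a buffer around the presences; :class:`MaxentNicheModel`
fits on the environmental values at both point sets; :meth:`predict_grid`
projects the fitted model onto any grid providing the same layers, yielding
a :class:`SuitabilityMap` in [0, 1]. :func:`auc` and
:func:`max_sss_threshold` evaluate and binarize predictions.

Because presences and background are sampled at an arbitrary ratio, the
fitted intercept is corrected to a common prevalence of 0.5 (the standard
case-control prior correction), so suitability surfaces are comparable
across models trained with different record counts — the role MaxEnt's
logistic output plays. When projecting to new grids, each layer is clamped
to its training range by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .grids import EnvGrid
from .occurrences import OccurrenceSet

__all__ = [
    "SuitabilityMap",
    "MaxentNicheModel",
    "sample_background",
    "fit_niche_model",
    "auc",
    "max_sss_threshold",
]


@dataclass
class SuitabilityMap:
    """Per-cell habitat suitability in [0, 1] on an EnvGrid geometry."""

    values: np.ndarray
    mask: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        v = self.values[self.mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    def same_geometry(self, other: "SuitabilityMap") -> bool:
        return (self.mask.shape == other.mask.shape
                and np.array_equal(self.mask, other.mask)
                and np.isclose(self.origin_x, other.origin_x)
                and np.isclose(self.origin_y, other.origin_y)
                and np.isclose(self.cell_size, other.cell_size))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_grid(self, name: str = "suitability") -> EnvGrid:
        """Wrap as a one-layer EnvGrid (e.g. for ASCII-grid output)."""
        return EnvGrid([name], self.values.copy(), self.mask.copy(),
                       self.origin_x, self.origin_y, self.cell_size)


def sample_background(grid: EnvGrid, presences: OccurrenceSet, n: int,
                      buffer_radius: float = 0.0,
                      seed: int | None = None) -> OccurrenceSet:
    """Draw background points from valid cell centres outside a buffer.

    Eligible cells are valid cells that contain no presence record and whose
    centre lies strictly farther than ``buffer_radius`` (map units) from
    every presence. Points are sampled uniformly without replacement; if
    fewer than ``n`` cells are eligible, all of them are returned with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    centers = grid.valid_cell_centers()
    eligible = np.ones(len(centers), dtype=bool)

    if len(presences):
        # exclude presence cells outright, then apply the distance buffer
        pr, pc = grid.cell_of(presences.x, presences.y)
        inside = (pr >= 0) & (pr < grid.n_rows) & (pc >= 0) & (pc < grid.n_cols)
        occupied = set(zip(pr[inside].tolist(), pc[inside].tolist()))
        rr, cc = np.nonzero(grid.mask)
        in_presence_cell = np.fromiter(
            ((r, c) in occupied for r, c in zip(rr, cc)), bool, len(rr))
        eligible &= ~in_presence_cell
        if buffer_radius > 0:
            d = cdist(centers, presences.coords()).min(axis=1)
            eligible &= d > buffer_radius

    pool = centers[eligible]
    if len(pool) == 0:
        warnings.warn("no eligible background cells outside the buffer")
        return OccurrenceSet.from_arrays(np.empty(0), np.empty(0),
                                         range_label="background")
    if len(pool) < n:
        warnings.warn(f"only {len(pool)} eligible background cells "
                      f"(requested {n}); returning all of them")
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = pool[idx]
    return OccurrenceSet.from_arrays(chosen[:, 0], chosen[:, 1],
                                     range_label="background")


class MaxentNicheModel(BaseEstimator):
    """Presence–background niche model (L1 logistic on linear+quadratic terms).

    Parameters
    ----------
    betamultiplier : float
        Regularization multiplier; the penalty is
        ``betamultiplier * lam * sum|coef|``. Larger values give smoother
        (eventually constant) suitability surfaces.
    lam : float or None
        Base penalty weight; defaults to ``1 / n_presence`` at fit time.
    tol : float
        Optimizer tolerance on the coefficient update.
    quadratic : bool
        Include squared terms of each standardized layer (default True).
    clamp : bool
        When predicting, clip each layer to its training-data range before
        building features (the usual guard against runaway extrapolation
        when projecting to novel environments; default True).

    Attributes
    ----------
    coef_ : ndarray of feature coefficients
    intercept_ : float
    feature_defs_ : list of (layer, kind) pairs, kind in {linear, quadratic}
    feature_means_, feature_stds_ : per-layer standardization constants
    layer_names_ : layers the model expects at prediction time
    training_meta_ : dict with n_presence, n_background and optional labels

    The estimator follows the scikit-learn protocol: ``fit(X, y)`` accepts a
    plain feature matrix with binary labels (1 = presence), so it composes
    with pipelines and model selection; :func:`fit_niche_model` builds X and
    y from occurrences and a grid.
    """

    def __init__(self, betamultiplier: float = 1.0, lam: float | None = None,
                 tol: float = 1e-8, max_iter: int = 10000,
                 quadratic: bool = True, clamp: bool = True):
        self.betamultiplier = betamultiplier
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.quadratic = quadratic
        self.clamp = clamp

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, sample_weight=None, layer_names=None,
            training_meta=None) -> "MaxentNicheModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (points x layers)")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = presence, 0 = background)")
        n_presence = int((y == 1).sum())
        if n_presence < 2:
            raise ValueError("need at least 2 presence points")
        if n_presence < 10:
            warnings.warn(f"only {n_presence} presence points; the fitted "
                          "niche may be unstable")
        if layer_names is None:
            layer_names = [f"layer{i}" for i in range(X.shape[1])]

        w = (np.ones(X.shape[0]) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        means = np.average(X, axis=0, weights=w)
        stds = np.sqrt(np.average((X - means) ** 2, axis=0, weights=w))
        keep = stds > 1e-12
        if not keep.all():
            dropped = [layer_names[i] for i in np.nonzero(~keep)[0]]
            warnings.warn(f"dropping constant layer(s): {dropped}")
        stds_safe = np.where(keep, stds, 1.0)
        Z = (X - means) / stds_safe

        feature_defs = [(layer_names[i], "linear") for i in np.nonzero(keep)[0]]
        cols = [Z[:, i] for i in np.nonzero(keep)[0]]
        if self.quadratic:
            feature_defs += [(layer_names[i], "quadratic")
                             for i in np.nonzero(keep)[0]]
            cols += [Z[:, i] ** 2 for i in np.nonzero(keep)[0]]
        F = np.column_stack(cols) if cols else np.zeros((X.shape[0], 0))

        lam = self.lam if self.lam is not None else 1.0 / n_presence
        # objective: sum NLL + lam*beta*sum|w|  <=>  sklearn C = 1/(lam*beta)
        C = 1.0 / (lam * self.betamultiplier)
        # case-control intercept correction: presences and background are
        # sampled at an arbitrary ratio, so the raw logistic intercept
        # reflects that ratio, not habitat. Shifting it by -log(n1/n0)
        # calibrates every model to a common prevalence of 0.5, making
        # suitability surfaces comparable across models trained with
        # different record counts (the role of MaxEnt's logistic output).
        n1_eff = float(w[y == 1].sum())
        n0_eff = float(w[y == 0].sum())
        offset = float(np.log(n1_eff / n0_eff))
        if F.shape[1] == 0:
            p = float(np.average(y, weights=sample_weight))
            p = min(max(p, 1e-12), 1 - 1e-12)
            self.coef_ = np.zeros(0)
            self.intercept_ = float(np.log(p / (1 - p))) - offset
        else:
            clf = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", tol=self.tol,
                max_iter=self.max_iter, intercept_scaling=100.0,
                random_state=0)
            clf.fit(F, y, sample_weight=sample_weight)
            self.coef_ = clf.coef_.ravel().copy()
            self.intercept_ = float(clf.intercept_[0]) - offset
        if not np.all(np.isfinite(self.coef_)):
            raise RuntimeError("non-finite coefficients after fitting")

        self.feature_defs_ = feature_defs
        self.layer_names_ = list(layer_names)
        self.feature_means_ = dict(zip(layer_names, means))
        self.feature_stds_ = dict(zip(layer_names, stds_safe))
        self.feature_ranges_ = {n: (float(np.nanmin(X[:, i])),
                                    float(np.nanmax(X[:, i])))
                                for i, n in enumerate(layer_names)}
        meta = {"n_presence": n_presence,
                "n_background": int((y == 0).sum())}
        if training_meta:
            meta.update(training_meta)
        self.training_meta_ = meta
        return self

    # -- prediction ---------------------------------------------------------
    def _design(self, X: np.ndarray, layer_names) -> np.ndarray:
        name_to_col = {n: i for i, n in enumerate(layer_names)}
        cols = []
        for layer, kind in self.feature_defs_:
            if layer not in name_to_col:
                raise ValueError(f"prediction input lacks layer {layer!r}")
            v = X[:, name_to_col[layer]]
            if self.clamp and hasattr(self, "feature_ranges_"):
                lo, hi = self.feature_ranges_[layer]
                v = np.clip(v, lo, hi)
            z = (v - self.feature_means_[layer]) / self.feature_stds_[layer]
            cols.append(z if kind == "linear" else z**2)
        return (np.column_stack(cols) if cols
                else np.zeros((X.shape[0], 0)))

    def decision_function(self, X, layer_names=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        names = layer_names if layer_names is not None else self.layer_names_
        F = self._design(X, names)
        return F @ self.coef_ + self.intercept_

    def predict_proba(self, X, layer_names=None) -> np.ndarray:
        from scipy.special import expit

        p = expit(self.decision_function(X, layer_names))
        return np.column_stack([1 - p, p])

    def predict_points(self, X, layer_names=None) -> np.ndarray:
        """Suitability in [0, 1] at environmental value rows."""
        return self.predict_proba(X, layer_names)[:, 1]

    def predict_grid(self, grid: EnvGrid) -> SuitabilityMap:
        """Project the fitted model onto every valid cell of a grid."""
        missing = [l for l, _ in self.feature_defs_ if l not in grid.layer_names]
        if missing:
            raise ValueError(f"grid lacks layer(s) {sorted(set(missing))}")
        rr, cc = np.nonzero(grid.mask)
        X = grid.values[:, rr, cc].T
        scores = self.predict_points(X, layer_names=grid.layer_names)
        out = np.zeros(grid.mask.shape)
        out[rr, cc] = scores
        return SuitabilityMap(out, grid.mask.copy(), grid.origin_x,
                              grid.origin_y, grid.cell_size)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "params": self.get_params(),
            "feature_defs": self.feature_defs_,
            "layer_names": self.layer_names_,
            "feature_means": {k: float(v) for k, v in self.feature_means_.items()},
            "feature_stds": {k: float(v) for k, v in self.feature_stds_.items()},
            "feature_ranges": {k: [float(a), float(b)]
                               for k, (a, b) in self.feature_ranges_.items()},
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "training_meta": self.training_meta_,
        })

    @classmethod
    def from_json(cls, text: str) -> "MaxentNicheModel":
        d = json.loads(text)
        model = cls(**d["params"])
        model.feature_defs_ = [tuple(fd) for fd in d["feature_defs"]]
        model.layer_names_ = d["layer_names"]
        model.feature_means_ = d["feature_means"]
        model.feature_stds_ = d["feature_stds"]
        model.feature_ranges_ = {k: tuple(v)
                                 for k, v in d["feature_ranges"].items()}
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model.training_meta_ = d["training_meta"]
        return model


def fit_niche_model(presences: OccurrenceSet, background: OccurrenceSet,
                    grid: EnvGrid, betamultiplier: float = 1.0,
                    seed: int | None = None, **kwargs) -> MaxentNicheModel:
    """Fit a niche model from presence and background point sets on a grid.

    Environmental values are extracted at each point; points off the grid or
    on invalid cells are dropped with a warning.
    """
    Xp = grid.extract(presences.x, presences.y)
    Xb = grid.extract(background.x, background.y)
    ok_p = np.isfinite(Xp).all(axis=1)
    ok_b = np.isfinite(Xb).all(axis=1)
    n_bad = int((~ok_p).sum() + (~ok_b).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} point(s) off-grid or on invalid cells")
    X = np.vstack([Xp[ok_p], Xb[ok_b]])
    y = np.concatenate([np.ones(ok_p.sum(), dtype=int),
                        np.zeros(ok_b.sum(), dtype=int)])
    model = MaxentNicheModel(betamultiplier=betamultiplier, **kwargs)
    meta = {}
    ranges = set(presences.range_labels.tolist())
    if len(ranges) == 1:
        meta["range_label"] = ranges.pop()
    return model.fit(X, y, layer_names=grid.layer_names, training_meta=meta)


def auc(predictions_at_presence, predictions_at_background) -> float:
    """Rank-based AUC: P(presence score > background) + 0.5 P(equal)."""
    pres = np.asarray(predictions_at_presence, dtype=float)
    bg = np.asarray(predictions_at_background, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    u = mannwhitneyu(pres, bg, alternative="two-sided").statistic
    return float(u / (pres.size * bg.size))


def max_sss_threshold(predictions_at_presence, predictions_at_background) -> float:
    """Threshold maximizing sensitivity + specificity (presence when >= t).

    Candidates are the unique predicted values; ties are broken by the
    smallest threshold.
    """
    pres = np.sort(np.asarray(predictions_at_presence, dtype=float))
    bg = np.sort(np.asarray(predictions_at_background, dtype=float))
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    # sensitivity = P(pres >= t); specificity = P(bg < t)
    sens = 1.0 - np.searchsorted(pres, candidates, side="left") / pres.size
    spec = np.searchsorted(bg, candidates, side="left") / bg.size
    total = sens + spec
    best = np.nonzero(total >= total.max() - 1e-12)[0][0]
    return float(candidates[best])
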