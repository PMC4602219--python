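"""Fisher-discriminant genotype classification with leave-one-animal-out CV.

The classifier is the classical two-class Fisher linear discriminant with a
small ridge on the pooled within-class scatter:

    w ∝ (Sw + λI)⁻¹ (μ_WT − μ_HYPO),   λ = ridge · trace(Sw) / d

The decision threshold b is chosen by scanning the midpoints of consecutive
sorted training projections and taking the value that minimizes the
class-balanced training misclassification — each sample weighted inversely
to its class count, so the threshold does not drift toward the majority
class when fold construction leaves the classes unequal (ties broken by
the largest margin between the flanking projections). Samples projecting exactly onto b are assigned to the
orientation class (the class lying above b).

Cross-validation holds out all samples of one animal per fold, so no
subject-identity information leaks into training. For principal-component
features, both the PCA and the choice of the number of components are made
inside each fold: an inner leave-one-animal-out loop over the training
animals picks the component count with the smallest inner aggregate error
(ties → fewest components), then PCA and classifier are refit on the full
training partition. Peak-feature imputation statistics are likewise fit on
training animals only.

The aggregate error is the pooled per-sample error over all held-out
samples; per-animal majority-vote genotype calls are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from mouseerp.features import (
    MULTI_CHANNELS,
    SINGLE_CHANNEL,
    FeatureMatrix,
    PeakImputer,
    WaveformPCA,
    build_peak_feature_matrix,
    build_waveform_feature_matrix,
)
from mouseerp.preprocess import EpochSet, block_average

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("peaks_single", "peaks_multi", "pc_multi")
DEFAULT_K_GRID = (1, 2, 4, 8, 16, 32)
DEFAULT_PC_GRID = tuple(range(1, 101))


# ----------------------------------------------------------------------------
# Fisher linear discriminant
# ----------------------------------------------------------------------------

def _class_stats(X: np.ndarray, y: np.ndarray, c0, c1):
    X0, X1 = X[y == c0], X[y == c1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc0, Xc1 = X0 - mu0, X1 - mu1
    Sw = Xc0.T @ Xc0 + Xc1.T @ Xc1
    return Sw, mu0, mu1


def _threshold_scan(p: np.ndarray, is_c1: np.ndarray) -> tuple[float, float]:
    """Exhaustive scan over midpoints of consecutive sorted projections.

    Rule: predict the orientation class (c1) when projection >= b. The scan
    minimizes the class-balanced training misclassification (each sample
    weighted by the inverse of its class count), so the threshold is
    invariant to class imbalance — essential under leave-one-animal-out
    folds, where the held-out animal's class is always the training
    minority. Returns (b, balanced training error); ties on error are
    broken by the largest gap between the flanking projections, then by the
    smallest candidate index.
    """
    n = len(p)
    order = np.argsort(p, kind="stable")
    ps, c1s = p[order], is_c1[order].astype(np.float64)
    n1 = c1s.sum()
    n0 = n - n1
    w1, w0 = 0.5 / n1, 0.5 / n0
    distinct = np.nonzero(np.diff(ps) > 0)[0]
    if len(distinct) == 0:
        # all projections identical: everything predicted c1
        return float(ps[0]), 0.5
    cum1 = np.cumsum(c1s)
    # boundary after sorted position i: below → c0, above (>= b) → c1
    miss_below = cum1[distinct]                    # class-1 samples predicted c0
    miss_above = n0 - (distinct + 1 - cum1[distinct])  # class-0 predicted c1
    errors = w1 * miss_below + w0 * miss_above
    best = errors.min()
    tied = np.nonzero(errors <= best + 1e-12)[0]
    gaps = ps[distinct[tied] + 1] - ps[distinct[tied]]
    pick = tied[np.argmax(gaps)]
    i = distinct[pick]
    b = 0.5 * (ps[i] + ps[i + 1])
    return float(b), float(best)


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Two-class Fisher linear discriminant with midpoint-scan threshold.

    Parameters
    ----------
    ridge : float
        Relative ridge on the within-class scatter; the absolute value used
        is ``ridge * trace(Sw) / n_features`` (exposed as ``ridge_value_``).

    Fitted attributes: ``coef_`` (unit-norm weight vector), ``threshold_``,
    ``orientation_`` (class predicted above the threshold), ``classes_``,
    ``training_error_``, ``degenerate_`` and ``majority_`` (degenerate fits
    — indistinguishable class means — predict the majority class, ties
    resolved toward the lexicographically later class, i.e. WT).
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {list(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        self.classes_ = classes
        c0, c1 = classes
        Sw, mu0, mu1 = _class_stats(X, y, c0, c1)
        d = X.shape[1]
        lam = self.ridge * np.trace(Sw) / d
        self.ridge_value_ = float(lam)
        dmu = mu1 - mu0

        scale = max(1.0, float(np.linalg.norm(mu0)), float(np.linalg.norm(mu1)))
        if np.linalg.norm(dmu) < 1e-10 * scale:
            self.degenerate_ = True
            self.coef_ = np.zeros(d)
            self.threshold_ = 0.0
            self.orientation_ = c1
            self.majority_ = c1 if counts[1] >= counts[0] else c0
            self.training_error_ = float(np.mean(y != self.majority_))
            return self

        # zero scatter (noise-free data): floor the ridge so the solve stays
        # well-posed and w falls back to the mean-difference direction
        lam_eff = lam if lam > 0 else 1e-12 * float(dmu @ dmu)
        w = np.linalg.solve(Sw + lam_eff * np.eye(d), dmu)
        w /= np.linalg.norm(w)
        self.degenerate_ = False
        self.majority_ = None
        self.coef_ = w
        self.orientation_ = c1  # w points toward class 1 (WT for WT/HYPO labels)
        self.threshold_, self.training_error_ = _threshold_scan(X @ w, y == c1)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coef_):
            raise ValueError("feature dimension does not match the fitted weights")
        return X @ self.coef_ - self.threshold_

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.degenerate_:
            return np.full(len(X), self.majority_, dtype=self.classes_.dtype)
        s = self.decision_function(X)
        other = self.classes_[0] if self.orientation_ == self.classes_[1] else self.classes_[1]
        return np.where(s >= 0, self.orientation_, other)

    @classmethod
    def _from_solution(cls, classes, w, b, ridge_value, training_error):
        clf = cls()
        clf.classes_ = np.asarray(classes)
        clf.coef_ = w
        clf.threshold_ = b
        clf.orientation_ = clf.classes_[1]
        clf.ridge_value_ = ridge_value
        clf.training_error_ = training_error
        clf.degenerate_ = False
        clf.majority_ = None
        return clf


def fit_fisher(features: FeatureMatrix, labels=None) -> FisherLDA:
    """Fit a :class:`FisherLDA` on a feature matrix (labels default to the
    matrix's genotype column)."""
    y = features.genotypes if labels is None else np.asarray(labels)
    return FisherLDA().fit(features.X, y)


def _fisher_prefix_grid(
    X: np.ndarray, y: np.ndarray, grid, ridge: float = 1e-6
) -> dict[int, FisherLDA]:
    """Fit Fisher classifiers on the first p columns for every p in grid.

    Equivalent to ``FisherLDA().fit(X[:, :p], y)`` for each p, but the full
    scatter matrix is computed once and sliced (scatter of a column prefix
    is the corresponding leading submatrix).
    """
    classes = np.unique(y)
    c0, c1 = classes
    Sw, mu0, mu1 = _class_stats(X, y, c0, c1)
    dmu = mu1 - mu0
    is_c1 = y == c1
    out = {}
    for p in grid:
        Swp = Sw[:p, :p]
        lam = ridge * np.trace(Swp) / p
        if lam <= 0:
            lam = 1e-12 * float(dmu[:p] @ dmu[:p]) or 1e-300
        w = np.linalg.solve(Swp + lam * np.eye(p), dmu[:p])
        w /= np.linalg.norm(w)
        b, err = _threshold_scan(X[:, :p] @ w, is_c1)
        out[p] = FisherLDA._from_solution(classes, w, b, float(lam), err)
    return out


# ----------------------------------------------------------------------------
# Leave-one-animal-out cross-validation
# ----------------------------------------------------------------------------

@dataclass
class CVCell:
    """One (k, feature kind) cell of the cross-validation grid."""

    k: int
    kind: str
    error: float
    n_samples: int
    chosen_pcs: dict = field(default_factory=dict)   # animal_id → n_pcs (pc kind)
    animal_votes: dict = field(default_factory=dict)  # animal_id → (true, voted, frac_correct)
    excluded: list = field(default_factory=list)

    @property
    def n_pcs(self) -> float:
        if not self.chosen_pcs:
            return np.nan
        return float(np.median(sorted(self.chosen_pcs.values())))


@dataclass
class CVReport:
    """Grid of CV cells over trial-average size × feature kind."""

    cells: list[CVCell]

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            votes = list(c.animal_votes.values())
            rows.append({
                "k": c.k,
                "feature_kind": c.kind,
                "n_pcs": c.n_pcs,
                "n_samples": c.n_samples,
                "error": c.error,
                "animal_error": (
                    float(np.mean([t != v for t, v, _ in votes])) if votes else np.nan
                ),
            })
        return pd.DataFrame(rows)

    def cell(self, k: int, kind: str) -> CVCell:
        for c in self.cells:
            if c.k == k and c.kind == kind:
                return c
        raise KeyError((k, kind))

    def to_csv(self, path: str | Path) -> None:
        self.table().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = [
            {
                "k": c.k,
                "feature_kind": c.kind,
                "error": c.error,
                "n_samples": c.n_samples,
                "chosen_pcs": c.chosen_pcs,
                "animal_votes": {
                    a: {"true": t, "voted": v, "frac_correct": f}
                    for a, (t, v, f) in c.animal_votes.items()
                },
                "excluded": c.excluded,
            }
            for c in self.cells
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def build_features_for_kind(
    animal_epochs: list[EpochSet],
    kind: str,
    k: int,
    channels=MULTI_CHANNELS,
    single_channel: str = SINGLE_CHANNEL,
) -> list[FeatureMatrix]:
    """Per-animal feature matrices for one (kind, k) cell; animals left with
    zero k-blocks are dropped with a warning."""
    if kind not in FEATURE_KINDS:
        raise ValueError(f"feature kind must be one of {FEATURE_KINDS}")
    out = []
    for ep in animal_epochs:
        blocked = block_average(ep, k)
        if blocked.n_epochs == 0:
            logger.warning("animal %s has no samples at k=%d; excluded", ep.animal_id, k)
            continue
        if kind == "peaks_single":
            fm = build_peak_feature_matrix(blocked, [single_channel], impute=False)
        elif kind == "peaks_multi":
            fm = build_peak_feature_matrix(blocked, channels, impute=False)
        else:
            fm = build_waveform_feature_matrix(blocked, channels)
        out.append(fm)
    return out


def _check_cohort(feats: list[FeatureMatrix]) -> None:
    genos = [f.genotypes[0] for f in feats]
    for g in ("WT", "HYPO"):
        if genos.count(g) < 2:
            raise ValueError(f"need at least 2 animals of genotype {g!r} for LOO CV")


def _fit_predict_peaks(train: list[FeatureMatrix], test: FeatureMatrix):
    Xtr = np.vstack([f.X for f in train])
    ytr = np.concatenate([f.genotypes for f in train])
    imputer = PeakImputer().fit(Xtr)
    clf = FisherLDA().fit(imputer.transform(Xtr), ytr)
    return clf.predict(imputer.transform(test.X))


def _select_n_pcs(train: list[FeatureMatrix], pc_grid, cap: int) -> int:
    """Inner leave-one-animal-out selection of the component count."""
    grid = sorted({int(p) for p in pc_grid if 1 <= p})
    miss = {}
    total = {}
    for v in range(len(train)):
        inner = train[:v] + train[v + 1 :]
        genos = {f.genotypes[0] for f in inner}
        if len(genos) < 2:
            continue
        Xin = np.vstack([f.X for f in inner])
        yin = np.concatenate([f.genotypes for f in inner])
        cap_v = min(cap, Xin.shape[0] - 1, Xin.shape[1])
        grid_v = [p for p in grid if p <= cap_v] or [cap_v]
        pca = WaveformPCA(n_components=cap_v).fit(Xin)
        Str = pca.transform(Xin)
        Sval = pca.transform(train[v].X)
        yval = train[v].genotypes
        classifiers = _fisher_prefix_grid(Str, yin, grid_v)
        for p, clf in classifiers.items():
            pred = clf.predict(Sval[:, :p])
            miss[p] = miss.get(p, 0) + int(np.sum(pred != yval))
            total[p] = total.get(p, 0) + len(yval)
    if not miss:
        return min(grid) if grid else 1
    rates = {p: miss[p] / total[p] for p in miss}
    best = min(rates.values())
    return min(p for p, r in rates.items() if r == best)


def _fit_predict_pc(train: list[FeatureMatrix], test: FeatureMatrix, pc_grid, cap: int):
    n_pcs = _select_n_pcs(train, pc_grid, cap)
    Xtr = np.vstack([f.X for f in train])
    ytr = np.concatenate([f.genotypes for f in train])
    cap_f = min(cap, Xtr.shape[0] - 1, Xtr.shape[1])
    n_pcs = min(n_pcs, cap_f)
    pca = WaveformPCA(n_components=cap_f).fit(Xtr)
    clf = FisherLDA().fit(pca.transform(Xtr)[:, :n_pcs], ytr)
    return clf.predict(pca.transform(test.X)[:, :n_pcs]), n_pcs


def loo_genotype_cv(
    animal_epochs: list[EpochSet],
    kind: str = "pc_multi",
    k: int = 4,
    pc_grid=DEFAULT_PC_GRID,
    channels=MULTI_CHANNELS,
    single_channel: str = SINGLE_CHANNEL,
) -> CVCell:
    """Leave-one-animal-out genotype prediction for one (kind, k) cell.

    ``animal_epochs`` are per-animal epoch sets (artifact rejection already
    applied). For every held-out animal the entire pipeline state — peak
    imputation statistics, PCA, component count, classifier — is fit on the
    remaining animals only.
    """
    feats = build_features_for_kind(animal_epochs, kind, k, channels, single_channel)
    present = {f.animal_ids[0] for f in feats}
    excluded = [ep.animal_id for ep in animal_epochs if ep.animal_id not in present]
    _check_cohort(feats)
    cap = int(max(pc_grid))

    misses = 0
    n_total = 0
    chosen: dict[str, int] = {}
    votes: dict[str, tuple] = {}
    for a in range(len(feats)):
        test = feats[a]
        train = feats[:a] + feats[a + 1 :]
        if kind == "pc_multi":
            pred, n_pcs = _fit_predict_pc(train, test, pc_grid, cap)
            chosen[str(test.animal_ids[0])] = n_pcs
        else:
            pred = _fit_predict_peaks(train, test)
        true = test.genotypes
        misses += int(np.sum(pred != true))
        n_total += len(true)
        frac = float(np.mean(pred == true))
        n_wt = int(np.sum(pred == "WT"))
        voted = "WT" if n_wt * 2 >= len(pred) else "HYPO"  # tie → WT
        votes[str(test.animal_ids[0])] = (str(true[0]), voted, frac)

    return CVCell(
        k=k,
        kind=kind,
        error=misses / n_total,
        n_samples=n_total,
        chosen_pcs=chosen,
        animal_votes=votes,
        excluded=excluded,
    )


def error_vs_averaging(
    animal_epochs: list[EpochSet],
    kinds=FEATURE_KINDS,
    k_grid=DEFAULT_K_GRID,
    pc_grid=DEFAULT_PC_GRID,
    channels=MULTI_CHANNELS,
    single_channel: str = SINGLE_CHANNEL,
) -> CVReport:
    """The full error-vs-trial-averaging grid for the requested feature
    families (one LOO CV cell per (k, kind) combination)."""
    cells = []
    for k in k_grid:
        for kind in kinds:
            cells.append(
                loo_genotype_cv(animal_epochs, kind, k, pc_grid, channels, single_channel)
            )
    return CVReport(cells)
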