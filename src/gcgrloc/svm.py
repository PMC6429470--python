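"""Multi-view SVM: fused GCGR + NSI + PseAAC + dipeptide features.

The fusion vector concatenates the selected views in the fixed order
GCGR (2) ‖ NSI (3) ‖ PseAAC (20+λ) ‖ dipeptide (400); with every view
and λ = 20 it has 445 components.  The classifier is an RBF-kernel
soft-margin SVM with libsvm semantics (one-vs-one multi-class; g is
the gamma of exp(−g·‖x−y‖²)) over scaled features, the scaling being
learned from the training samples only — inside every jackknife fold —
so the held-out sample never leaks into the scaler.

The default scaling maps every feature to [0, 1] from its training
range, libsvm's ``svm-scale`` convention.  Z-scoring is available but
a poor default here: it inflates squared distances between
445-dimensional fusion vectors into the hundreds, where
exp(−g·d²) ≈ 0 for every g in the default grid, the kernel matrix
degenerates toward the identity and the classifier falls back to the
training majority class.

Model selection follows a grid search over c and g, by
default the 11 × 11 grid of powers of two from 2⁻⁵ to 2⁵, scored by
full jackknife accuracy with ties broken toward the smallest c then
the smallest g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

from gcgrloc.classic import FeatureVector, dipeptide_composition, pseaac
from gcgrloc.encoding import encode_six, encode_three
from gcgrloc.evaluation import EvaluationReport, report_from_predictions
from gcgrloc.gcgr import gcgr_features, gcgr_trace, make_hexagon
from gcgrloc.io import LabeledDataset, ProteinRecord
from gcgrloc.nsi import nsi_features

VIEW_ORDER = ("gcgr", "nsi", "pseaac", "dipeptide")

DEFAULT_GRID = tuple(2.0**k for k in range(-5, 6))


@dataclass(frozen=True)
class FusionConfig:
    """Which views to fuse and the SVM / PseAAC hyper-parameters."""

    views: tuple[str, ...] = VIEW_ORDER
    c: float = 8.0
    g: float = 0.0625
    scaling: str = "minmax"  # "minmax" | "zscore" | "none"
    pseaac_lambda: int = 20
    pseaac_weight: float = 0.05

    def __post_init__(self) -> None:
        views = tuple(v.lower() for v in self.views)
        unknown = set(views) - set(VIEW_ORDER)
        if unknown:
            raise ValueError(f"unknown views: {', '.join(sorted(unknown))}")
        if not views:
            raise ValueError("at least one view is required")
        # store in canonical order
        object.__setattr__(self, "views", tuple(v for v in VIEW_ORDER if v in views))
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be positive")


def build_fusion_vector(record: ProteinRecord, config: FusionConfig = FusionConfig()) -> FeatureVector:
    """Concatenate the selected per-protein views into one named vector."""
    parts: list[np.ndarray] = []
    names: list[str] = []
    for view in config.views:
        if view == "gcgr":
            feats = gcgr_features(gcgr_trace(encode_six(record.sequence), make_hexagon()))
            parts.append(feats)
            names += ["gcgr_xbar", "gcgr_ybar"]
        elif view == "nsi":
            parts.append(nsi_features(encode_three(record.sequence)))
            names += ["nsi_I_F", "nsi_I_D", "nsi_I_S"]
        elif view == "pseaac":
            try:
                fv = pseaac(record.sequence, lam=config.pseaac_lambda, weight=config.pseaac_weight)
            except ValueError as exc:
                raise ValueError(f"view 'pseaac' failed for record {record.id!r}: {exc}") from exc
            parts.append(fv.values)
            names += list(fv.names)
        elif view == "dipeptide":
            try:
                fv = dipeptide_composition(record.sequence)
            except ValueError as exc:
                raise ValueError(f"view 'dipeptide' failed for record {record.id!r}: {exc}") from exc
            parts.append(fv.values)
            names += list(fv.names)
    return FeatureVector(id=record.id, names=tuple(names), values=np.concatenate(parts))


def fusion_matrix(dataset: LabeledDataset, config: FusionConfig = FusionConfig()) -> tuple[np.ndarray, list[str]]:
    """Stack fusion vectors for a dataset; returns (X, labels)."""
    vectors = [build_fusion_vector(rec, config) for rec in dataset.records]
    labels = [rec.label for rec in dataset.records]
    if any(l is None for l in labels):
        raise ValueError("all records must be labeled")
    return np.stack([v.values for v in vectors]), [str(l) for l in labels]


def train_svm(X: np.ndarray, y: Sequence[str], c: float, g: float, *, scaling: str = "minmax") -> Pipeline:
    """Fit the standardize-then-RBF-SVM pipeline.

    The returned object is a scikit-learn pipeline whose SVC uses
    libsvm's one-vs-one decision scheme with cost ``c`` and RBF gamma
    ``g``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    steps = []
    if scaling == "minmax":
        steps.append(("scale", MinMaxScaler(feature_range=(0.0, 1.0), clip=False)))
    elif scaling == "zscore":
        steps.append(("scale", StandardScaler()))
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    steps.append(("svm", SVC(C=c, gamma=g, kernel="rbf")))
    model = Pipeline(steps)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def jackknife_svm(
    X: np.ndarray,
    y: Sequence[str],
    c: float,
    g: float,
    *,
    scaling: str = "minmax",
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation of the SVM on a precomputed feature matrix.

    The scaler and the SVM are re-fit inside every fold on the n−1
    training rows only.
    """
    X = np.asarray(X, dtype=float)
    y = [str(l) for l in y]
    if classes is None:
        classes = tuple(dict.fromkeys(y))
    singletons = [cl for cl in classes if y.count(cl) < 2]
    if singletons:
        raise ValueError(f"classes with fewer than two samples: {', '.join(singletons)}")
    n = len(y)
    mask = np.ones(n, dtype=bool)
    predictions: list[str] = []
    for i in range(n):
        mask[i] = False
        model = train_svm(X[mask], [y[j] for j in range(n) if j != i], c, g, scaling=scaling)
        predictions.append(str(model.predict(X[i : i + 1])[0]))
        mask[i] = True
    return report_from_predictions(y, predictions, classes)


@dataclass(frozen=True)
class GridSearchResult:
    best_c: float
    best_g: float
    best_accuracy: float
    accuracy_table: dict[tuple[float, float], float] = field(compare=False)


def grid_search_jackknife(
    X: np.ndarray,
    y: Sequence[str],
    c_grid: Sequence[float] = DEFAULT_GRID,
    g_grid: Sequence[float] = DEFAULT_GRID,
    *,
    scaling: str = "minmax",
) -> GridSearchResult:
    """Jackknife accuracy over every (c, g) pair; deterministic argmax.

    Among pairs of equal accuracy the smallest c wins, then the
    smallest g.
    """
    if not c_grid or not g_grid:
        raise ValueError("grids must be non-empty")
    table: dict[tuple[float, float], float] = {}
    best = (-1.0, np.inf, np.inf)  # (-acc, c, g) ordering via min
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            acc = jackknife_svm(X, y, c, g, scaling=scaling).overall_acc
            table[(c, g)] = acc
            if acc > best[0]:
                best = (acc, c, g)
    return GridSearchResult(best_c=best[1], best_g=best[2], best_accuracy=best[0], accuracy_table=table)
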