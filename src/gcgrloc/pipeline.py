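"""End-to-end experiment drivers tying features, models and evaluation.

Two pipelines mirror the two predictors:

* ``jackknife_distance`` — the classifier-free route: per protein the
  2-D GCGR mean vector and the 3-D interval-statistics vector are
  fused in parallel into a 3-component complex vector (the GCGR pair
  padded with its own x̄/ȳ-derived value) and classified by nearest
  class centroid under the unitary distance, evaluated leave-one-out.
* ``jackknife_fusion_svm`` — the multi-view SVM over concatenated
  GCGR + NSI + PseAAC + dipeptide features.
"""

from __future__ import annotations

from typing import Literal

from gcgrloc.encoding import encode_six, encode_three
from gcgrloc.evaluation import EvaluationReport, jackknife
from gcgrloc.fusion import (
    ComplexFeature,
    PaddingRule,
    fit_distance_model,
    parallel_combine,
    predict_distance,
)
from gcgrloc.gcgr import gcgr_features, gcgr_trace, make_hexagon
from gcgrloc.io import LabeledDataset, ProteinRecord
from gcgrloc.nsi import nsi_features
from gcgrloc.svm import FusionConfig, fusion_matrix, jackknife_svm


def distance_feature(record: ProteinRecord, rule: PaddingRule = "ratio") -> ComplexFeature:
    """The parallel GCGR + NSI complex feature of one protein."""
    hexagon = make_hexagon()
    u = gcgr_features(gcgr_trace(encode_six(record.sequence), hexagon))
    v = nsi_features(encode_three(record.sequence))
    return parallel_combine(u, v, pad_values=(float(u[0]), float(u[1])), rule=rule)


def jackknife_distance(
    dataset: LabeledDataset,
    mode: Literal["centroid", "neighbor"] = "centroid",
    rule: PaddingRule = "ratio",
) -> EvaluationReport:
    """Leave-one-out evaluation of the unitary-distance model."""
    features = [distance_feature(rec, rule) for rec in dataset.records]
    labels = [str(rec.label) for rec in dataset.records]

    def fit(train_x, train_y):
        return fit_distance_model(train_x, train_y, classes=dataset.classes, mode=mode)

    return jackknife(features, labels, fit, predict_distance, classes=dataset.classes)


def jackknife_fusion_svm(
    dataset: LabeledDataset,
    config: FusionConfig = FusionConfig(),
) -> EvaluationReport:
    """Leave-one-out evaluation of the multi-view SVM."""
    X, y = fusion_matrix(dataset, config)
    return jackknife_svm(X, y, config.c, config.g, scaling=config.scaling, classes=dataset.classes)
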