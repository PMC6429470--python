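"""Parallel complex-vector feature fusion and the unitary-distance predictor.

Two real feature vectors u and v are fused in parallel as one complex
vector z = u + v·i rather than concatenated.  When their dimensions
differ, the lower-dimensional one is right-padded to m =
max(dim u, dim v).  The padding value comes from the GCGR feature pair
(x̄, ȳ): the default "ratio" rule appends the scalar x̄/ȳ repeatedly;
the "alternate" rule appends x̄, then ȳ, cycling.

The unitary norm ||z|| = sqrt(Σ a_k² + b_k²) is the norm induced by the
complex inner product ⟨a, b⟩ = aᴴb, numerically the Euclidean norm of
the stacked real and imaginary parts; the unitary distance is
||z1 − z2||.  The classifier-free predictor assigns a query to the
class whose centroid (component-wise complex mean; or nearest stored
neighbor) is closest in unitary distance, with ties broken by class
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

PaddingRule = Literal["ratio", "alternate"]


@dataclass(frozen=True)
class ComplexFeature:
    """A parallel-combined complex feature vector with padding metadata."""

    z: np.ndarray  # complex, shape (m,)
    padded_from: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.z)

    @property
    def real_part(self) -> np.ndarray:
        return self.z.real

    @property
    def imag_part(self) -> np.ndarray:
        return self.z.imag


def _pad(vec: np.ndarray, m: int, pad_values: tuple[float, float], rule: PaddingRule) -> np.ndarray:
    k = m - len(vec)
    if k <= 0:
        return vec
    x_bar, y_bar = pad_values
    if rule == "ratio":
        if y_bar == 0:
            raise ZeroDivisionError("ratio padding undefined: ȳ = 0")
        fill = np.full(k, x_bar / y_bar)
    elif rule == "alternate":
        fill = np.array([x_bar if i % 2 == 0 else y_bar for i in range(k)])
    else:
        raise ValueError(f"unknown padding rule {rule!r}")
    return np.concatenate([vec, fill])


def parallel_combine(
    u: Sequence[float] | np.ndarray,
    v: Sequence[float] | np.ndarray,
    pad_values: tuple[float, float] = (0.0, 1.0),
    rule: PaddingRule = "ratio",
) -> ComplexFeature:
    """Combine real vectors u and v as z = u + v·i, padding the shorter one.

    ``pad_values`` is the (x̄, ȳ) pair supplying the padding scalar(s).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise ValueError("both vectors must be non-empty")
    m = max(len(u), len(v))
    meta = {"dim_u": int(len(u)), "dim_v": int(len(v)), "rule": rule, "pad_values": tuple(map(float, pad_values))}
    up = _pad(u, m, pad_values, rule)
    vp = _pad(v, m, pad_values, rule)
    return ComplexFeature(z=up + 1j * vp, padded_from=meta)


def unitary_norm(z: ComplexFeature | np.ndarray) -> float:
    """sqrt of Σ (realₖ² + imagₖ²) over all components."""
    arr = z.z if isinstance(z, ComplexFeature) else np.asarray(z)
    return float(np.sqrt(np.sum(arr.real**2 + arr.imag**2)))


def unitary_distance(z1: ComplexFeature | np.ndarray, z2: ComplexFeature | np.ndarray) -> float:
    """Unitary-space distance ||z1 − z2||."""
    a = z1.z if isinstance(z1, ComplexFeature) else np.asarray(z1)
    b = z2.z if isinstance(z2, ComplexFeature) else np.asarray(z2)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return unitary_norm(a - b)


@dataclass(frozen=True)
class DistanceModel:
    """Classifier-free unitary-distance model.

    ``centroid`` mode stores one per-class complex mean; ``neighbor``
    mode stores every training sample (1-NN prediction).  Class order is
    the dataset's order and is the deterministic tie-break.
    """

    classes: tuple[str, ...]
    mode: Literal["centroid", "neighbor"]
    templates: dict[str, np.ndarray]  # centroid mode: class -> (m,) complex
    samples: tuple[tuple[str, np.ndarray], ...] = ()  # neighbor mode

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "mode": self.mode,
            "classes": list(self.classes),
            "templates": {
                c: {"real": t.real.tolist(), "imag": t.imag.tolist()}
                for c, t in self.templates.items()
            },
            "samples": [
                {"label": lbl, "real": z.real.tolist(), "imag": z.imag.tolist()}
                for lbl, z in self.samples
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "DistanceModel":
        doc = json.loads(text)
        templates = {
            c: np.array(t["real"]) + 1j * np.array(t["imag"])
            for c, t in doc["templates"].items()
        }
        samples = tuple(
            (s["label"], np.array(s["real"]) + 1j * np.array(s["imag"]))
            for s in doc["samples"]
        )
        return cls(classes=tuple(doc["classes"]), mode=doc["mode"], templates=templates, samples=samples)


def fit_distance_model(
    features: Sequence[ComplexFeature],
    labels: Sequence[str],
    classes: Sequence[str] | None = None,
    mode: Literal["centroid", "neighbor"] = "centroid",
) -> DistanceModel:
    """Fit per-class centroids (or store all samples) in complex space."""
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    if len(features) == 0:
        raise ValueError("empty training set")
    if classes is None:
        classes = tuple(dict.fromkeys(labels))
    else:
        classes = tuple(classes)
    dims = {len(f) for f in features}
    if len(dims) != 1:
        raise ValueError("all features must share one dimensionality")
    z = np.stack([f.z for f in features])
    y = np.asarray(labels)
    templates: dict[str, np.ndarray] = {}
    for c in classes:
        mask = y == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no training samples")
        templates[c] = z[mask].mean(axis=0)
    samples = tuple((str(lbl), zi) for lbl, zi in zip(y, z)) if mode == "neighbor" else ()
    return DistanceModel(classes=classes, mode=mode, templates=templates, samples=samples)


def predict_distance(model: DistanceModel, z: ComplexFeature | np.ndarray) -> str:
    """Class of the nearest template (or neighbor); ties go to class order."""
    query = z.z if isinstance(z, ComplexFeature) else np.asarray(z)
    if model.mode == "centroid":
        best_class, best_d = None, np.inf
        for c in model.classes:
            d = unitary_distance(model.templates[c], query)
            if d < best_d:  # strict: earlier class wins ties
                best_class, best_d = c, d
        assert best_class is not None
        return best_class
    # neighbor mode: nearest sample; among equidistant samples the
    # earliest class in class order wins, then earliest sample.
    order = {c: i for i, c in enumerate(model.classes)}
    best = min(
        ((unitary_distance(zi, query), order[lbl], lbl) for lbl, zi in model.samples),
        key=lambda t: (t[0], t[1]),
    )
    return best[2]
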