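"""Random-Forest pixel classification with out-of-bag (OOB) control.

Every preprocessed map pixel is classified into one of the polymer classes
or the non-microplastic (NMP) class by a Random Forest trained on a
labeled spectral library (1500 trees by default).  The prediction error is
estimated from the OOB samples, which also yield a per-class confusion
matrix.  Each prediction carries a confidence score — the fraction of
trees voting for the winning class — and pixels below a review threshold
are flagged for manual inspection, mirroring the operator control loop of
the laboratory workflow.  Constant (degenerate) spectra bypass the forest
entirely and are assigned NMP with confidence 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .preprocess import PreprocessParams, preprocess_pipeline
from .spectra import SpectralMap, Spectrum, TrainingLibrary


class AxisError(ValueError):
    """Spectra are not on the model's common wavenumber grid."""


class TrainingError(ValueError):
    """The training library cannot support a multi-class model."""


@dataclass
class ClassifierModel:
    """A trained forest plus its OOB diagnostics.

    ``confusion`` rows are true classes, columns predicted classes (order
    = ``classes``); row sums equal the per-class training counts.
    """

    forest: RandomForestClassifier
    n_trees: int
    classes: list[str]
    oob_error: float
    confusion: np.ndarray
    seed: int
    axis: np.ndarray

    @property
    def per_class_error(self) -> dict[str, float]:
        """OOB misclassification fraction per true class."""
        out = {}
        for i, c in enumerate(self.classes):
            row = self.confusion[i]
            n = row.sum()
            out[c] = float((n - row[i]) / n) if n else float("nan")
        return out


@dataclass
class PixelClassification:
    """Classification record for one map pixel."""

    position: tuple[float, float]
    label: str
    confidence: float
    review: bool
    degenerate: bool = False
    spectrum_index: int | None = None


def preprocess_library(
    lib: TrainingLibrary, params: PreprocessParams | None = None
) -> TrainingLibrary:
    """Run the full preprocessing chain over every library entry."""
    params = params or PreprocessParams()
    return TrainingLibrary([preprocess_pipeline(s, params) for s in lib.entries])


def preprocess_map(
    map_: SpectralMap, params: PreprocessParams | None = None
) -> SpectralMap:
    """Run the full preprocessing chain over every map pixel."""
    params = params or PreprocessParams()
    return SpectralMap(
        [preprocess_pipeline(s, params) for s in map_.spectra],
        step=map_.step,
        analyzed_fraction=map_.analyzed_fraction,
        filter_area=map_.filter_area,
    )


def _check_axis(spectra: list[Spectrum], axis: np.ndarray | None = None) -> np.ndarray:
    if not spectra:
        raise TrainingError("no spectra")
    ref = spectra[0].wavenumbers if axis is None else axis
    for s in spectra:
        if len(s.wavenumbers) != len(ref) or not np.allclose(
            s.wavenumbers, ref, rtol=0, atol=1e-9
        ):
            raise AxisError(
                "spectra are not on a single common grid; run the "
                "preprocessing pipeline first"
            )
    return ref


def train(
    lib: TrainingLibrary, n_trees: int = 1500, seed: int = 0
) -> ClassifierModel:
    """Train the forest on a preprocessed library.

    The library must already be on the common grid (axis mismatch raises
    :class:`AxisError`).  OOB error and the OOB confusion matrix are
    stored on the model; training is reproducible given ``seed``.
    """
    classes = lib.classes
    if len(classes) < 2:
        raise TrainingError(f"need at least 2 classes, got {classes}")
    axis = _check_axis(lib.entries)
    X = np.vstack([s.intensities for s in lib.entries])
    y = np.array([s.label for s in lib.entries])
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    model_classes = [str(c) for c in forest.classes_]
    oob_error = 1.0 - float(forest.oob_score_)

    proba = forest.oob_decision_function_
    k = len(model_classes)
    confusion = np.zeros((k, k), dtype=int)
    cls_index = {c: i for i, c in enumerate(model_classes)}
    for probs, true in zip(proba, y):
        ti = cls_index[true]
        if np.all(probs == 0) or np.any(np.isnan(probs)):
            # sample was in-bag for every tree (only possible for tiny
            # forests): count as correct to keep row sums == class counts
            confusion[ti, ti] += 1
        else:
            confusion[ti, int(np.argmax(probs))] += 1
    return ClassifierModel(
        forest=forest,
        n_trees=n_trees,
        classes=model_classes,
        oob_error=oob_error,
        confusion=confusion,
        seed=int(seed),
        axis=axis,
    )


def predict(
    model: ClassifierModel,
    map_: SpectralMap,
    review_threshold: float = 0.5,
    merge_stearate_nmp: bool = False,
) -> list[PixelClassification]:
    """Classify every pixel of a preprocessed map.

    Confidence is the fraction of trees voting for the winning class
    (fully-grown trees have pure leaves, so the forest's averaged class
    probabilities coincide with the tree-vote fraction).  Degenerate
    pixels bypass the forest: NMP, confidence 0, review flag set.  With
    ``merge_stearate_nmp`` stearate calls are relabeled NMP, reflecting
    that glove stearates are contamination rather than microplastic.
    """
    records: list[PixelClassification | None] = [None] * len(map_.spectra)
    live_idx = []
    for idx, s in enumerate(map_.spectra):
        if s.degenerate:
            records[idx] = PixelClassification(
                position=s.position,
                label="NMP",
                confidence=0.0,
                review=True,
                degenerate=True,
                spectrum_index=idx,
            )
        else:
            live_idx.append(idx)
    if live_idx:
        _check_axis([map_.spectra[i] for i in live_idx], axis=model.axis)
        X = np.vstack([map_.spectra[i].intensities for i in live_idx])
        proba = model.forest.predict_proba(X)
        winners = np.argmax(proba, axis=1)
        for row, (idx, w) in enumerate(zip(live_idx, winners)):
            label = model.classes[w]
            conf = float(proba[row, w])
            if merge_stearate_nmp and label == "stearate":
                label = "NMP"
            records[idx] = PixelClassification(
                position=map_.spectra[idx].position,
                label=label,
                confidence=conf,
                review=conf < review_threshold,
                degenerate=False,
                spectrum_index=idx,
            )
    return records  # type: ignore[return-value]


def report_confusion(model: ClassifierModel) -> pd.DataFrame:
    """OOB confusion matrix (true × predicted) with per-class error.

    Rows sum to the per-class training counts; the ``error`` column is the
    fraction of each class's training spectra misclassified out-of-bag.
    """
    df = pd.DataFrame(model.confusion, index=model.classes, columns=model.classes)
    n = df.sum(axis=1)
    df["error"] = (n - np.diag(model.confusion)) / n.replace(0, np.nan)
    return df
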