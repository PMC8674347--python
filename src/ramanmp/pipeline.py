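"""End-to-end orchestration: scene → preprocess → classify → detect →
quantify, driven by a :class:`~ramanmp.config.RunConfig`.

This is the programmatic counterpart of the ``run-all`` CLI command and
the entry point the examples and tests use.
"""

from __future__ import annotations

import json

import numpy as np

from . import classify as _classify
from .config import RunConfig
from .particles import cluster_particles
from .preprocess import PreprocessParams
from .quantify import QuantReport, build_report
from .spectra import CLASSES, SpectralMap, TrainingLibrary
from .synth import ParticleSpec, SceneSpec, generate_map, generate_training_library

#: polymer classes eligible for planted particles (NMP is background and
#: stearate is a contamination decoy, so neither is planted by default)
PARTICLE_CLASSES = tuple(c for c in CLASSES if c not in ("NMP", "stearate"))


def preprocess_params(cfg: RunConfig) -> PreprocessParams:
    b = cfg.preprocess
    return PreprocessParams(
        grid_start=b.grid_start,
        grid_end=b.grid_end,
        grid_step=b.grid_step,
        baseline_lam=b.baseline_lam,
        baseline_p=b.baseline_p,
        baseline_niter=b.baseline_niter,
        smooth_lam=b.smooth_lam,
    )


def scene_from_config(cfg: RunConfig) -> SceneSpec:
    """Build a random scene (particle classes and diameters drawn from the
    config ranges) whose randomness is fully determined by ``cfg.seed``."""
    b = cfg.synth
    rng = np.random.default_rng(cfg.seed)
    classes = tuple(b.particle_classes) if b.particle_classes else PARTICLE_CLASSES
    lo, hi = b.diameter_range_um
    particles = [
        ParticleSpec(
            cls=classes[int(rng.integers(len(classes)))],
            diameter_um=float(rng.uniform(lo, hi)),
        )
        for _ in range(b.n_particles)
    ]
    return SceneSpec(
        width_um=b.width_um,
        height_um=b.height_um,
        step=b.step,
        filter_area=b.filter_area,
        analyzed_fraction=b.analyzed_fraction,
        particles=particles,
        fibers=b.fibers,
        dropout_prob=b.dropout_prob,
        snr_range=tuple(b.snr_range),
        seed=cfg.seed,
    )


def train_from_config(
    cfg: RunConfig, library: TrainingLibrary | None = None
) -> _classify.ClassifierModel:
    """Preprocess a library (generated from the config when not given) and
    train the forest."""
    if library is None:
        library = generate_training_library(
            n_per_class=cfg.synth.n_per_class,
            snr_range=tuple(cfg.synth.library_snr_range),
            seed=cfg.seed + 1,
        )
    params = preprocess_params(cfg)
    prepped = _classify.preprocess_library(library, params)
    return _classify.train(prepped, n_trees=cfg.classifier.n_trees, seed=cfg.seed)


def load_blank(path: str) -> dict[str, int]:
    """Per-class counts to subtract, read from a blank report JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return {c: int(n) for c, n in data.get("extrapolated_counts", {}).items()}


def run_all(
    cfg: RunConfig,
    map_: SpectralMap | None = None,
    library: TrainingLibrary | None = None,
    model: _classify.ClassifierModel | None = None,
) -> tuple[QuantReport, dict]:
    """Full pipeline; returns the report and intermediate artifacts.

    When ``map_`` is None a synthetic scene is generated from the config
    (its ground truth is returned under ``extras["truth"]``).  The report
    embeds the exact config and seed, so identical invocations produce
    byte-identical output.
    """
    extras: dict = {}
    if map_ is None:
        scene = scene_from_config(cfg)
        map_, truth = generate_map(scene)
        extras["truth"] = truth
    if model is None:
        model = train_from_config(cfg, library)
    extras["model"] = model

    params = preprocess_params(cfg)
    prepped = _classify.preprocess_map(map_, params)
    pixels = _classify.predict(
        model,
        prepped,
        review_threshold=cfg.classifier.review_threshold,
        merge_stearate_nmp=cfg.classifier.merge_stearate_nmp,
    )
    extras["pixels"] = pixels

    particles = cluster_particles(
        pixels,
        step=map_.step,
        max_gap=cfg.clustering.max_gap,
        exclude=set(cfg.clustering.exclude),
        metric=cfg.clustering.metric,
        drop_review=cfg.classifier.drop_review,
    )
    extras["particles"] = particles

    if cfg.quantify.analyzed_fraction is not None:
        map_ = SpectralMap(
            map_.spectra,
            step=map_.step,
            analyzed_fraction=cfg.quantify.analyzed_fraction,
            filter_area=map_.filter_area,
        )
    blank = load_blank(cfg.blank) if cfg.blank else None
    report = build_report(
        particles,
        map_,
        blank=blank,
        sample_volume_mL=cfg.quantify.sample_volume_mL,
        kind=cfg.quantify.kind,
        include_spectra=cfg.quantify.include_spectra,
        provenance={
            "config": cfg.model_dump(),
            "seed": cfg.seed,
            "oob_error": model.oob_error,
            "n_trees": model.n_trees,
        },
    )
    return report, extras
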