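"""Run configuration: schema-validated parameter blocks for the pipeline.

A YAML config file maps 1:1 onto :class:`RunConfig`; unknown keys are
rejected before any computation starts, so a typo in a parameter name
fails fast instead of silently using a default.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

import yaml


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessBlock(_Strict):
    grid_start: float = 559.0
    grid_end: float = 1990.0
    grid_step: float = 3.0
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    smooth_lam: float = 5.0


class ClassifierBlock(_Strict):
    n_trees: int = 1500
    review_threshold: float = 0.5
    drop_review: bool = False
    merge_stearate_nmp: bool = False


class ClusteringBlock(_Strict):
    max_gap: int = 2
    metric: str = "chebyshev"
    exclude: list[str] = Field(default_factory=lambda: ["NMP"])


class QuantifyBlock(_Strict):
    sample_volume_mL: float = 25.0
    analyzed_fraction: float | None = None  # None: take it from the map
    kind: str = "sample"
    include_spectra: bool = True


class SynthBlock(_Strict):
    width_um: float = 400.0
    height_um: float = 400.0
    step: float = 5.0
    filter_area: float = 14.0
    analyzed_fraction: float = 0.5
    n_particles: int = 20
    particle_classes: list[str] | None = None
    diameter_range_um: list[float] = Field(default_factory=lambda: [10.0, 20.0])
    fibers: int = 0
    dropout_prob: float = 0.0
    snr_range: list[float] = Field(default_factory=lambda: [15.0, 30.0])
    library_snr_range: list[float] = Field(default_factory=lambda: [3.0, 30.0])
    n_per_class: int = 50


class RunConfig(_Strict):
    seed: int = 0
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    classifier: ClassifierBlock = Field(default_factory=ClassifierBlock)
    clustering: ClusteringBlock = Field(default_factory=ClusteringBlock)
    quantify: QuantifyBlock = Field(default_factory=QuantifyBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)
    blank: str | None = None  # path to a blank report (JSON) to subtract


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file and apply flag overrides (dotted keys)."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        parts = key.split(".")
        node = data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return RunConfig.model_validate(data)
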