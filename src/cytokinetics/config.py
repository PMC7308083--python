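"""Analysis configuration: every numeric parameter of the pipeline in one
serializable object, written verbatim next to every result."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .containers import ORDERED_MARKERS

__all__ = [
    "SimulationConfig", "PreprocessConfig", "DAConfig", "TrajectoryConfig",
    "AnalysisConfig", "dump_yaml", "load_yaml",
]


@dataclass
class SimulationConfig:
    """Study-design and generator parameters for the synthetic experiment."""

    n_events_per_sample: int = 5000
    ligands: list = field(default_factory=lambda: ["N4", "T4", "G4", "NP68"])
    timepoints: list = field(default_factory=lambda: [1.0, 2.0, 4.0, 6.0])
    n_replicates: int = 2
    # conditions re-acquired in both batches (replicate 1) for normalization
    shared_conditions: list = field(
        default_factory=lambda: [
            ("unstim", 0.0), ("N4", 1.0), ("N4", 6.0), ("G4", 6.0),
        ]
    )
    rate_per_ligand: dict | None = None
    event_offsets: dict | None = None
    transient_durations: dict | None = None
    doublet_fraction: dict | None = None
    dead_fraction: float | None = None
    bead_fraction: float | None = None
    batch_gains: dict | None = None

    def validate(self) -> None:
        if self.n_events_per_sample < 0:
            raise ValueError("n_events_per_sample must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be nonnegative")
        self.shared_conditions = [tuple(c) for c in self.shared_conditions]

    def kinetic_model(self):
        from .simulate import KineticModel

        kwargs = {}
        if self.rate_per_ligand is not None:
            kwargs["rate_per_ligand"] = dict(self.rate_per_ligand)
        if self.event_offsets is not None:
            kwargs["event_offsets"] = dict(self.event_offsets)
        if self.transient_durations is not None:
            kwargs["transient_durations"] = dict(self.transient_durations)
        return KineticModel(**kwargs)

    def intensity_model(self):
        from .simulate import IntensityModel

        kwargs = {}
        if self.doublet_fraction is not None:
            kwargs["doublet_fraction"] = dict(self.doublet_fraction)
        if self.dead_fraction is not None:
            kwargs["dead_fraction"] = self.dead_fraction
        if self.bead_fraction is not None:
            kwargs["bead_fraction"] = self.bead_fraction
        return IntensityModel(**kwargs)


@dataclass
class PreprocessConfig:
    """Transformation, normalization and gating parameters."""

    logicle_t: float = 262144.0
    logicle_w: float = 0.1
    logicle_m: float = 4.5
    logicle_a: float = 0.0
    batch_p: float = 0.001
    fix_zero: bool = True
    mad_k: float = 5.0          # keep cells >= median - mad_k * MAD (TCRb, CD8)
    mad_scaled: bool = True     # use the 1.4826 consistency constant
    event_length_k: float = 5.0  # remove events > median + k * MAD of length
    positivity_quantile: float = 0.995

    def validate(self) -> None:
        if not 0 < self.batch_p < 0.5:
            raise ValueError("batch_p must lie in (0, 0.5)")
        if not 0 < self.positivity_quantile < 1:
            raise ValueError("positivity_quantile must lie in (0, 1)")
        if self.mad_k <= 0 or self.event_length_k <= 0:
            raise ValueError("MAD multipliers must be positive")
        if not (self.logicle_w >= 0 and self.logicle_t > 0 and self.logicle_m > self.logicle_w):
            raise ValueError("invalid logicle parameters")

    def transformer(self):
        from .transforms import LogicleTransform

        return LogicleTransform(
            t=self.logicle_t, w=self.logicle_w, m=self.logicle_m, a=self.logicle_a
        ).fit()


@dataclass
class DAConfig:
    """Hypersphere differential-abundance parameters."""

    tol: float = 0.4
    downsample: int = 200
    min_mean: float = 50.0
    alpha: float = 0.05
    cluster_distance: float = 0.05  # 1 - Pearson r cut for phenotype clusters

    def validate(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class TrajectoryConfig:
    """Trajectory construction and initiation-detection parameters."""

    anchor: str = "pS6"
    markers: list = field(default_factory=lambda: list(ORDERED_MARKERS))
    span: float = 0.2
    n_sample: int = 2000
    n_downsample: int = 5000
    window: float = 0.05
    step: float = 0.01
    k_sd: float = 1.0
    shift_fraction: float = 0.5

    def validate(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if not 0 < self.window < 1 or not 0 < self.step < 1:
            raise ValueError("window and step must lie in (0, 1)")
        if self.k_sd <= 0 or self.shift_fraction < 0:
            raise ValueError("k_sd must be positive and shift_fraction nonnegative")


@dataclass
class AnalysisConfig:
    """Top-level pipeline configuration; one seed drives every stage."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    diff_abundance: DAConfig = field(default_factory=DAConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)

    def validate(self) -> None:
        self.simulation.validate()
        self.preprocess.validate()
        self.diff_abundance.validate()
        self.trajectory.validate()


_SECTIONS = {
    "simulation": SimulationConfig,
    "preprocess": PreprocessConfig,
    "diff_abundance": DAConfig,
    "trajectory": TrajectoryConfig,
}


def _to_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def dump_yaml(config, path) -> None:
    """Write any config dataclass as YAML."""
    d = _to_dict(config)
    d["_type"] = type(config).__name__
    Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_yaml(path, cls=None):
    """Load a config written by :func:`dump_yaml` (or hand-written YAML)."""
    d = yaml.safe_load(Path(path).read_text())
    name = d.pop("_type", None)
    if cls is None:
        classes = {c.__name__: c for c in
                   (AnalysisConfig, *(v for v in _SECTIONS.values()))}
        cls = classes.get(name, AnalysisConfig)
    if cls is AnalysisConfig:
        kwargs = {k: v for k, v in d.items() if k not in _SECTIONS}
        for section, sec_cls in _SECTIONS.items():
            if section in d and d[section] is not None:
                kwargs[section] = sec_cls(**d[section])
        config = AnalysisConfig(**kwargs)
    else:
        config = cls(**d)
    config.validate()
    return config
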