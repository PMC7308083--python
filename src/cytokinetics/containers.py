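"""In-memory containers for mass-cytometry event data and analysis results.

The central object is :class:`EventTable`: an events x channels intensity
matrix (raw, nonnegative ion-count scale unless noted otherwise) together
with per-event sample assignment, a sample metadata sheet and a channel
panel describing what each channel measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: channel roles recognised by the panel
ROLES = {"signalling", "total-protein", "surface", "DNA", "viability", "bead", "technical"}


def default_panel() -> pd.DataFrame:
    """Panel of the 14 markers used in differential-abundance testing plus
    DNA, viability, bead and event-length channels.

    Index is the channel short name (metal_marker); columns are ``marker``,
    ``role`` and, for signalling channels, ``direction`` ("gain" for
    phosphorylation/expression, "loss" for degradation read-outs such as
    IkBa).
    """
    rows = [
        # channel,        marker,    role,          direction
        ("Nd143_pSTAT5", "pSTAT5", "signalling", "gain"),
        ("Nd148_pAKT", "pAKT", "signalling", "gain"),
        ("Sm149_pSLP76", "pSLP76", "signalling", "gain"),
        ("Eu151_pLCK", "pLCK", "signalling", "gain"),
        ("Sm152_IkBa", "IkBa", "signalling", "loss"),
        ("Eu153_pPLCg1", "pPLCg1", "signalling", "gain"),
        ("Er167_pERK12", "pERK12", "signalling", "gain"),
        ("Er168_pZAP70", "pZAP70", "signalling", "gain"),
        ("Yb172_pS6", "pS6", "signalling", "gain"),
        ("Gd160_CD44", "CD44", "surface", "gain"),
        ("Nd145_CD25", "CD25", "surface", "gain"),
        ("Nd146_CD8a", "CD8a", "surface", "gain"),
        ("Sm154_TCRb", "TCRb", "surface", "gain"),
        ("Y89_CD45", "CD45", "surface", "gain"),
        ("Ir191_DNA1", "DNA1", "DNA", "gain"),
        ("Ir193_DNA2", "DNA2", "DNA", "gain"),
        ("Pt195_Viability", "Viability", "viability", "gain"),
        ("Ce140_Bead", "Bead", "bead", "gain"),
        ("Event_length", "Event_length", "technical", "gain"),
    ]
    panel = pd.DataFrame(rows, columns=["channel", "marker", "role", "direction"])
    return panel.set_index("channel")


#: markers included in differential-abundance testing
DA_MARKERS = [
    "pSTAT5", "pAKT", "pSLP76", "pLCK", "IkBa", "pPLCg1", "pERK12",
    "pZAP70", "pS6", "CD8a", "CD44", "CD25", "TCRb", "CD45",
]

#: the four ordered activation events of the trajectory analysis
ORDERED_MARKERS = ["pS6", "pERK12", "pSTAT5", "CD44"]


@dataclass
class EventTable:
    """Events x channels intensity matrix with sample metadata and panel.

    Parameters
    ----------
    data : DataFrame
        One row per event, one column per channel.
    sample_ids : Series
        Sample assignment per event, aligned with ``data``.
    samples : DataFrame
        Sample sheet indexed by sample_id with columns
        ``ligand``, ``time_h``, ``replicate``, ``batch``.
    panel : DataFrame
        Channel panel (see :func:`default_panel`).
    """

    data: pd.DataFrame
    sample_ids: pd.Series
    samples: pd.DataFrame
    panel: pd.DataFrame = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        self.sample_ids = pd.Series(
            np.asarray(self.sample_ids), index=self.data.index, name="sample_id"
        )
        self.validate()

    # -- basic protocol ---------------------------------------------------
    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        if len(self.sample_ids) != len(self.data):
            raise ValueError("sample_ids must align with the event matrix")
        present = set(pd.unique(self.sample_ids))
        known = set(self.samples.index)
        missing = present - known
        if missing:
            raise ValueError(f"sample metadata missing for: {sorted(missing)}")
        unknown_roles = set(self.panel["role"]) - ROLES
        if unknown_roles:
            raise ValueError(f"unknown channel roles: {sorted(unknown_roles)}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    # -- panel lookups ----------------------------------------------------
    def channel_for(self, marker: str) -> str:
        """Channel short name carrying ``marker``."""
        hits = self.panel.index[self.panel["marker"] == marker]
        if len(hits) != 1:
            raise KeyError(f"marker {marker!r} not uniquely present in panel")
        return hits[0]

    def channels_for(self, markers) -> list[str]:
        return [self.channel_for(m) for m in markers]

    def marker_direction(self, marker: str) -> str:
        return str(self.panel.loc[self.channel_for(marker), "direction"])

    def channels_by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [c for c in self.panel.index[self.panel["role"] == role] if c in self.data.columns]

    # -- manipulation -----------------------------------------------------
    def subset(self, mask: np.ndarray) -> "EventTable":
        """Boolean or index subset of events; metadata and panel are shared."""
        data = self.data.loc[np.asarray(mask)] if np.asarray(mask).dtype == bool else self.data.iloc[mask]
        ids = self.sample_ids.loc[data.index]
        return replace(self, data=data, sample_ids=ids)

    def with_data(self, data: pd.DataFrame) -> "EventTable":
        return replace(self, data=data, sample_ids=self.sample_ids.loc[data.index])

    def events_of(self, sample_id: str) -> pd.DataFrame:
        return self.data.loc[self.sample_ids.to_numpy() == sample_id]

    def sample_meta(self, column: str) -> pd.Series:
        """Per-event broadcast of a sample-sheet column."""
        return self.sample_ids.map(self.samples[column])

    @classmethod
    def concat(cls, tables: list["EventTable"]) -> "EventTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        data = pd.concat([t.data for t in tables], ignore_index=True)
        ids = pd.concat([t.sample_ids for t in tables], ignore_index=True)
        samples = pd.concat([t.samples for t in tables])
        samples = samples[~samples.index.duplicated(keep="first")]
        return cls(data=data, sample_ids=ids, samples=samples, panel=tables[0].panel)


@dataclass
class GateResult:
    """Ordered record of a hierarchical gating run.

    ``steps`` holds (name, kept mask, n_before, n_after) per gate; masks are
    nested: each step's kept set is a subset of the previous one's.
    """

    steps: list[tuple[str, np.ndarray, int, int]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, threshold=None) -> None:
        prev = self.final_mask
        mask = np.asarray(mask, dtype=bool)
        if prev is not None:
            if np.any(mask & ~prev):
                raise ValueError(f"gate {name!r} breaks mask nesting")
            n_before = int(prev.sum())
        else:
            n_before = mask.size
        self.steps.append((name, mask, n_before, int(mask.sum())))
        if threshold is not None:
            self.thresholds[name] = threshold

    @property
    def final_mask(self) -> np.ndarray | None:
        return self.steps[-1][1] if self.steps else None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, b, a, b - a) for n, _, b, a in self.steps],
            columns=["gate", "n_before", "n_after", "n_removed"],
        )


@dataclass
class HypersphereSet:
    """Hyperspheres tiling the transformed marker space.

    ``centers`` is hyperspheres x markers (each row an observed cell's
    coordinates), ``counts`` hyperspheres x samples, ``medians`` the median
    marker intensities of the member cells of each hypersphere.
    """

    centers: pd.DataFrame
    counts: pd.DataFrame
    medians: pd.DataFrame
    radius: float
    markers: list[str]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_hyperspheres(self) -> int:
        return len(self.centers)

    def subset(self, keep: np.ndarray) -> "HypersphereSet":
        keep = np.asarray(keep)
        return HypersphereSet(
            centers=self.centers.loc[keep].reset_index(drop=True)
            if keep.dtype == bool else self.centers.iloc[keep].reset_index(drop=True),
            counts=self.counts.loc[keep].reset_index(drop=True)
            if keep.dtype == bool else self.counts.iloc[keep].reset_index(drop=True),
            medians=self.medians.loc[keep].reset_index(drop=True)
            if keep.dtype == bool else self.medians.iloc[keep].reset_index(drop=True),
            radius=self.radius,
            markers=self.markers,
        )


@dataclass
class Trajectory:
    """A pS6-anchored activation trajectory for one ligand.

    Cells are ordered by the anchor marker on the transformed scale;
    ``rank`` is the pseudotime position in [0, 1].
    """

    ligand: str
    data: pd.DataFrame            # ordered cells x marker columns (transformed)
    rank: np.ndarray              # pseudotime in [0, 1], same order as data
    time_h: np.ndarray            # real sampling time per cell
    anchor: str
    timepoints: list[float]

    @property
    def n_cells(self) -> int:
        return len(self.data)


@dataclass
class InitiationResult:
    """Sliding-window initiation call for one marker along a trajectory."""

    marker: str
    window_index: int | None      # None when the threshold was never crossed
    shift_without_threshold: bool
    window: float
    step: float
    k_sd: float
    n_cells: int
    start_mean: float
    start_sd: float

    def __post_init__(self) -> None:
        if self.window_index is not None and self.shift_without_threshold:
            raise ValueError("a window index excludes the shift flag")


@dataclass
class EventOrder:
    """Derived order of activation events along a trajectory."""

    markers: list[str]                 # ordered first -> last when determinable
    ranks: dict[str, int] | None       # marker -> 1-based rank
    determinable: bool
    reason: str | None = None          # "two-failed-threshold" | "shared-window"

    def __post_init__(self) -> None:
        if self.determinable:
            if self.ranks is None or sorted(self.ranks.values()) != list(
                range(1, len(self.ranks) + 1)
            ):
                raise ValueError("ranks must be a permutation of 1..n")


@dataclass
class OrderComparison:
    """Pairwise order-agreement permutation test results."""

    pairs: list[tuple[str, str]]
    msd: list[float]
    pvalues: list[float]
    combined_p: float
    null_method: str
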