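"""Synthetic CyTOF-like snapshot data with known activation kinetics.

The generator realizes a rate-not-order model of T-cell receptor
signalling: every cell draws an activation initiation time from an
exponential law whose rate depends only on ligand potency, and the
downstream programme of activation events (pS6 -> pERK1/2 -> pSTAT5 ->
CD44, with fixed per-marker delays) is identical for every ligand. Marker
intensities are bimodal log-normal on/off mixtures; the DNA channel carries
doublets at ~2x content; dead (cisplatin-high) cells and normalization
beads are mixed in; snapshot sampling emulates fixing cells at 0/1/2/4/6 h.

Ground truth (initiation time, true on/off state per marker, doublet /
dead / bead identity) is returned alongside every event so downstream
stages can be scored exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ORDERED_MARKERS, EventTable, default_panel

__all__ = [
    "KineticModel",
    "MarkerIntensity",
    "IntensityModel",
    "simulate_cells",
    "inject_doublets",
    "simulate_experiment",
]

TRUTH_COLUMNS = ["initiation_time", "is_doublet", "is_live", "is_bead", "constituents"]


@dataclass
class KineticModel:
    """Activation-initiation rates and the fixed event programme.

    ``rate_per_ligand`` holds the initiation rate lambda (1/h) per ligand;
    ``event_offsets`` the delay (h) of each activation event after
    initiation; ``transient_durations`` how long each event stays on
    (``inf`` = sustained). IkBa is a loss-of-signal read-out; its "on"
    state means the protein has been degraded.
    """

    rate_per_ligand: dict = field(
        default_factory=lambda: {"N4": 1.0, "T4": 0.3, "G4": 0.1, "NP68": 0.0}
    )
    event_offsets: dict = field(
        default_factory=lambda: {
            "pS6": 0.0,
            "pERK12": 0.5,
            "pSTAT5": 1.5,
            "CD44": 3.0,
            "pAKT": 0.5,
            "IkBa": 0.5,
            "pSLP76": 0.25,
            "CD25": 3.5,
            "pZAP70": 0.0,
            "pPLCg1": 0.0,
        }
    )
    transient_durations: dict = field(
        default_factory=lambda: {
            "pERK12": 1.5,
            "pAKT": 1.5,
            "IkBa": 2.0,
            "pSLP76": 1.0,
            "pZAP70": 0.25,
            "pPLCg1": 0.25,
        }
    )
    ikba_direction: str = "loss"

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rate_per_ligand.values()):
            raise ValueError("initiation rates must be nonnegative")
        offsets = [self.event_offsets[m] for m in ORDERED_MARKERS if m in self.event_offsets]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("offsets of the four ordered events must be strictly increasing")
        if any(t <= 0 for t in self.transient_durations.values()):
            raise ValueError("transient durations must be positive")

    def duration(self, marker: str) -> float:
        return self.transient_durations.get(marker, math.inf)


@dataclass
class MarkerIntensity:
    """Log10-normal on/off mixture for one marker.

    For gain markers ``on_mean > off_mean``; for loss markers (IkBa) the
    "on" (actively signalling, degraded) state is dimmer than rest. When
    ``ramp_tau`` is set, the on-state mean rises from the off level towards
    ``on_mean`` with a saturating exponential in the time since the event
    switched on, giving graded progression information (used for pS6 and
    CD44).
    """

    off_mean: float
    off_sd: float
    on_mean: float
    on_sd: float
    ramp_tau: float | None = None

    def __post_init__(self) -> None:
        if self.off_sd <= 0 or self.on_sd <= 0:
            raise ValueError("intensity sds must be positive")


def _default_markers() -> dict:
    base = dict(off_mean=0.7, off_sd=0.25, on_mean=1.9, on_sd=0.18)
    markers = {
        "pS6": MarkerIntensity(0.7, 0.25, 2.1, 0.12, ramp_tau=1.2),
        "pERK12": MarkerIntensity(**base),
        "pSTAT5": MarkerIntensity(**base),
        "CD44": MarkerIntensity(0.9, 0.22, 2.2, 0.15, ramp_tau=1.5),
        "pAKT": MarkerIntensity(**base),
        "pSLP76": MarkerIntensity(0.7, 0.25, 1.6, 0.2),
        "pZAP70": MarkerIntensity(0.5, 0.25, 1.3, 0.2),
        # inhibitory phospho present at rest; treated as constitutive here
        "pLCK": MarkerIntensity(1.6, 0.2, 1.6, 0.2),
        "pPLCg1": MarkerIntensity(0.5, 0.25, 1.3, 0.2),
        "CD25": MarkerIntensity(0.7, 0.25, 2.0, 0.2),
        # loss read-out: resting cells are bright, signalling cells dim
        "IkBa": MarkerIntensity(1.8, 0.15, 0.6, 0.25),
        # constitutive surface markers (no kinetics: on == off)
        "CD8a": MarkerIntensity(2.2, 0.12, 2.2, 0.12),
        "TCRb": MarkerIntensity(2.2, 0.12, 2.2, 0.12),
        "CD45": MarkerIntensity(2.5, 0.1, 2.5, 0.1),
    }
    return markers


@dataclass
class IntensityModel:
    """Channel intensity distributions and nuisance-event fractions."""

    markers: dict = field(default_factory=_default_markers)
    dna_mean: float = 2.6          # log10 counts of a singlet
    dna_sd: float = 0.043          # ~= sigma/mu of 0.1 on the raw scale
    viability_live: tuple = (0.5, 0.3)
    viability_dead: tuple = (2.5, 0.2)
    bead_signal: tuple = (2.8, 0.1)     # bead events on the bead channel
    bead_background: tuple = (0.2, 0.2)  # cells on the bead channel
    event_length: tuple = (30.0, 3.0)
    doublet_fraction: dict = field(
        default_factory=lambda: {"N4": 0.10, "T4": 0.06, "G4": 0.04, "NP68": 0.02}
    )
    dead_fraction: float = 0.03
    bead_fraction: float = 0.02

    def __post_init__(self) -> None:
        fracs = list(self.doublet_fraction.values()) + [self.dead_fraction, self.bead_fraction]
        if any(not 0 <= f < 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1)")
        if self.dead_fraction + self.bead_fraction >= 1:
            raise ValueError("dead + bead fractions must be < 1")
        for name, mk in self.markers.items():
            if name == "IkBa":
                continue
            if mk.ramp_tau is not None and mk.ramp_tau <= 0:
                raise ValueError("ramp_tau must be positive")


def _log10_normal(rng: np.random.Generator, mean, sd, n: int) -> np.ndarray:
    return 10.0 ** rng.normal(mean, sd, size=n)


def simulate_cells(
    model: KineticModel,
    intensity: IntensityModel,
    n: int,
    ligand: str,
    time_h: float,
    seed,
    sample_id: str | None = None,
    sample_meta: dict | None = None,
) -> tuple[EventTable, pd.DataFrame]:
    """Simulate ``n`` snapshot events of one sample.

    Each live cell draws an initiation time T ~ Exponential(lambda_ligand)
    (T = +inf when lambda = 0); event ``m`` is on iff
    ``T + delta_m <= time_h < T + delta_m + tau_m``. A fraction of events
    are dead cells (cisplatin-high, no signalling) or normalization beads.
    Doublets are injected separately with :func:`inject_doublets`.

    Returns the event table and the per-event ground-truth frame.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if ligand not in model.rate_per_ligand:
        raise KeyError(f"unknown ligand {ligand!r}; known: {sorted(model.rate_per_ligand)}")
    if time_h < 0:
        raise ValueError("time_h must be nonnegative")
    rng = np.random.default_rng(seed)
    panel = default_panel()
    sample_id = sample_id or f"{ligand}_{time_h:g}h"

    u = rng.random(n)
    is_bead = u < intensity.bead_fraction
    is_dead = (~is_bead) & (u < intensity.bead_fraction + intensity.dead_fraction)
    is_live = ~(is_bead | is_dead)

    lam = model.rate_per_ligand[ligand]
    t_init = np.full(n, np.inf)
    if lam > 0:
        t_init = rng.exponential(1.0 / lam, size=n)
    t_init[~is_live] = np.inf
    age = time_h - t_init  # time since initiation; negative = not initiated

    data = {}
    truth = pd.DataFrame(
        {
            "initiation_time": t_init,
            "is_doublet": np.zeros(n, dtype=bool),
            "is_live": is_live,
            "is_bead": is_bead,
            "constituents": [None] * n,
        }
    )

    for channel, row in panel.iterrows():
        marker = row["marker"]
        if marker in intensity.markers:
            mk = intensity.markers[marker]
            delta = model.event_offsets.get(marker)
            if delta is None:
                state = np.zeros(n, dtype=bool)  # constitutive marker
            else:
                tau = model.duration(marker)
                event_age = age - delta
                state = (event_age >= 0) & (event_age < tau)
            z = rng.normal(size=n)
            mean = np.where(state, mk.on_mean, mk.off_mean)
            sd = np.where(state, mk.on_sd, mk.off_sd)
            if mk.ramp_tau is not None and delta is not None:
                ramp = 1.0 - np.exp(-np.maximum(age - delta, 0.0) / mk.ramp_tau)
                mean = np.where(state, mk.off_mean + (mk.on_mean - mk.off_mean) * ramp, mean)
            values = 10.0 ** (mean + sd * z)
            values[is_bead] = _log10_normal(
                rng, *intensity.bead_background, int(is_bead.sum())
            )
            data[channel] = values
            if delta is not None:
                truth[f"state_{marker}"] = state & is_live
        elif row["role"] == "DNA":
            v = _log10_normal(rng, intensity.dna_mean, intensity.dna_sd, n)
            v[is_bead] = _log10_normal(rng, 0.3, 0.2, int(is_bead.sum()))
            data[channel] = v
        elif row["role"] == "viability":
            v = _log10_normal(rng, *intensity.viability_live, n)
            v[is_dead] = _log10_normal(rng, *intensity.viability_dead, int(is_dead.sum()))
            v[is_bead] = _log10_normal(rng, 0.2, 0.2, int(is_bead.sum()))
            data[channel] = v
        elif row["role"] == "bead":
            v = _log10_normal(rng, *intensity.bead_background, n)
            v[is_bead] = _log10_normal(rng, *intensity.bead_signal, int(is_bead.sum()))
            data[channel] = v
        elif channel == "Event_length":
            data[channel] = np.clip(
                rng.normal(*intensity.event_length, size=n), 1.0, None
            )

    meta = {"ligand": ligand, "time_h": time_h, "replicate": 1, "batch": 1}
    meta.update(sample_meta or {})
    samples = pd.DataFrame([meta], index=pd.Index([sample_id], name="sample_id"))
    table = EventTable(
        data=pd.DataFrame(data),
        sample_ids=pd.Series([sample_id] * n),
        samples=samples,
        panel=panel,
    )
    return table, truth


def inject_doublets(
    events: EventTable, truth: pd.DataFrame, fraction: float, seed
) -> tuple[EventTable, pd.DataFrame]:
    """Fuse pairs of singlet cells into doublet events by channel summation.

    ``fraction`` is the fraction of the original cells consumed by doublet
    formation; each doublet consumes two cells, so ``n * fraction / 2``
    doublet events are created. Ion counts add in a fused event, so the
    DNA content is ~2x and every other channel is the sum of the pair.
    """
    if not 0 <= fraction < 1:
        raise ValueError("doublet fraction must lie in [0, 1)")
    eligible = np.flatnonzero(
        ~truth["is_bead"].to_numpy() & ~truth["is_doublet"].to_numpy()
    )
    n_pairs = int(round(len(eligible) * fraction / 2.0))
    if n_pairs == 0:
        if fraction > 0 and len(eligible) < 2:
            warnings.warn("fewer than 2 singlets available; no doublets formed")
        return events, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=2 * n_pairs, replace=False)
    first, second = chosen[:n_pairs], chosen[n_pairs:]

    mat = events.data.to_numpy()
    fused = mat[first] + mat[second]
    keep = np.ones(events.n_events, dtype=bool)
    keep[chosen] = False

    data = pd.DataFrame(
        np.vstack([mat[keep], fused]), columns=events.data.columns
    )
    sample_ids = pd.Series(
        np.concatenate(
            [events.sample_ids.to_numpy()[keep], events.sample_ids.to_numpy()[first]]
        )
    )

    state_cols = [c for c in truth.columns if c.startswith("state_")]
    fused_truth = pd.DataFrame(
        {
            "initiation_time": np.minimum(
                truth["initiation_time"].to_numpy()[first],
                truth["initiation_time"].to_numpy()[second],
            ),
            "is_doublet": True,
            "is_live": truth["is_live"].to_numpy()[first]
            & truth["is_live"].to_numpy()[second],
            "is_bead": False,
            "constituents": [f"{i}|{j}" for i, j in zip(first, second)],
        }
    )
    for c in state_cols:
        fused_truth[c] = (
            truth[c].to_numpy()[first] | truth[c].to_numpy()[second]
        )
    new_truth = pd.concat(
        [truth.loc[keep].reset_index(drop=True), fused_truth], ignore_index=True
    )
    table = EventTable(
        data=data, sample_ids=sample_ids, samples=events.samples, panel=events.panel
    )
    return table, new_truth


def simulate_experiment(config, seed, out_dir=None):
    """Simulate a full stimulation time course over ligands x timepoints,
    two replicates split across two batches, with shared samples duplicated
    in both batches for range normalization.

    ``config`` is a :class:`~cytokinetics.config.SimulationConfig`. When
    ``out_dir`` is given, per-sample FCS files, the sample sheet, the
    ground truth and the config are written there.

    Returns a dict with keys ``events`` (one concatenated
    :class:`EventTable`), ``truth`` (ground-truth frame with a sample_id
    column) and ``samples`` (the sample sheet).
    """
    from .config import SimulationConfig  # local import to avoid a cycle

    if not isinstance(config, SimulationConfig):
        raise TypeError("config must be a SimulationConfig")
    config.validate()
    model = config.kinetic_model()
    intensity = config.intensity_model()
    root = np.random.SeedSequence(seed)
    # one spawned stream per (replicate, sample) plus one for batch gains
    gain_seed, *_ = root.spawn(1)
    rng_gain = np.random.default_rng(gain_seed)

    panel = default_panel()
    gains = config.batch_gains
    if gains is None:
        gains = {
            ch: float(g)
            for ch, g in zip(panel.index, rng_gain.uniform(0.85, 1.18, len(panel.index)))
            if ch != "Event_length"
        }

    tables: list[EventTable] = []
    truths: list[pd.DataFrame] = []
    rows = []

    def add_sample(table, truth, sample_id, ligand, time_h, replicate, batch, shared_group):
        table.samples.loc[sample_id, ["replicate", "batch"]] = [replicate, batch]
        tables.append(table)
        t = truth.copy()
        t.insert(0, "sample_id", sample_id)
        truths.append(t)
        rows.append(
            dict(sample_id=sample_id, ligand=ligand, time_h=time_h,
                 replicate=replicate, batch=batch, shared_group=shared_group)
        )

    conditions = [("unstim", 0.0)] + [
        (lig, t) for lig in config.ligands for t in config.timepoints
    ]
    shared = set(config.shared_conditions)
    children = iter(root.spawn(len(conditions) * config.n_replicates * 2))
    for replicate in range(1, config.n_replicates + 1):
        batch = 1 if replicate <= config.n_replicates / 2 else 2
        for ligand, time_h in conditions:
            sim_ligand = "NP68" if ligand == "unstim" else ligand
            sid = f"r{replicate}_{ligand}_{time_h:g}h"
            table, truth = simulate_cells(
                model, intensity, config.n_events_per_sample, sim_ligand,
                time_h, next(children), sample_id=sid,
                sample_meta={"ligand": ligand, "replicate": replicate, "batch": batch},
            )
            table, truth = inject_doublets(
                table, truth,
                intensity.doublet_fraction.get(sim_ligand, 0.0), next(children),
            )
            is_shared = replicate == 1 and (ligand, time_h) in shared
            add_sample(table, truth, sid, ligand, time_h, replicate, batch,
                       sid if is_shared else None)
            if batch == 2:
                _apply_gains(table, gains)
            if is_shared:
                # re-acquisition of the same sample in the other pool
                dup_data = table.data.copy()
                dup_id = sid + "_b2"
                dup = EventTable(
                    data=dup_data,
                    sample_ids=pd.Series([dup_id] * len(dup_data)),
                    samples=pd.DataFrame(
                        [dict(ligand=ligand, time_h=time_h, replicate=replicate, batch=2)],
                        index=pd.Index([dup_id], name="sample_id"),
                    ),
                    panel=table.panel,
                )
                _apply_gains(dup, gains)
                add_sample(dup, truth, dup_id, ligand, time_h, replicate, 2, sid)

    events = EventTable.concat(tables)
    truth = pd.concat(truths, ignore_index=True)
    sheet = pd.DataFrame(rows).set_index("sample_id")
    events.samples = sheet
    result = {"events": events, "truth": truth, "samples": sheet, "batch_gains": gains}

    if out_dir is not None:
        _write_dataset(result, config, out_dir)
    return result


def _apply_gains(table: EventTable, gains: dict) -> None:
    for ch, g in gains.items():
        if ch in table.data.columns:
            table.data[ch] = table.data[ch] * g


def _write_dataset(result, config, out_dir) -> None:
    from pathlib import Path

    from . import fcs
    from .config import dump_yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: EventTable = result["events"]
    for sid in result["samples"].index:
        fcs.write_fcs(out / f"{sid}.fcs", events.events_of(sid))
    result["samples"].to_csv(out / "samples.csv")
    result["truth"].to_csv(out / "truth.csv", index=False)
    dump_yaml(config, out / "simulation_config.yaml")
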