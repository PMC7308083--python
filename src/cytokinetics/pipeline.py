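"""End-to-end orchestration: simulate -> preprocess -> differential
abundance -> trajectory, with one config, per-stage seeds and a markdown
report. Every stage writes its artifacts (plus the config and seed) into
its own subdirectory of ``out_dir``."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_abundance as da
from . import trajectory as tj
from .config import AnalysisConfig, dump_yaml
from .containers import ORDERED_MARKERS, EventTable, default_panel
from .preprocess import (
    PositivityThreshold,
    combinatorial_states,
    gate_hierarchy,
    normalize_batch_range,
    summarize_fractions,
)
from .simulate import simulate_experiment
from .transforms import transform_table

log = logging.getLogger("cytokinetics")

STAGES = ("simulate", "preprocess", "da", "trajectory")


def stage_seeds(seed: int) -> dict[str, int]:
    """Split one global seed into per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(STAGES, states)}


def config_hash(config: AnalysisConfig) -> str:
    import dataclasses

    blob = yaml.safe_dump(json.loads(json.dumps(dataclasses.asdict(config), default=str)))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_dataset(path) -> dict:
    """Read a dataset directory written by the simulate stage."""
    from . import fcs

    path = Path(path)
    samples = pd.read_csv(path / "samples.csv", index_col="sample_id")
    tables = []
    for sid in samples.index:
        data = fcs.read_fcs(path / f"{sid}.fcs")
        tables.append(
            EventTable(
                data=data,
                sample_ids=pd.Series([sid] * len(data)),
                samples=samples.loc[[sid]],
                panel=default_panel(),
            )
        )
    events = EventTable.concat(tables)
    events.samples = samples
    truth_path = path / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return {"events": events, "truth": truth, "samples": samples}


def run_pipeline(config: AnalysisConfig, stages=STAGES, out_dir="results") -> dict:
    """Run the requested stages in order; returns the accumulated state."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    chash = config_hash(config)
    dump_yaml(config, out / "config.yaml")
    (out / "run.json").write_text(json.dumps(
        {"config_hash": chash, "seeds": seeds, "stages": list(stages)}, indent=2
    ))
    state: dict = {"config": config, "seeds": seeds}

    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s (seed %d)", stage, seeds[stage])
        _RUNNERS[stage](state, config, out, seeds[stage])

    _write_report(state, out)
    return state


def _stage_simulate(state, config, out, seed):
    state["dataset"] = simulate_experiment(config.simulation, seed, out / "simulate")


def _stage_preprocess(state, config, out, seed):
    pre = config.preprocess
    if "dataset" not in state:
        sim_dir = out / "simulate"
        if not sim_dir.exists():
            raise FileNotFoundError(f"no simulated dataset at {sim_dir}")
        state["dataset"] = load_dataset(sim_dir)
    events = state["dataset"]["events"]
    transformer = pre.transformer()
    transformed = transform_table(events, transformer)
    # batch range normalization on the shared samples, then keep one
    # technical replicate of each shared sample
    if "shared_group" in transformed.samples.columns and (
        transformed.samples["shared_group"].notna().any()
        and transformed.samples["batch"].nunique() > 1
    ):
        transformed, normalizer = normalize_batch_range(
            transformed, p=pre.batch_p, fix_zero=pre.fix_zero
        )
        state["normalizer"] = normalizer
        dupes = transformed.samples.index[
            transformed.samples.index.str.endswith("_b2")
        ]
        keep = ~transformed.sample_ids.isin(dupes).to_numpy()
        transformed = transformed.subset(keep)
        transformed.samples = transformed.samples.drop(index=dupes)

    gated, gate_result = gate_hierarchy(transformed, pre, transformer)
    state["gated"] = gated
    state["gate_result"] = gate_result

    unstim = gated.subset(gated.sample_meta("ligand").to_numpy() == "unstim")
    thresholds = PositivityThreshold(quantile=pre.positivity_quantile).fit(unstim)
    state["thresholds"] = thresholds
    positives = thresholds.predict(gated)
    state["positives"] = positives
    fractions = summarize_fractions(gated, positives)
    group = (
        gated.sample_meta("ligand").astype(str)
        + "_" + gated.sample_meta("time_h").astype(str)
    )
    states16 = combinatorial_states(positives, group, ORDERED_MARKERS)
    stage_dir = out / "preprocess"
    stage_dir.mkdir(exist_ok=True)
    gate_result.summary().to_csv(stage_dir / "gate_report.csv", index=False)
    (stage_dir / "gate_report.json").write_text(json.dumps(
        {
            "steps": gate_result.summary().to_dict("records"),
            "thresholds": {k: float(v) for k, v in gate_result.thresholds.items()},
        }, indent=2,
    ))
    fractions.to_csv(stage_dir / "positive_fractions.csv", index=False)
    states16.to_csv(stage_dir / "combinatorial_states.csv")
    gated.data.assign(sample_id=gated.sample_ids.to_numpy()).to_csv(
        stage_dir / "gated_events.csv", index=False
    )
    state["fractions"] = fractions
    state["states16"] = states16


def _stage_da(state, config, out, seed):
    cfg = config.diff_abundance
    gated: EventTable = state["gated"]
    eq = da.downsample_equal(gated, seed)
    hs = da.build_hyperspheres(eq, tol=cfg.tol, downsample=cfg.downsample)
    hs = da.filter_hyperspheres(hs, min_mean=cfg.min_mean)
    samples = eq.samples.copy()
    samples["condition"] = np.where(
        samples["ligand"].astype(str) == "unstim", "unstim",
        samples["ligand"].astype(str) + "_"
        + samples["time_h"].astype(float).map("{:g}h".format),
    )
    totals = eq.sample_ids.value_counts().reindex(hs.counts.columns).to_numpy()
    tester = da.DifferentialAbundanceTest(
        alpha=cfg.alpha, cluster_distance=cfg.cluster_distance
    ).fit(hs, samples, thresholds=state["thresholds"].thresholds_, totals=totals)
    state["hyperspheres"] = hs
    state["da_results"] = tester.results_
    stage_dir = out / "da"
    stage_dir.mkdir(exist_ok=True)
    table = pd.concat(
        [hs.centers.add_prefix("center_"), hs.medians.add_prefix("median_"),
         tester.results_.reset_index(drop=True)], axis=1,
    )
    table.to_csv(stage_dir / "hyperspheres.csv", index=False)


def _stage_trajectory(state, config, out, seed):
    cfg = config.trajectory
    gated: EventTable = state["gated"]
    ligands = [
        l for l in pd.unique(gated.sample_meta("ligand"))
        if l not in ("unstim", "NP68")
    ]
    replicates = sorted(pd.unique(gated.sample_meta("replicate")))
    seeds = np.random.SeedSequence(seed).generate_state(
        len(replicates) * len(ligands) * (1 + len(cfg.markers))
    ) % (2**31)
    seed_iter = iter(int(s) for s in seeds)
    per_replicate = {}
    for rep in replicates:
        rep_mask = gated.sample_meta("replicate").to_numpy() == rep
        rep_events = gated.subset(rep_mask)
        lig = rep_events.sample_meta("ligand").to_numpy()
        t_h = rep_events.sample_meta("time_h").to_numpy()
        unstim = rep_events.subset(lig == "unstim")
        orders, initiations = {}, {}
        for ligand in ligands:
            stim = rep_events.subset((lig == ligand) & (t_h > 0))
            if stim.n_events == 0:
                continue
            traj = tj.build_trajectory(
                stim, unstim, anchor=cfg.anchor, seed=next(seed_iter)
            )
            inits = {
                m: tj.detect_initiation(
                    traj, m, n_downsample=cfg.n_downsample, window=cfg.window,
                    step=cfg.step, k_sd=cfg.k_sd,
                    shift_fraction=cfg.shift_fraction, seed=next(seed_iter),
                )
                for m in cfg.markers
            }
            initiations[ligand] = inits
            orders[ligand] = tj.order_events(inits)
        comparison = tj.compare_orders(orders, seed=seeds[0])
        per_replicate[rep] = {
            "orders": orders, "initiations": initiations, "comparison": comparison,
        }
    # one representative comparison per replicate (strongest vs weakest
    # ligand) multiplies into the across-replicate combined probability
    rep_ps = [
        r["comparison"].pvalues[_extreme_pair_index(r["comparison"], ligands)]
        for r in per_replicate.values()
        if r["comparison"].pvalues
    ]
    combined = tj.combine_order_pvalues(rep_ps) if rep_ps else float("nan")
    state["trajectories"] = per_replicate
    state["combined_p"] = combined
    stage_dir = out / "trajectory"
    stage_dir.mkdir(exist_ok=True)
    payload = {
        "combined_p": combined,
        "combined_p_3sf": float(f"{combined:.3g}") if combined == combined else None,
        "replicates": {
            str(rep): {
                "orders": {
                    lig: {
                        "determinable": o.determinable,
                        "order": o.markers if o.determinable else None,
                        "reason": o.reason,
                    }
                    for lig, o in r["orders"].items()
                },
                "pairs": [list(p) for p in r["comparison"].pairs],
                "msd": r["comparison"].msd,
                "pvalues": r["comparison"].pvalues,
            }
            for rep, r in per_replicate.items()
        },
    }
    (stage_dir / "event_orders.json").write_text(json.dumps(payload, indent=2))


def _extreme_pair_index(comparison, ligands) -> int:
    want = tuple(sorted((ligands[0], ligands[-1])))
    for i, pair in enumerate(comparison.pairs):
        if tuple(sorted(pair)) == want:
            return i
    return 0


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "da": _stage_da,
    "trajectory": _stage_trajectory,
}


def _write_report(state, out: Path) -> None:
    lines = ["# cytokinetics pipeline report", ""]
    lines += [f"- config hash: {config_hash(state['config'])}",
              f"- stage seeds: {state['seeds']}", ""]
    if "gate_result" in state:
        lines += ["## Gating attrition", "",
                  state["gate_result"].summary().to_markdown(index=False), ""]
    if "da_results" in state:
        res = state["da_results"]
        sig = res["significant"]
        lines += [
            "## Differential abundance", "",
            f"- hyperspheres tested: {len(res)}",
            f"- significant (spatial FDR): {int(sig.sum())}",
        ]
        if sig.any():
            counts = res.loc[sig, "phenotype"].value_counts().to_dict()
            lines += [f"- phenotype labels among significant: {counts}"]
        lines += [""]
    if "trajectories" in state:
        lines += ["## Event order", ""]
        for rep, r in state["trajectories"].items():
            for lig, o in r["orders"].items():
                desc = " < ".join(o.markers) if o.determinable else f"indeterminate ({o.reason})"
                lines += [f"- replicate {rep}, {lig}: {desc}"]
            lines += [f"- replicate {rep} pair p-values: "
                      f"{[f'{p:.4g}' for p in r['comparison'].pvalues]}"]
        lines += [f"- combined p (one comparison per replicate): "
                  f"{state['combined_p']:.3g}", ""]
    (out / "report.md").write_text("\n".join(lines))
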