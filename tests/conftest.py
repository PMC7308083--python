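import numpy as np
import pandas as pd
import pytest

import cytokinetics as ck


def clean_intensity(**overrides) -> ck.IntensityModel:
    """Intensity model without nuisance events (no beads/dead/doublets)."""
    kwargs = dict(dead_fraction=0.0, bead_fraction=0.0,
                  doublet_fraction={"N4": 0.0, "T4": 0.0, "G4": 0.0, "NP68": 0.0})
    kwargs.update(overrides)
    return ck.IntensityModel(**kwargs)


@pytest.fixture(scope="session")
def kinetic_model():
    return ck.KineticModel()


@pytest.fixture(scope="session")
def small_experiment():
    """A small two-batch experiment with shared samples and ground truth."""
    cfg = ck.SimulationConfig(n_events_per_sample=1500)
    cfg.validate()
    return ck.simulate_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def gated_experiment(small_experiment):
    transformed = ck.transform_table(small_experiment["events"])
    gated, report = ck.gate_hierarchy(transformed)
    return {"gated": gated, "report": report, "transformed": transformed}


def make_event_table(data: pd.DataFrame, sample_ids=None, samples=None):
    """Assemble a minimal EventTable around an arbitrary data frame."""
    n = len(data)
    if sample_ids is None:
        sample_ids = ["s1"] * n
    if samples is None:
        uniq = pd.unique(pd.Series(sample_ids))
        samples = pd.DataFrame(
            {"ligand": "N4", "time_h": 1.0, "replicate": 1, "batch": 1},
            index=pd.Index(uniq, name="sample_id"),
        )
    panel = ck.default_panel()
    extra = [c for c in data.columns if c not in panel.index]
    if extra:
        panel = pd.concat([
            panel,
            pd.DataFrame({"marker": extra, "role": "signalling",
                          "direction": "gain"}, index=pd.Index(extra)),
        ])
    return ck.EventTable(data=data, sample_ids=pd.Series(sample_ids),
                         samples=samples, panel=panel)
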