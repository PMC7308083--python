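import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytokinetics as ck
from cytokinetics.preprocess import mad
from conftest import make_event_table


def two_batch_table(gain: float = 1.0, n: int = 4000, seed: int = 0):
    """One biological sample acquired in two batches; batch 2 distorted by
    ``gain`` on pS6."""
    rng = np.random.default_rng(seed)
    base = pd.DataFrame({
        "Yb172_pS6": rng.lognormal(1.0, 0.5, n),
        "Er167_pERK12": rng.lognormal(0.5, 0.4, n),
    })
    b2 = base.copy()
    b2["Yb172_pS6"] = b2["Yb172_pS6"] * gain
    data = pd.concat([base, b2], ignore_index=True)
    ids = ["shared_b1"] * n + ["shared_b2"] * n
    samples = pd.DataFrame(
        {"ligand": "N4", "time_h": 1.0, "replicate": 1, "batch": [1, 2],
         "shared_group": "g"},
        index=pd.Index(["shared_b1", "shared_b2"], name="sample_id"),
    )
    return make_event_table(data, ids, samples)


class TestBatchRangeNormalization:
    def test_identical_batches_give_identity(self):
        et = two_batch_table(gain=1.0)
        norm = ck.BatchRangeNormalizer().fit(et)
        assert np.allclose(norm.scale_.to_numpy(), 1.0, atol=1e-9)

    def test_recovers_planted_twofold_distortion(self):
        et = two_batch_table(gain=2.0)
        norm = ck.BatchRangeNormalizer().fit(et)
        rel = norm.relative_scale(2, 1)["Yb172_pS6"]
        assert rel == pytest.approx(0.5, abs=0.01)
        out = norm.transform(et)
        # shared-sample upper quantiles agree across batches afterwards
        q1 = out.events_of("shared_b1")["Yb172_pS6"].quantile(0.999)
        q2 = out.events_of("shared_b2")["Yb172_pS6"].quantile(0.999)
        assert q2 == pytest.approx(q1, rel=0.01)

    def test_fix_zero_maps_zero_to_zero(self):
        et = two_batch_table(gain=2.0)
        et.data.iloc[0, 0] = 0.0
        norm = ck.BatchRangeNormalizer(fix_zero=True).fit(et)
        out = norm.transform(et)
        assert out.data.iloc[0, 0] == 0.0

    def test_no_shared_samples_errors(self):
        et = two_batch_table()
        et.samples = et.samples.drop(columns=["shared_group"])
        with pytest.raises(ValueError, match="shared"):
            ck.BatchRangeNormalizer().fit(et)

    def test_bad_p_errors(self):
        with pytest.raises(ValueError, match="p must"):
            ck.BatchRangeNormalizer(p=0.7).fit(two_batch_table())


class TestNormalizeToChannel:
    def test_hand_arithmetic(self):
        data = pd.DataFrame({"Yb172_pS6": [6.0], "Ir191_DNA1": [3.0]})
        et = make_event_table(data)
        # reference median DNA = 3 in-sample; force 2 by adding events
        data2 = pd.DataFrame({"Yb172_pS6": [6.0, 0.0, 0.0],
                              "Ir191_DNA1": [3.0, 2.0, 2.0]})
        et2 = make_event_table(data2)
        out, flagged = ck.normalize_to_channel(
            et2, ["Yb172_pS6"], "Ir191_DNA1", "s1"
        )
        assert out.data["Yb172_pS6"].iloc[0] == pytest.approx(6.0 / 3.0 * 2.0)
        assert not flagged.any()

    def test_identity_when_denominator_equals_reference_median(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({
            "Yb172_pS6": rng.lognormal(1, 0.3, 100),
            "Ir191_DNA1": np.full(100, 5.0),
        })
        et = make_event_table(data)
        out, _ = ck.normalize_to_channel(et, ["Yb172_pS6"], "Ir191_DNA1", "s1")
        assert np.allclose(out.data["Yb172_pS6"], data["Yb172_pS6"])

    def test_perfect_doublet_returns_to_singlet_value(self):
        data = pd.DataFrame({
            "Yb172_pS6": [4.0, 8.0], "Ir191_DNA1": [5.0, 10.0],
        })
        et = make_event_table(data)
        out, _ = ck.normalize_to_channel(et, ["Yb172_pS6"], "Ir191_DNA1", "s1")
        assert out.data["Yb172_pS6"].iloc[0] == pytest.approx(
            out.data["Yb172_pS6"].iloc[1]
        )

    def test_nonpositive_denominator_flagged(self):
        data = pd.DataFrame({"Yb172_pS6": [1.0, 2.0], "Ir191_DNA1": [0.0, 4.0]})
        et = make_event_table(data)
        out, flagged = ck.normalize_to_channel(et, ["Yb172_pS6"], "Ir191_DNA1", "s1")
        assert flagged.tolist() == [True, False]

    def test_empty_reference_errors(self):
        data = pd.DataFrame({"Yb172_pS6": [1.0], "Ir191_DNA1": [1.0]})
        et = make_event_table(data)
        with pytest.raises(ValueError, match="empty"):
            ck.normalize_to_channel(et, ["Yb172_pS6"], "Ir191_DNA1", "nope")


class TestDNAContent:
    def test_separated_populations_classified_accurately(self):
        rng = np.random.default_rng(0)
        n = 5000
        mu = 400.0
        singlets = rng.normal(mu, 0.1 * mu, n)
        doublets = rng.normal(2 * mu, 0.1 * 2 * mu, n)
        x = ck.logicle(np.concatenate([singlets, doublets]))
        labels, clf = ck.classify_dna_content(x)
        truth = np.array([1] * n + [2] * n)
        assert (labels == truth).mean() >= 0.99

    def test_constant_dna_all_singlet(self):
        with pytest.warns(UserWarning):
            labels, clf = ck.classify_dna_content(np.full(100, 2.0))
        assert (labels == 1).all()

    def test_unimodal_all_singlet(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="no second"):
            labels, _ = ck.classify_dna_content(rng.normal(2.0, 0.05, 3000))
        assert (labels == 1).all()

    def test_recovers_planted_doublet_fraction(self):
        rng = np.random.default_rng(2)
        n = 10000
        is_doub = rng.random(n) < 0.30
        raw = np.where(is_doub, rng.normal(800, 80, n), rng.normal(400, 40, n))
        labels, _ = ck.classify_dna_content(ck.logicle(raw))
        assert (labels == 2).mean() == pytest.approx(0.30, abs=0.02)


class TestGateHierarchy:
    def test_clean_data_survives(self, kinetic_model):
        from conftest import clean_intensity

        et, _ = ck.simulate_cells(kinetic_model, clean_intensity(), 20000, "N4", 2.0, seed=0)
        transformed = ck.transform_table(et)
        gated, report = ck.gate_hierarchy(transformed)
        assert gated.n_events / et.n_events >= 0.99

    def test_nested_masks_and_attrition_bookkeeping(self, gated_experiment):
        report = gated_experiment["report"]
        steps = report.steps
        assert [s[0] for s in steps] == [
            "beads", "event_length", "dna_singlets", "live", "tcrb", "cd8"
        ]
        prev = None
        for name, mask, n_before, n_after in steps:
            if prev is not None:
                assert not np.any(mask & ~prev)
                assert n_before == prev.sum()
            assert n_after == mask.sum()
            prev = mask

    def test_planted_beads_removed(self, kinetic_model):
        from conftest import clean_intensity

        intensity = clean_intensity(bead_fraction=0.05)
        et, truth = ck.simulate_cells(kinetic_model, intensity, 20000, "N4", 2.0, seed=1)
        transformed = ck.transform_table(et)
        gated, report = ck.gate_hierarchy(transformed)
        removed = report.steps[0][2] - report.steps[0][3]
        assert removed / et.n_events == pytest.approx(0.05, abs=0.01)

    def test_constant_channel_mad_removes_nothing(self, kinetic_model):
        from conftest import clean_intensity

        et, _ = ck.simulate_cells(kinetic_model, clean_intensity(), 5000, "N4", 2.0, seed=2)
        et.data[et.channel_for("TCRb")] = 100.0  # MAD = 0 -> keep everything
        transformed = ck.transform_table(et)
        gated, report = ck.gate_hierarchy(transformed)
        tcrb_step = dict((s[0], (s[2], s[3])) for s in report.steps)["tcrb"]
        assert tcrb_step[0] == tcrb_step[1]

    def test_missing_channel_named_in_error(self, kinetic_model):
        from conftest import clean_intensity

        et, _ = ck.simulate_cells(kinetic_model, clean_intensity(), 100, "N4", 1.0, seed=0)
        et.data = et.data.drop(columns=["Event_length"])
        with pytest.raises(ValueError, match="Event_length"):
            ck.gate_hierarchy(ck.transform_table(et))


class TestPositivity:
    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(3)
        unstim = rng.normal(1.0, 0.2, 20000)
        stim = rng.normal(1.0, 0.2, 20000)
        pos, thr = ck.threshold_positive(stim, unstim)
        # ~0.5% by construction of the 99.5th-percentile threshold
        assert pos.mean() == pytest.approx(0.005, abs=0.003)

    def test_separated_on_state_fully_positive(self):
        rng = np.random.default_rng(4)
        unstim = rng.normal(1.0, 0.1, 5000)
        stim = rng.normal(3.0, 0.1, 5000)
        pos, _ = ck.threshold_positive(stim, unstim)
        assert pos.mean() > 0.999

    def test_loss_marker_degraded_population_positive(self):
        rng = np.random.default_rng(5)
        unstim = rng.normal(2.0, 0.1, 5000)    # resting: bright
        stim = rng.normal(0.5, 0.1, 5000)      # degraded: dim
        pos, thr = ck.threshold_positive(stim, unstim, direction="loss")
        assert pos.mean() > 0.999
        assert thr < 2.0

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            ck.threshold_positive(np.array([]), np.array([1.0]))


class TestSummaries:
    def _positives_table(self):
        rng = np.random.default_rng(6)
        n = 10
        data = pd.DataFrame({
            "Yb172_pS6": [7.0, 7.5, 6.5, 7.0] + [1.0] * 6,
            "Er167_pERK12": rng.normal(1, 0.1, n),
        })
        et = make_event_table(data)
        positives = pd.DataFrame({
            "pS6": [True] * 4 + [False] * 6,
            "pERK12": [False] * n,
        }, index=data.index)
        return et, positives

    def test_hand_built_fraction_and_median(self):
        et, positives = self._positives_table()
        out = ck.summarize_fractions(et, positives, markers=["pS6", "pERK12"])
        ps6 = out[out["marker"] == "pS6"].iloc[0]
        assert ps6["pct_positive"] == pytest.approx(40.0)
        assert ps6["median_intensity"] == pytest.approx(7.0)
        perk = out[out["marker"] == "pERK12"].iloc[0]
        assert perk["pct_positive"] == 0.0
        assert np.isnan(perk["median_intensity"])

    def test_scaled_medians_are_zscores(self, gated_experiment):
        gated = gated_experiment["gated"]
        unstim = gated.subset(gated.sample_meta("ligand").to_numpy() == "unstim")
        positives = ck.PositivityThreshold().fit(unstim).predict(gated)
        out = ck.summarize_fractions(gated, positives, markers=["pS6"])
        z = out.loc[out["marker"] == "pS6", "scaled_median"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_potency_orders_ps6_positivity(self, gated_experiment):
        gated = gated_experiment["gated"]
        unstim = gated.subset(gated.sample_meta("ligand").to_numpy() == "unstim")
        positives = ck.PositivityThreshold().fit(unstim).predict(gated)
        out = ck.summarize_fractions(gated, positives, markers=["pS6"])
        sub = out[out["marker"] == "pS6"].set_index(["ligand", "time_h"])
        for t in (2.0, 4.0):
            assert (
                sub.loc[("N4", t), "pct_positive"]
                >= sub.loc[("T4", t), "pct_positive"]
                >= sub.loc[("G4", t), "pct_positive"]
            )

    def test_unknown_marker_errors(self):
        et, positives = self._positives_table()
        with pytest.raises(KeyError):
            ck.summarize_fractions(et, positives, markers=["pXYZ"])


class TestCombinatorialStates:
    def test_sixteen_states_sum_to_one(self):
        rng = np.random.default_rng(7)
        positives = pd.DataFrame(
            rng.random((200, 4)) < 0.4, columns=["CD44", "pS6", "pSTAT5", "pERK12"]
        )
        groups = pd.Series(["a"] * 100 + ["b"] * 100)
        out = ck.combinatorial_states(positives, groups, ["CD44", "pS6", "pSTAT5", "pERK12"])
        assert out.shape[1] == 16
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_built_counts(self):
        positives = pd.DataFrame({
            "pS6": [True, True, False, False, True, False, True, True],
            "pERK12": [True, False, True, False, False, False, True, True],
        })
        groups = pd.Series(["g"] * 8)
        out = ck.combinatorial_states(positives, groups, ["pS6", "pERK12"])
        assert out.loc["g", "pS6+pERK12+"] == pytest.approx(3 / 8)
        assert out.loc["g", "pS6+pERK12-"] == pytest.approx(2 / 8)
        assert out.loc["g", "pS6-pERK12+"] == pytest.approx(1 / 8)
        assert out.loc["g", "pS6-pERK12-"] == pytest.approx(2 / 8)

    def test_no_markers_errors(self):
        with pytest.raises(ValueError):
            ck.combinatorial_states(pd.DataFrame(), pd.Series(dtype=object), [])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=1, max_value=60))
    def test_frequencies_partition_property(self, n):
        rng = np.random.default_rng(n)
        positives = pd.DataFrame(rng.random((n, 3)) < 0.5, columns=["a", "b", "c"])
        out = ck.combinatorial_states(positives, pd.Series(["g"] * n), ["a", "b", "c"])
        assert out.shape[1] == 8
        assert out.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_mad_consistency_constant():
    x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    assert mad(x, scaled=False) == pytest.approx(1.0)
    assert mad(x, scaled=True) == pytest.approx(1.4826)
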