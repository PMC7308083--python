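import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytokinetics as ck
from cytokinetics.containers import EventOrder, Trajectory
from cytokinetics.trajectory import detect_initiation, order_events
from conftest import clean_intensity, make_event_table


def toy_trajectory(values: dict, rank=None) -> Trajectory:
    """Trajectory directly from per-marker value arrays (already ordered)."""
    data = pd.DataFrame(values)
    n = len(data)
    return Trajectory(
        ligand="N4", data=data,
        rank=np.arange(n) / max(n - 1, 1) if rank is None else rank,
        time_h=np.zeros(n), anchor="pS6", timepoints=[1.0],
    )


def order_from_ranks(ranks: dict) -> EventOrder:
    ordered = sorted(ranks, key=ranks.__getitem__)
    return EventOrder(markers=ordered, ranks=dict(ranks), determinable=True)


@pytest.fixture(scope="module")
def ligand_tables(kinetic_model):
    intensity = clean_intensity()
    tables = {}
    for lig in ("N4", "T4", "G4"):
        parts = []
        for i, t in enumerate((1.0, 2.0, 4.0, 6.0)):
            et, _ = ck.simulate_cells(
                kinetic_model, intensity, 8000, lig, t, seed=50 + i,
                sample_id=f"{lig}_{t:g}h",
            )
            parts.append(et)
        tables[lig] = ck.transform_table(ck.EventTable.concat(parts))
    un, _ = ck.simulate_cells(kinetic_model, intensity, 8000, "NP68", 0.0,
                              seed=99, sample_id="unstim",
                              sample_meta={"ligand": "unstim", "time_h": 0.0})
    tables["unstim"] = ck.transform_table(un)
    return tables


class TestBuildTrajectory:
    def test_composition_equal_per_timepoint(self, ligand_tables):
        traj = ck.build_trajectory(ligand_tables["N4"], ligand_tables["unstim"], seed=0)
        times, counts = np.unique(traj.time_h, return_counts=True)
        assert set(times) == {0.0, 1.0, 2.0, 4.0, 6.0}
        assert len(set(counts)) == 1

    def test_anchor_nondecreasing_along_order(self, ligand_tables):
        traj = ck.build_trajectory(ligand_tables["N4"], ligand_tables["unstim"], seed=0)
        ps6 = traj.data["pS6"].to_numpy()
        assert np.all(np.diff(ps6) >= -1e-6)
        assert traj.rank[0] == 0.0 and traj.rank[-1] == 1.0

    def test_all_equal_anchor_gives_reproducible_permutation(self):
        data = pd.DataFrame({"Yb172_pS6": np.ones(50),
                             "Er167_pERK12": np.arange(50.0)})
        samples = pd.DataFrame({"ligand": "N4", "time_h": 1.0,
                                "replicate": 1, "batch": 1},
                               index=pd.Index(["s1"], name="sample_id"))
        et = make_event_table(data, ["s1"] * 50, samples)
        un = make_event_table(data.copy(), ["s1"] * 50, samples)
        t1 = ck.build_trajectory(et, un, seed=3)
        t2 = ck.build_trajectory(et, un, seed=3)
        assert np.array_equal(t1.data["pERK12"], t2.data["pERK12"])
        assert not np.array_equal(t1.data["pERK12"].to_numpy(),
                                  np.sort(t1.data["pERK12"].to_numpy()))

    def test_pseudotime_tracks_real_time(self, ligand_tables):
        traj = ck.build_trajectory(ligand_tables["N4"], ligand_tables["unstim"], seed=1)
        rho, p = stats.spearmanr(traj.rank, traj.time_h)
        assert rho > 0 and p < 0.01

    def test_missing_anchor_errors(self, ligand_tables):
        with pytest.raises(KeyError, match="anchor"):
            ck.build_trajectory(ligand_tables["N4"], ligand_tables["unstim"],
                                anchor="pXYZ", seed=0)


def reference_loess(x, y, grid, span):
    """Independent local-linear tricube loess used as the oracle."""
    n = len(x)
    k = max(int(np.ceil(span * n)), 2)
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argsort(d)[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / max(dmax, 1e-12)) ** 3) ** 3
        X = np.column_stack([np.ones(k), x[idx] - x0])
        WX = X * w[:, None]
        beta = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)[0]
        out[i] = beta[0]
    return out


class TestSmoothCurves:
    def test_constant_marker_stays_constant(self):
        traj = toy_trajectory({"pS6": np.full(3000, 2.5)})
        curves = ck.smooth_curves(traj, ["pS6"], seed=0)
        assert np.allclose(curves["pS6"], 2.5, atol=1e-9)

    def test_linear_marker_reproduced(self):
        n = 3000
        rank = np.arange(n) / (n - 1)
        traj = toy_trajectory({"pS6": 1.0 + 2.0 * rank})
        curves = ck.smooth_curves(traj, ["pS6"], seed=0)
        interior = (curves.index > 0.1) & (curves.index < 0.9)
        expected = 1.0 + 2.0 * curves.index.to_numpy()
        assert np.allclose(curves["pS6"].to_numpy()[interior],
                           expected[interior], atol=1e-6)

    def test_noisy_step_matches_reference_loess(self):
        rng = np.random.default_rng(0)
        n = 2000
        rank = np.arange(n) / (n - 1)
        y = np.where(rank > 0.6, 1.0, 0.0) + rng.normal(0, 0.05, n)
        traj = toy_trajectory({"pS6": y})
        grid = np.linspace(0.05, 0.95, 19)
        curves = ck.smooth_curves(traj, ["pS6"], n_sample=n, seed=0, grid=grid)
        ref = reference_loess(rank, y, grid, span=0.2)
        assert np.max(np.abs(curves["pS6"].to_numpy() - ref)) < 0.05

    def test_bad_span_errors(self):
        traj = toy_trajectory({"pS6": np.zeros(100)})
        with pytest.raises(ValueError):
            ck.smooth_curves(traj, ["pS6"], span=0.0)


class TestDetectInitiation:
    def test_constant_marker_no_initiation_no_shift(self):
        traj = toy_trajectory({"pS6": np.full(5000, 1.0)})
        res = detect_initiation(traj, "pS6")
        assert res.window_index is None and not res.shift_without_threshold

    def test_step_matches_fine_grained_oracle(self):
        rng = np.random.default_rng(1)
        n = 5000
        rank = np.arange(n) / (n - 1)
        amp = 1.0
        y = np.where(rank >= 0.60, amp, 0.0) + rng.normal(0, 0.01 * amp, n)
        traj = toy_trajectory({"pERK12": y})
        res = detect_initiation(traj, "pERK12")
        wlen, slen = round(0.05 * n), round(0.01 * n)
        mean0, sd0 = y[:wlen].mean(), y[:wlen].std()
        # oracle: same rule at single-cell steps
        starts = np.arange(1, n - wlen + 1)
        means = np.convolve(y, np.ones(wlen) / wlen, mode="valid")[1:]
        cross = starts[np.abs(means - mean0) > sd0][0]
        assert abs(res.window_index * slen - cross) <= slen

    def test_rise_just_after_start_detected_in_first_window(self):
        n = 5000
        wlen = round(0.05 * n)
        y = np.where(np.arange(n) >= wlen, 1.0, 0.0)
        y = y + np.random.default_rng(2).normal(0, 0.01, n)
        traj = toy_trajectory({"pS6": y})
        res = detect_initiation(traj, "pS6")
        assert res.window_index == 1

    def test_shift_without_threshold_flag(self):
        rng = np.random.default_rng(3)
        n = 5000
        # drift of ~0.8 starting SDs: below threshold, above shift_fraction
        y = rng.normal(0, 1.0, n) + np.linspace(0, 0.8, n)
        traj = toy_trajectory({"CD44": y})
        res = detect_initiation(traj, "CD44", shift_fraction=0.5)
        assert res.window_index is None
        assert res.shift_without_threshold

    def test_depends_only_on_cell_order(self):
        rng = np.random.default_rng(4)
        y = np.sort(rng.normal(size=4000))
        a = detect_initiation(toy_trajectory({"pS6": y}), "pS6", seed=9)
        b = detect_initiation(
            toy_trajectory({"pS6": y}, rank=np.linspace(0, 1, 4000) ** 3), "pS6",
            seed=9,
        )
        assert a.window_index == b.window_index

    def test_too_few_cells_errors(self):
        traj = toy_trajectory({"pS6": np.ones(3)})
        with pytest.raises(ValueError, match="too few|window"):
            detect_initiation(traj, "pS6", window=0.9, step=0.5)


class TestOrderEvents:
    def _init(self, marker, window, shift=False):
        from cytokinetics.containers import InitiationResult

        return InitiationResult(marker=marker, window_index=window,
                                shift_without_threshold=shift, window=0.05,
                                step=0.01, k_sd=1.0, n_cells=5000,
                                start_mean=0.0, start_sd=1.0)

    def test_ranked_by_window_index(self):
        order = order_events({
            "pS6": self._init("pS6", 2), "pERK12": self._init("pERK12", 10),
            "pSTAT5": self._init("pSTAT5", 30), "CD44": self._init("CD44", 60),
        })
        assert order.determinable
        assert order.markers == ["pS6", "pERK12", "pSTAT5", "CD44"]

    def test_single_shift_marker_ranked_last(self):
        order = order_events({
            "pS6": self._init("pS6", 2), "pERK12": self._init("pERK12", 10),
            "pSTAT5": self._init("pSTAT5", 30),
            "CD44": self._init("CD44", None, shift=True),
        })
        assert order.determinable
        assert order.markers[-1] == "CD44"
        assert order.ranks["CD44"] == 4

    def test_shared_window_indeterminate(self):
        order = order_events({
            "pS6": self._init("pS6", 10), "pERK12": self._init("pERK12", 10),
        })
        assert not order.determinable and order.reason == "shared-window"

    def test_two_failures_indeterminate(self):
        order = order_events({
            "pS6": self._init("pS6", 2),
            "pSTAT5": self._init("pSTAT5", None, shift=True),
            "CD44": self._init("CD44", None),
        })
        assert not order.determinable and order.reason == "two-failed-threshold"


class TestMSD:
    def test_identical_orders_zero(self):
        o = order_from_ranks({"a": 1, "b": 2, "c": 3})
        assert ck.msd(o, o) == 0.0

    def test_reversed_three_events(self):
        o1 = order_from_ranks({"a": 1, "b": 2, "c": 3})
        o2 = order_from_ranks({"a": 3, "b": 2, "c": 1})
        assert ck.msd(o1, o2) == pytest.approx(8 / 3)

    def test_single_marker_always_zero(self):
        o = order_from_ranks({"a": 1})
        assert ck.msd(o, o) == 0.0

    def test_mismatched_sets_error(self):
        with pytest.raises(ValueError, match="marker sets"):
            ck.msd(order_from_ranks({"a": 1}), order_from_ranks({"b": 1}))


class TestOrderAgreement:
    def test_identical_four_event_orders(self):
        o = order_from_ranks({"pS6": 1, "pERK12": 2, "pSTAT5": 3, "CD44": 4})
        assert ck.order_agreement_test(o, o) == pytest.approx(1 / 24)

    def test_single_event_is_one(self):
        o = order_from_ranks({"a": 1})
        assert ck.order_agreement_test(o, o) == 1.0

    def test_reversed_three_events_is_one(self):
        o1 = order_from_ranks({"a": 1, "b": 2, "c": 3})
        o2 = order_from_ranks({"a": 3, "b": 2, "c": 1})
        assert ck.order_agreement_test(o1, o2) == 1.0

    def test_indeterminate_orders_rejected(self):
        good = order_from_ranks({"a": 1, "b": 2})
        bad = EventOrder(markers=["a", "b"], ranks=None, determinable=False,
                         reason="shared-window")
        with pytest.raises(ValueError, match="indeterminate"):
            ck.order_agreement_test(good, bad)

    def test_sampled_close_to_exact(self):
        o1 = order_from_ranks({m: i + 1 for i, m in enumerate("abcd")})
        o2 = order_from_ranks({"a": 1, "b": 2, "c": 4, "d": 3})
        exact = ck.order_agreement_test(o1, o2, method="exact")
        sampled = ck.order_agreement_test(o1, o2, method="sampled",
                                          n_perm=20000, seed=0)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(sampled - exact) < 3 * se + 1 / 20000


class TestCombine:
    def test_headline_product(self):
        combined = ck.combine_order_pvalues([1 / 24, 1 / 24])
        assert combined == pytest.approx(1 / 576)
        assert f"{combined:.3g}" == "0.00174"

    def test_single_p_unchanged(self):
        assert ck.combine_order_pvalues([0.2]) == pytest.approx(0.2)

    def test_unit_elements_drop_out(self):
        assert ck.combine_order_pvalues([1.0, 0.25]) == pytest.approx(0.25)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            ck.combine_order_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            ck.combine_order_pvalues([])
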