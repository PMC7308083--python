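"""pS6-anchored activation trajectories and event-order inference.

Cells pooled across timepoints (plus unstimulated cells) are ordered by
pS6 intensity — a sustained marker that rises with activation in real time
— giving a pseudotime in [0, 1]. Per-marker initiation is detected with a
sliding window (5% of the trajectory, 1% steps): the first window whose
mean deviates from the starting window's mean by more than one starting-
window SD marks the event's initiation. Orders derived per ligand are
compared across stimulation strengths with a mean-squared-distance (MSD)
permutation test; per-comparison probabilities multiply into a combined
p-value.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import EventOrder, EventTable, InitiationResult, OrderComparison, Trajectory

__all__ = [
    "TrajectoryBuilder",
    "build_trajectory",
    "smooth_curves",
    "detect_initiation",
    "order_events",
    "msd",
    "order_agreement_test",
    "combine_order_pvalues",
    "compare_orders",
]


class TrajectoryBuilder(BaseEstimator):
    """Build one activation trajectory for a ligand.

    ``fit`` takes the (transformed, gated) stimulated events of one ligand
    across timepoints plus unstimulated events; equal numbers of cells per
    stimulated timepoint are pooled with the same number of unstimulated
    cells, ordered by the anchor marker (ties broken by a seeded jitter),
    and assigned pseudotime ranks uniform in [0, 1].
    """

    def __init__(self, anchor: str = "pS6", n_per_timepoint: int | None = None,
                 random_state: int = 0):
        self.anchor = anchor
        self.n_per_timepoint = n_per_timepoint
        self.random_state = random_state

    def fit(self, stim_events: EventTable, unstim_events: EventTable, y=None):
        rng = np.random.default_rng(self.random_state)
        try:
            anchor_ch = stim_events.channel_for(self.anchor)
        except KeyError as err:
            raise KeyError(f"anchor marker {self.anchor!r} missing") from err
        times = stim_events.sample_meta("time_h").to_numpy()
        timepoints = sorted(t for t in np.unique(times) if t > 0)
        if not timepoints:
            raise ValueError("no stimulated timepoint present")
        sizes = [int((times == t).sum()) for t in timepoints]
        n = min(sizes + [unstim_events.n_events])
        if self.n_per_timepoint is not None:
            n = min(n, self.n_per_timepoint)
        parts, time_of = [], []
        for t in timepoints:
            idx = np.flatnonzero(times == t)
            take = rng.choice(idx, size=n, replace=False)
            parts.append(stim_events.data.iloc[take])
            time_of.append(np.full(n, t))
        take = rng.choice(unstim_events.n_events, size=n, replace=False)
        parts.append(unstim_events.data.iloc[take])
        time_of.append(np.zeros(n))
        pooled = pd.concat(parts, ignore_index=True)
        time_h = np.concatenate(time_of)

        anchor_vals = pooled[anchor_ch].to_numpy(dtype=float)
        span = np.ptp(anchor_vals)
        jitter = rng.uniform(-0.5, 0.5, len(anchor_vals)) * 1e-9 * max(span, 1.0)
        order = np.argsort(anchor_vals + jitter, kind="stable")

        # marker-named view of the ordered cells
        chan_to_marker = stim_events.panel["marker"].to_dict()
        data = pooled.iloc[order].reset_index(drop=True)
        data.columns = [chan_to_marker.get(c, c) for c in data.columns]
        n_cells = len(data)
        rank = np.arange(n_cells) / max(n_cells - 1, 1)
        ligand = str(pd.unique(stim_events.sample_meta("ligand"))[0])
        self.trajectory_ = Trajectory(
            ligand=ligand, data=data, rank=rank, time_h=time_h[order],
            anchor=self.anchor, timepoints=[float(t) for t in timepoints],
        )
        return self


def build_trajectory(stim_events, unstim_events, anchor="pS6", seed=0,
                     n_per_timepoint=None) -> Trajectory:
    return TrajectoryBuilder(
        anchor=anchor, n_per_timepoint=n_per_timepoint, random_state=seed
    ).fit(stim_events, unstim_events).trajectory_


def smooth_curves(traj: Trajectory, markers, span: float = 0.2,
                  n_sample: int = 2000, seed: int = 0, grid=None) -> pd.DataFrame:
    """Local-linear (tricube-weighted) fit of each marker against
    pseudotime rank over ``n_sample`` randomly sampled cells."""
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = traj.n_cells
    idx = np.sort(rng.choice(n, size=min(n_sample, n), replace=False))
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, dtype=float)
    out = {}
    x = traj.rank[idx]
    for m in markers:
        y = traj.data[m].to_numpy()[idx]
        out[m] = lowess(y, x, frac=span, it=0, xvals=grid)
    return pd.DataFrame(out, index=pd.Index(grid, name="rank"))


def _window_stats(values: np.ndarray, wlen: int, slen: int):
    starts = np.arange(0, len(values) - wlen + 1, slen)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csum2 = np.concatenate([[0.0], np.cumsum(values**2)])
    means = (csum[starts + wlen] - csum[starts]) / wlen
    var = (csum2[starts + wlen] - csum2[starts]) / wlen - means**2
    sds = np.sqrt(np.maximum(var, 0.0))
    return starts, means, sds


def detect_initiation(
    traj: Trajectory,
    marker: str,
    n_downsample: int = 5000,
    window: float = 0.05,
    step: float = 0.01,
    k_sd: float = 1.0,
    shift_fraction: float = 0.5,
    seed: int = 0,
) -> InitiationResult:
    """Sliding-window initiation call for one marker along the trajectory.

    The trajectory is downsampled to ``n_downsample`` cells (order kept);
    windows of ``window`` x N cells slide in steps of ``step`` x N from
    least to most activated. The first window whose mean is more than
    ``k_sd`` starting-window SDs away from the starting window's mean is
    the initiation window. If no window crosses but the final window's
    mean has shifted by more than ``shift_fraction`` SDs, the
    shift-without-threshold flag is set (such events rank last).
    A zero starting-window SD is replaced by the smallest positive window
    SD (machine epsilon scale as a last resort).
    """
    values = traj.data[marker].to_numpy(dtype=float)
    n = len(values)
    if n > n_downsample:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=n_downsample, replace=False))
        values = values[idx]
        n = n_downsample
    wlen = max(int(round(window * n)), 1)
    slen = max(int(round(step * n)), 1)
    if n < wlen or (n - wlen) // slen < 1:
        raise ValueError("too few cells for the requested window/step")
    _, means, sds = _window_stats(values, wlen, slen)
    mean0, sd0 = float(means[0]), float(sds[0])
    if sd0 == 0.0:
        positive = sds[sds > 0]
        sd0 = float(positive.min()) if positive.size else float(
            np.finfo(float).eps * max(abs(mean0), 1.0)
        )
    crossing = np.flatnonzero(np.abs(means - mean0) > k_sd * sd0)
    crossing = crossing[crossing > 0]
    window_index: int | None = int(crossing[0]) if crossing.size else None
    shift = False
    if window_index is None:
        shift = bool(abs(means[-1] - mean0) > shift_fraction * sd0)
    return InitiationResult(
        marker=marker, window_index=window_index, shift_without_threshold=shift,
        window=window, step=step, k_sd=k_sd, n_cells=n,
        start_mean=mean0, start_sd=sd0,
    )


def order_events(initiations: dict[str, InitiationResult]) -> EventOrder:
    """Derive the order of activation events from initiation windows.

    Markers with windows rank by window index; exactly one marker that
    failed the threshold ranks last; two or more failures, or a shared
    window index, make the order indeterminate.
    """
    markers = list(initiations)
    windows = {m: r.window_index for m, r in initiations.items()}
    failed = [m for m, w in windows.items() if w is None]
    if len(failed) >= 2:
        return EventOrder(markers=markers, ranks=None, determinable=False,
                          reason="two-failed-threshold")
    indexed = {m: w for m, w in windows.items() if w is not None}
    if len(set(indexed.values())) != len(indexed):
        return EventOrder(markers=markers, ranks=None, determinable=False,
                          reason="shared-window")
    ordered = sorted(indexed, key=indexed.__getitem__) + failed
    ranks = {m: i + 1 for i, m in enumerate(ordered)}
    return EventOrder(markers=ordered, ranks=ranks, determinable=True)


def msd(order1: EventOrder, order2: EventOrder) -> float:
    """Mean over events of the squared rank difference between two orders."""
    if not (order1.determinable and order2.determinable):
        raise ValueError("both orders must be determinable")
    if set(order1.ranks) != set(order2.ranks):
        raise ValueError("orders cover different marker sets")
    return float(
        np.mean([(order1.ranks[m] - order2.ranks[m]) ** 2 for m in order1.ranks])
    )


def order_agreement_test(
    order1: EventOrder,
    order2: EventOrder,
    method: str = "auto",
    n_perm: int = 100000,
    seed: int = 0,
) -> float:
    """P(MSD(order1, random permutation of order2) <= observed MSD).

    Exact enumeration for n <= 8 events; seeded permutation sampling
    otherwise (with the observed permutation included, so p > 0 always).
    """
    if not (order1.determinable and order2.determinable):
        raise ValueError(
            "indeterminate order: exclude this trajectory pair from testing"
        )
    obs = msd(order1, order2)
    markers = list(order1.ranks)
    r1 = np.array([order1.ranks[m] for m in markers], dtype=float)
    ranks = np.array([order2.ranks[m] for m in markers], dtype=float)
    n = len(markers)
    if method == "auto":
        method = "exact" if n <= 8 else "sampled"
    eps = 1e-12
    if method == "exact":
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ranks):
            if np.mean((r1 - np.asarray(perm)) ** 2) <= obs + eps:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    msds = np.mean((r1[None, :] - ranks[perms]) ** 2, axis=1)
    count = int(np.sum(msds <= obs + eps))
    return (1 + count) / (1 + n_perm)


def combine_order_pvalues(pvalues) -> float:
    """Product of independent per-comparison probabilities."""
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("at least one p-value is required")
    if any(not 0 < p <= 1 for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.prod(pvalues))


def compare_orders(
    orders: dict[str, EventOrder], method: str = "auto", n_perm: int = 100000, seed: int = 0
) -> OrderComparison:
    """All-pairs order agreement among determinable trajectories."""
    names = [k for k, o in orders.items() if o.determinable]
    pairs = list(itertools.combinations(names, 2))
    msds, ps = [], []
    for a, b in pairs:
        msds.append(msd(orders[a], orders[b]))
        ps.append(order_agreement_test(orders[a], orders[b], method=method,
                                       n_perm=n_perm, seed=seed))
    combined = combine_order_pvalues(ps) if ps else float("nan")
    null = "exact-enumeration" if all(
        len(orders[a].ranks) <= 8 for a in names
    ) else f"sampled-permutations({n_perm})"
    return OrderComparison(pairs=pairs, msd=msds, pvalues=ps,
                           combined_p=combined, null_method=null)
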