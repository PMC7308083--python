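"""Preprocessing: batch range normalization, per-event channel
normalization, hierarchical gating, DNA-content singlet discrimination,
positivity calling and the positive-fraction / combinatorial-state
summaries.

All gating and positivity decisions are taken on the logicle scale; the
raw scale is retained in the :class:`~cytokinetics.containers.EventTable`
the caller holds.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

from .containers import EventTable, GateResult

__all__ = [
    "BatchRangeNormalizer",
    "normalize_batch_range",
    "normalize_to_channel",
    "DNAContentClassifier",
    "classify_dna_content",
    "gate_hierarchy",
    "PositivityThreshold",
    "threshold_positive",
    "summarize_fractions",
    "combinatorial_states",
    "mad",
]


def mad(x: np.ndarray, scaled: bool = True) -> float:
    """Median absolute deviation; ``scaled`` applies the 1.4826 normal
    consistency constant."""
    x = np.asarray(x, dtype=float)
    m = float(np.median(np.abs(x - np.median(x))))
    return m * 1.4826 if scaled else m


# ---------------------------------------------------------------------------
# batch range normalization
# ---------------------------------------------------------------------------
class BatchRangeNormalizer(BaseEstimator):
    """Map each batch's [p, 1-p] intensity range onto the across-batch mean
    range, channel by channel, using samples acquired in every batch.

    With ``fix_zero`` the map is a pure scaling (zero maps to zero), using
    the upper quantile only; otherwise it is the affine map between ranges.
    Intended to run on logicle-transformed intensities.

    Attributes
    ----------
    scale_, offset_ : DataFrame (batches x channels)
        Per-batch affine adjustment; ``offset_`` is all zero with
        ``fix_zero``.
    """

    def __init__(self, p: float = 0.001, fix_zero: bool = True, channels=None):
        self.p = p
        self.fix_zero = fix_zero
        self.channels = channels

    def fit(self, events: EventTable, shared: dict[int, list] | None = None):
        """``shared`` maps batch -> sample ids of the shared samples; when
        omitted it is derived from a ``shared_group`` sample-sheet column."""
        if not 0 < self.p < 0.5:
            raise ValueError("p must lie in (0, 0.5)")
        if shared is None:
            if "shared_group" not in events.samples.columns:
                raise ValueError("no shared samples given or discoverable")
            sheet = events.samples[events.samples["shared_group"].notna()]
            shared = {
                b: list(g.index) for b, g in sheet.groupby("batch")
            }
        batches = sorted(events.samples["batch"].unique())
        if any(b not in shared or not shared[b] for b in batches):
            raise ValueError("every batch needs at least one shared sample")
        channels = self.channels or [
            c for c in events.channels if c not in events.channels_by_role("technical")
        ]
        lo, hi = {}, {}
        ids = events.sample_ids.to_numpy()
        for b in batches:
            mask = np.isin(ids, shared[b])
            pooled = events.data.loc[mask, channels]
            lo[b] = pooled.quantile(self.p)
            hi[b] = pooled.quantile(1 - self.p)
        lo = pd.DataFrame(lo).T
        hi = pd.DataFrame(hi).T
        target_lo, target_hi = lo.mean(axis=0), hi.mean(axis=0)
        if self.fix_zero:
            scale = target_hi / hi
            offset = scale * 0.0
        else:
            scale = (target_hi - target_lo) / (hi - lo)
            offset = target_lo - lo * scale
        self.channels_ = channels
        self.batches_ = batches
        self.scale_ = scale
        self.offset_ = offset
        return self

    def transform(self, events: EventTable) -> EventTable:
        data = events.data.copy()
        batch = events.sample_meta("batch").to_numpy()
        for b in self.batches_:
            rows = batch == b
            if not rows.any():
                continue
            data.loc[rows, self.channels_] = (
                data.loc[rows, self.channels_] * self.scale_.loc[b]
                + self.offset_.loc[b]
            )
        return events.with_data(data)

    def fit_transform(self, events: EventTable, shared=None) -> EventTable:
        return self.fit(events, shared).transform(events)

    def relative_scale(self, batch, reference_batch) -> pd.Series:
        """Scaling applied to ``batch`` relative to ``reference_batch``
        (convention-free read-out of a recovered distortion)."""
        return self.scale_.loc[batch] / self.scale_.loc[reference_batch]


def normalize_batch_range(events, shared=None, p=0.001, fix_zero=True):
    """Functional wrapper over :class:`BatchRangeNormalizer`."""
    norm = BatchRangeNormalizer(p=p, fix_zero=fix_zero)
    return norm.fit_transform(events, shared), norm


# ---------------------------------------------------------------------------
# per-event normalization to DNA / total protein
# ---------------------------------------------------------------------------
def normalize_to_channel(
    events: EventTable,
    numerator_channels: list,
    denominator_channel: str,
    reference_sample: str,
) -> tuple[EventTable, np.ndarray]:
    """Divide each event's signal by its own denominator-channel signal and
    rescale by the reference sample's median denominator, so a perfect 2x
    doublet returns to the singlet range.

    Returns the normalized table and a boolean mask flagging events whose
    denominator was <= 0 (to be excluded from downstream summaries).
    """
    if denominator_channel not in events.data.columns:
        raise KeyError(f"denominator channel {denominator_channel!r} missing")
    ref = events.events_of(reference_sample)
    if ref.empty:
        raise ValueError(f"reference sample {reference_sample!r} is empty")
    ref_median = float(ref[denominator_channel].median())
    denom = events.data[denominator_channel].to_numpy()
    flagged = denom <= 0
    data = events.data.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in numerator_channels:
            data[c] = data[c].to_numpy() / denom * ref_median
    return events.with_data(data), flagged


# ---------------------------------------------------------------------------
# DNA-content singlet/doublet discrimination
# ---------------------------------------------------------------------------
class DNAContentClassifier(ClassifierMixin, BaseEstimator):
    """Label events as 1 or 2 cell-equivalents of DNA.

    A two-component Gaussian mixture is fitted on the transformed DNA
    channel; events are labelled by the posterior-0.5 boundary between the
    components. When the fitted components are not separated (ratio of
    mean gap to component sd below ``separation_min``) the data are deemed
    unimodal: everything is labelled 1 and a warning is emitted.
    """

    def __init__(self, separation_min: float = 2.0, max_fit: int = 50000,
                 random_state: int = 0):
        self.separation_min = separation_min
        self.max_fit = max_fit
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("no events to fit")
        if np.ptp(x) == 0:
            self.bimodal_ = False
            self.threshold_ = np.inf
            warnings.warn("DNA channel is constant; all events labelled 1")
            return self
        fit_x = x
        if x.size > self.max_fit:
            rng = np.random.default_rng(self.random_state)
            fit_x = rng.choice(x, size=self.max_fit, replace=False)
        gmm = GaussianMixture(
            n_components=2, random_state=self.random_state, n_init=2
        ).fit(fit_x.reshape(-1, 1))
        means = gmm.means_.ravel()
        sds = np.sqrt(gmm.covariances_.ravel())
        order = np.argsort(means)
        means, sds = means[order], sds[order]
        weights = gmm.weights_.ravel()[order]
        self.means_, self.sds_, self.weights_ = means, sds, weights
        self.separation_ = float(abs(means[1] - means[0]) / max(sds.max(), 1e-12))
        self.bimodal_ = bool(
            self.separation_ >= self.separation_min and weights.min() > 1e-4
        )
        if not self.bimodal_:
            self.threshold_ = np.inf
            warnings.warn(
                "no second DNA component detected; all events labelled 1"
            )
            return self
        # posterior-0.5 boundary located on a fine grid between the means
        grid = np.linspace(means[0], means[1], 2001)
        post = gmm.predict_proba(grid.reshape(-1, 1))[:, order[1]]
        cross = np.searchsorted(post, 0.5)
        cross = min(max(cross, 0), len(grid) - 1)
        self.threshold_ = float(grid[cross])
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return np.where(x > self.threshold_, 2, 1)


def classify_dna_content(values, **kwargs) -> tuple[np.ndarray, "DNAContentClassifier"]:
    clf = DNAContentClassifier(**kwargs).fit(values)
    return clf.predict(values), clf


# ---------------------------------------------------------------------------
# hierarchical gating
# ---------------------------------------------------------------------------
def gate_hierarchy(events: EventTable, config=None, transformer=None) -> tuple[EventTable, GateResult]:
    """Six nested gates in acquisition-cleanup order: bead removal, event
    length, single cell-equivalent of DNA, dead-cell removal, TCRb
    retention, CD8 retention.

    Thresholds are computed on the logicle scale among events surviving the
    previous steps; the MAD retention gates keep cells with signal at least
    ``median - mad_k * MAD``.
    """
    from .config import PreprocessConfig

    config = config or PreprocessConfig()
    transformer = transformer or config.transformer()

    required = {
        "bead": events.channels_by_role("bead"),
        "DNA": events.channels_by_role("DNA"),
        "viability": events.channels_by_role("viability"),
    }
    for role, chans in required.items():
        if not chans:
            raise ValueError(f"no channel with role {role!r} in panel")
    for marker in ("TCRb", "CD8a"):
        events.channel_for(marker)  # raises if absent
    if "Event_length" not in events.data.columns:
        raise ValueError("no Event_length channel present")

    bead_ch = required["bead"][0]
    dna_ch = required["DNA"][0]
    via_ch = required["viability"][0]
    tcrb_ch = events.channel_for("TCRb")
    cd8_ch = events.channel_for("CD8a")

    t = {
        ch: transformer.transform(events.data[ch].to_numpy())
        for ch in (bead_ch, dna_ch, via_ch, tcrb_ch, cd8_ch)
    }
    length = events.data["Event_length"].to_numpy()

    result = GateResult()
    n = events.n_events
    alive = np.ones(n, dtype=bool)

    # 1. residual normalization beads: bright second component on the bead
    # channel (nothing removed when no bead population is present)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bead_clf = DNAContentClassifier().fit(t[bead_ch])
    alive = alive & (bead_clf.predict(t[bead_ch]) == 1)
    result.add("beads", alive, bead_clf.threshold_)

    # 2. high event length
    thr = np.median(length[alive]) + config.event_length_k * mad(
        length[alive], config.mad_scaled
    )
    alive = alive & (length <= thr)
    result.add("event_length", alive, thr)

    # 3. single cell-equivalent of DNA
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = DNAContentClassifier().fit(t[dna_ch][alive])
    alive = alive & (clf.predict(t[dna_ch]) == 1)
    result.add("dna_singlets", alive, clf.threshold_)

    # 4. dead cells: second (bright) component on the viability channel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dead_clf = DNAContentClassifier().fit(t[via_ch][alive])
    alive = alive & (dead_clf.predict(t[via_ch]) == 1)
    result.add("live", alive, dead_clf.threshold_)

    # 5-6. TCRb and CD8 retention gates
    for name, ch in (("tcrb", tcrb_ch), ("cd8", cd8_ch)):
        x = t[ch][alive]
        thr = np.median(x) - config.mad_k * mad(x, config.mad_scaled)
        alive = alive & (t[ch] >= thr)
        result.add(name, alive, thr)

    return events.subset(alive), result


# ---------------------------------------------------------------------------
# positivity
# ---------------------------------------------------------------------------
def threshold_positive(stim_values, unstim_values, direction: str = "gain",
                       quantile: float = 0.995) -> tuple[np.ndarray, float]:
    """Call signalling-positive events by comparison with unstimulated
    cells (on the transformed scale).

    Gain markers are positive above the ``quantile`` (default 99.5th
    percentile) of the unstimulated distribution; loss markers (IkBa) are
    positive below the mirrored lower quantile.
    """
    stim_values = np.asarray(stim_values, dtype=float)
    unstim_values = np.asarray(unstim_values, dtype=float)
    if stim_values.size == 0 or unstim_values.size == 0:
        raise ValueError("both stimulated and unstimulated values are required")
    if direction == "gain":
        thr = float(np.quantile(unstim_values, quantile))
        return stim_values > thr, thr
    elif direction == "loss":
        thr = float(np.quantile(unstim_values, 1 - quantile))
        return stim_values < thr, thr
    raise ValueError(f"unknown direction {direction!r}")


class PositivityThreshold(BaseEstimator):
    """Per-marker positivity thresholds learned from unstimulated cells.

    Expects logicle-transformed event tables. ``predict`` returns an
    events x markers boolean frame.
    """

    def __init__(self, quantile: float = 0.995, markers=None):
        self.quantile = quantile
        self.markers = markers

    def fit(self, unstim_events: EventTable, y=None):
        markers = self.markers or [
            m for m in unstim_events.panel["marker"]
            if unstim_events.panel.set_index("marker").loc[m, "role"]
            in ("signalling", "surface")
        ]
        if unstim_events.n_events == 0:
            raise ValueError("unstimulated event table is empty")
        self.thresholds_ = {}
        for m in markers:
            ch = unstim_events.channel_for(m)
            direction = unstim_events.marker_direction(m)
            x = unstim_events.data[ch].to_numpy()
            q = self.quantile if direction == "gain" else 1 - self.quantile
            self.thresholds_[m] = (float(np.quantile(x, q)), direction)
        return self

    def predict(self, events: EventTable) -> pd.DataFrame:
        out = {}
        for m, (thr, direction) in self.thresholds_.items():
            x = events.data[events.channel_for(m)].to_numpy()
            out[m] = x > thr if direction == "gain" else x < thr
        return pd.DataFrame(out, index=events.data.index)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def summarize_fractions(
    events: EventTable,
    positives: pd.DataFrame,
    markers=None,
    groupby=("ligand", "time_h"),
) -> pd.DataFrame:
    """Per group x marker: % positive cells and the centred/scaled median
    intensity of the positive fraction (z-score of medians across groups,
    computed per marker). Groups with no positive cell report 0% and a
    missing median."""
    markers = list(markers or positives.columns)
    unknown = [m for m in markers if m not in positives.columns]
    if unknown:
        raise KeyError(f"positivity not computed for markers: {unknown}")
    keys = pd.DataFrame(
        {g: events.sample_meta(g).to_numpy() for g in groupby},
        index=events.data.index,
    )
    rows = []
    for group_vals, idx in keys.groupby(list(groupby)).groups.items():
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        for m in markers:
            pos = positives.loc[idx, m]
            pct = 100.0 * float(pos.mean()) if len(pos) else 0.0
            if pos.any():
                ch = events.channel_for(m)
                med = float(events.data.loc[idx[pos.to_numpy()], ch].median())
            else:
                med = np.nan
            rows.append(dict(zip(groupby, group_vals)) | {
                "marker": m, "pct_positive": pct, "median_intensity": med,
            })
    out = pd.DataFrame(rows)
    scaled = []
    for m, sub in out.groupby("marker"):
        med = sub["median_intensity"]
        mu, sd = med.mean(), med.std(ddof=0)
        z = (med - mu) / sd if sd > 0 else med * 0.0
        scaled.append(pd.Series(z, index=sub.index))
    out["scaled_median"] = pd.concat(scaled).sort_index()
    return out


def combinatorial_states(
    positives: pd.DataFrame,
    groups: pd.Series,
    markers: list,
) -> pd.DataFrame:
    """Frequencies of the 2^k on/off states of ``markers`` per group.

    State labels are canonical, e.g. ``CD44-pS6+pSTAT5+pERK12-``; per
    group the frequencies sum to 1.
    """
    if len(markers) == 0:
        raise ValueError("at least one marker is required")
    missing = [m for m in markers if m not in positives.columns]
    if missing:
        raise KeyError(f"positivity not computed for markers: {missing}")
    states = list(itertools.product([True, False], repeat=len(markers)))

    def label(state):
        return "".join(f"{m}{'+' if s else '-'}" for m, s in zip(markers, state))

    labels = [label(s) for s in states]
    rows = {}
    groups = pd.Series(np.asarray(groups), index=positives.index)
    for g, idx in groups.groupby(groups).groups.items():
        sub = positives.loc[idx, markers].to_numpy()
        # encode each event's state as an integer
        code = np.zeros(len(sub), dtype=int)
        for j in range(len(markers)):
            code = code * 2 + (~sub[:, j]).astype(int)
        freq = np.bincount(code, minlength=len(states)) / max(len(sub), 1)
        rows[g] = freq
    out = pd.DataFrame(rows, index=labels).T
    out.index.name = "group"
    return out
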