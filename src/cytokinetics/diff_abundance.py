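"""Hypersphere differential abundance with spatial FDR control.

The transformed marker space is tiled with fixed-radius hyperspheres
centred on every ``downsample``-th cell (radius ``tol * sqrt(M)`` for M
markers); per-sample cell counts inside each hypersphere are tested with a
negative-binomial analysis of deviance (replicate-blocked), multiplicity-
corrected by a density-weighted Benjamini-Hochberg procedure over the
marker space, and significant hyperspheres are clustered by Pearson
correlation of their median marker intensities into signalling phenotypes
(A / A' / B / B').
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from . import nbglm
from .containers import DA_MARKERS, EventTable, HypersphereSet

__all__ = [
    "downsample_equal",
    "HypersphereCounter",
    "build_hyperspheres",
    "filter_hyperspheres",
    "test_differential_abundance",
    "spatial_fdr",
    "cluster_phenotypes",
    "DifferentialAbundanceTest",
]


def downsample_equal(events: EventTable, seed) -> EventTable:
    """Down-sample every sample to the size of the smallest one, uniformly
    without replacement."""
    rng = np.random.default_rng(seed)
    ids = events.sample_ids.to_numpy()
    sizes = pd.Series(ids).value_counts()
    empty = [s for s in events.samples.index if s not in sizes.index]
    if empty:
        raise ValueError(f"samples without any cell: {empty}")
    target = int(sizes.min())
    keep = np.zeros(len(ids), dtype=bool)
    for sid in sizes.index:
        idx = np.flatnonzero(ids == sid)
        keep[rng.choice(idx, size=target, replace=False)] = True
    return events.subset(keep)


class HypersphereCounter(BaseEstimator):
    """Assign cells to hyperspheres and count them per sample.

    Centers are every ``downsample``-th cell in the deterministic ordering
    of the event table (sample then event index); the radius is
    ``tol * sqrt(n_markers)``.
    """

    def __init__(self, tol: float = 0.4, downsample: int = 200, markers=None):
        self.tol = tol
        self.downsample = downsample
        self.markers = markers

    def fit(self, events: EventTable, y=None):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        markers = list(self.markers or DA_MARKERS)
        channels = events.channels_for(markers)
        X = events.data[channels].to_numpy(dtype=float)
        if len(X) == 0:
            raise ValueError("no cells to build hyperspheres from")
        radius = self.tol * np.sqrt(len(markers))
        center_idx = np.arange(0, len(X), self.downsample)
        centers = X[center_idx]
        tree = cKDTree(X)
        sample_codes, sample_levels = pd.factorize(events.sample_ids.to_numpy())
        ordered_levels = [s for s in events.samples.index if s in set(sample_levels)]
        level_pos = {s: i for i, s in enumerate(sample_levels)}
        counts = np.zeros((len(centers), len(ordered_levels)), dtype=int)
        medians = np.empty_like(centers)
        members = tree.query_ball_point(centers, r=radius)
        for h, idx in enumerate(members):
            idx = np.asarray(idx)
            bc = np.bincount(sample_codes[idx], minlength=len(sample_levels))
            counts[h] = [bc[level_pos[s]] for s in ordered_levels]
            medians[h] = np.median(X[idx], axis=0)
        self.hyperspheres_ = HypersphereSet(
            centers=pd.DataFrame(centers, columns=markers),
            counts=pd.DataFrame(counts, columns=ordered_levels),
            medians=pd.DataFrame(medians, columns=markers),
            radius=float(radius),
            markers=markers,
        )
        return self


def build_hyperspheres(events: EventTable, tol=0.4, downsample=200, markers=None) -> HypersphereSet:
    return HypersphereCounter(tol=tol, downsample=downsample, markers=markers).fit(
        events
    ).hyperspheres_


def filter_hyperspheres(hs: HypersphereSet, min_mean: float = 50.0) -> HypersphereSet:
    """Keep hyperspheres containing strictly more than ``min_mean`` cells
    on average across samples."""
    keep = hs.counts.mean(axis=1).to_numpy() > min_mean
    return hs.subset(keep)


def test_differential_abundance(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str = "condition",
    replicate: str = "replicate",
    reference: str = "unstim",
    totals=None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB analysis of deviance per hypersphere for any condition effect.

    ``counts`` is hyperspheres x samples (columns are sample ids present in
    ``samples``); ``totals`` the per-sample cell totals used as the log
    offset (defaults to the column sums). Returns a frame with ``pvalue``
    and one ``log2fc_<condition>`` column per stimulated condition.
    """
    sample_ids = list(counts.columns)
    meta = samples.loc[sample_ids]
    n_cond = meta[condition].nunique()
    if n_cond < 2:
        raise ValueError("at least two conditions are required")
    X_full, X_red, levels = nbglm.design_matrices(
        meta, condition=condition, replicate=replicate, reference=reference
    )
    if totals is None:
        totals = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        totals = np.asarray(totals, dtype=float)
    offset = np.log(np.maximum(totals, 1.0))
    Y = counts.to_numpy(dtype=float)
    aod = nbglm.analysis_of_deviance(Y, X_full, X_red, offset=offset, alpha=dispersion)
    out = pd.DataFrame({"pvalue": aod["pvalue"].to_numpy()}, index=counts.index)
    beta = aod.attrs["beta"]
    n_levels = len(levels)
    for j, level in enumerate(levels):
        out[f"log2fc_{level}"] = beta[:, -n_levels + j] / np.log(2.0)
    out.attrs["dispersion"] = aod.attrs["alpha"]
    return out


def spatial_fdr(
    pvals, centers, radius: float, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Density-weighted Benjamini-Hochberg over the marker space.

    Each hypersphere's weight is the reciprocal of the number of
    hypersphere centers (itself included) within ``radius`` of its center,
    so dense regions do not dominate the FDR budget. Returns ``(q, sig)``.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    tree = cKDTree(centers)
    neighbors = np.array([len(ix) for ix in tree.query_ball_point(centers, r=radius)])
    w = 1.0 / neighbors
    order = np.argsort(p, kind="stable")
    w_sorted = w[order]
    q_sorted = p[order] * w.sum() / np.cumsum(w_sorted)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def _correlation_distance(M: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows, with a defined value for constant rows:
    two identical constant rows are at distance 0, a constant row is at
    distance 1 from everything else."""
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=1)
    centered = M - M.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * M.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = centered @ centered.T / denom
    dist = 1.0 - corr
    flat = np.flatnonzero(sd == 0)
    for i in flat:
        same = np.all(np.isclose(M, M[i]), axis=1)
        dist[i, :] = np.where(same, 0.0, 1.0)
        dist[:, i] = dist[i, :]
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def cluster_phenotypes(
    medians: pd.DataFrame,
    thresholds: dict,
    distance: float = 0.05,
) -> pd.DataFrame:
    """Cluster significant hyperspheres by Pearson correlation of their
    median marker intensities (average linkage) and label the clusters.

    ``thresholds`` maps marker -> (threshold, direction) as produced by
    :class:`~cytokinetics.preprocess.PositivityThreshold`. Labels follow
    the pS6/pSTAT5/pERK1/2 phenotype definitions: A = pS6+ pSTAT5+ pERK+,
    A' = pS6+ pSTAT5- pERK+, B = pS6+ pSTAT5+ pERK-, B' = pS6+ pSTAT5-
    pERK-; anything pS6- is "other". CD44 positivity is reported in a
    separate column.
    """
    n = len(medians)
    if n == 0:
        raise ValueError("no hyperspheres to cluster")
    if n < 2:
        warnings.warn("fewer than 2 hyperspheres; a single cluster is returned")
        clusters = np.array([1])
    else:
        dist = _correlation_distance(medians.to_numpy())
        Z = linkage(squareform(dist, checks=False), method="average")
        clusters = fcluster(Z, t=distance, criterion="distance")

    def positive(profile, marker):
        thr, direction = thresholds[marker]
        v = profile[marker]
        return v > thr if direction == "gain" else v < thr

    out = pd.DataFrame({"cluster": clusters}, index=medians.index)
    labels = {}
    cd44 = {}
    for c in np.unique(clusters):
        profile = medians.loc[out["cluster"] == c].median()
        ps6 = positive(profile, "pS6")
        pstat5 = positive(profile, "pSTAT5")
        perk = positive(profile, "pERK12")
        if not ps6:
            labels[c] = "other"
        elif perk:
            labels[c] = "A" if pstat5 else "A'"
        else:
            labels[c] = "B" if pstat5 else "B'"
        cd44[c] = bool(positive(profile, "CD44")) if "CD44" in medians.columns else False
    out["phenotype"] = out["cluster"].map(labels)
    out["cd44_positive"] = out["cluster"].map(cd44)
    return out


class DifferentialAbundanceTest(BaseEstimator):
    """End-to-end hypersphere differential-abundance estimator.

    ``fit`` takes a filtered :class:`HypersphereSet` plus the sample sheet
    and populates ``results_`` with p-values, spatial-FDR q-values,
    significance flags, log2 fold-changes, and (when positivity thresholds
    are supplied) cluster and phenotype labels for the significant
    hyperspheres.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        condition: str = "condition",
        replicate: str = "replicate",
        reference: str = "unstim",
        cluster_distance: float = 0.05,
    ):
        self.alpha = alpha
        self.condition = condition
        self.replicate = replicate
        self.reference = reference
        self.cluster_distance = cluster_distance

    def fit(self, hs: HypersphereSet, samples: pd.DataFrame, thresholds: dict | None = None,
            totals=None):
        res = test_differential_abundance(
            hs.counts, samples, condition=self.condition,
            replicate=self.replicate, reference=self.reference, totals=totals,
        )
        q, sig = spatial_fdr(
            res["pvalue"].to_numpy(), hs.centers.to_numpy(), hs.radius, self.alpha
        )
        res["qvalue"] = q
        res["significant"] = sig
        res["cluster"] = pd.NA
        res["phenotype"] = pd.NA
        if thresholds is not None and sig.sum() > 0:
            lab = cluster_phenotypes(
                hs.medians.loc[sig], thresholds, distance=self.cluster_distance
            )
            res.loc[sig, "cluster"] = lab["cluster"].to_numpy()
            res.loc[sig, "phenotype"] = lab["phenotype"].to_numpy()
            res.loc[sig, "cd44_positive"] = lab["cd44_positive"].to_numpy()
        self.results_ = res
        self.dispersion_ = res.attrs.get("dispersion")
        return self
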