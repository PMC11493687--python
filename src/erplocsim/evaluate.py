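"""Cluster-based scoring of a reconstruction against the simulated truth.

Pipeline: (ERP evoked - noise evoked) CSD, averaged over the window of
interest (default 100-220 ms post-stimulus, endpoints inclusive at sample
resolution), thresholded to the top 5% of dipoles, grouped into connected
components under a 5 mm adjacency radius, with components of fewer than
five dipoles dropped. Clusters within a maximal center-to-center distance
(default 3 cm) of a simulated ROI make that ROI a true positive; ROIs with
no such cluster are false negatives; clusters near no ROI are false
positives. Sensitivity is TP/(TP+FN) over ROIs; precision is TP/(TP+FP),
deliberately mixing ROI-level TPs with cluster-level FPs as the procedure
defines it. Localization error and spatial dispersion are computed over
true-positive ROIs only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError
from .headmodel import SourceSpace
from .inverse import SourceEstimate
from .simulate import NetworkSpec, select_roi_dipoles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalParams:
    window_ms: tuple[float, float] = (100.0, 220.0)
    top_fraction: float = 0.05
    adjacency_mm: float = 5.0
    min_size: int = 5
    max_dist_mm: float = 30.0
    weighted_centers: bool = False


@dataclass
class ClusterSet:
    clusters: list[np.ndarray]  # dipole index arrays, pairwise disjoint
    centers: np.ndarray  # (n_clusters, 3) meters
    volumes_mm3: np.ndarray  # (n_clusters,)
    threshold_used: float
    params: EvalParams

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class EvalResult:
    tp: int
    fn: int
    fp: int
    sensitivity: float
    precision: float  # NaN when tp + fp == 0 (undefined, not zero)
    localization_error_mm: float  # mean over TP ROIs; NaN if no TPs
    spatial_dispersion: float  # mean over TP ROIs; NaN if no TPs
    max_dist_mm: float
    per_roi_locerr_mm: dict[str, float] = field(default_factory=dict)
    per_roi_dispersion: dict[str, float] = field(default_factory=dict)
    roi_is_tp: dict[str, bool] = field(default_factory=dict)
    n_clusters: int = 0


def condition_difference(
    erp_evoked: SourceEstimate,
    noise_evoked: SourceEstimate,
    window_ms: tuple[float, float] = (100.0, 220.0),
) -> np.ndarray:
    """Per-dipole (ERP - noise) CSD averaged over the analysis window."""
    if erp_evoked.csd.shape != noise_evoked.csd.shape:
        raise InvalidArgumentError("evoked responses live on different grids")
    t = erp_evoked.time_axis_ms()
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise InvalidArgumentError("analysis window lies outside the epoch")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    diff = erp_evoked.csd - noise_evoked.csd
    return diff[:, mask].mean(axis=1)


def threshold_top_fraction(values: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the ceil(fraction * n) largest signed values.

    Ties are broken by ascending dipole index for determinism.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidArgumentError("fraction must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    n = values.size
    k = int(np.ceil(fraction * n))
    if np.ptp(values) == 0.0:
        warnings.warn(
            "all difference values are equal; top-fraction selection is by "
            "index tie-break only",
            stacklevel=2,
        )
    order = np.argsort(-values, kind="stable")  # stable: lowest index first on ties
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def cluster_adjacent(
    mask: np.ndarray,
    sources: SourceSpace,
    adjacency_mm: float = 5.0,
    min_size: int = 5,
    values: np.ndarray | None = None,
    weighted_centers: bool = False,
    params: EvalParams | None = None,
    threshold_used: float = np.nan,
) -> ClusterSet:
    """Connected components of active dipoles under strict distance adjacency.

    Two active dipoles are adjacent iff their distance is strictly smaller
    than ``adjacency_mm``. Components below ``min_size`` are discarded.
    """
    if adjacency_mm <= 0:
        raise InvalidArgumentError("adjacency radius must be positive")
    active = np.flatnonzero(np.asarray(mask, dtype=bool))
    params = params or EvalParams(
        adjacency_mm=adjacency_mm, min_size=min_size, weighted_centers=weighted_centers
    )
    if active.size == 0:
        return ClusterSet([], np.empty((0, 3)), np.empty(0), threshold_used, params)
    pos = sources.positions[active]
    r = adjacency_mm * 1e-3
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]  # strict inequality
    n = active.size
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters, centers, volumes = [], [], []
    for comp in range(n_comp):
        members = active[labels == comp]
        if members.size < min_size:
            continue
        p = sources.positions[members]
        if weighted_centers and values is not None:
            w = np.abs(values[members])
            w = w / w.sum() if w.sum() > 0 else np.full(members.size, 1.0 / members.size)
            centers.append(w @ p)
        else:
            centers.append(p.mean(axis=0))
        clusters.append(members)
        volumes.append(members.size * sources.per_dipole_volume_mm3)
    centers_arr = np.array(centers) if centers else np.empty((0, 3))
    return ClusterSet(clusters, centers_arr, np.array(volumes), threshold_used, params)


def classify_clusters(
    clusters: ClusterSet,
    network: NetworkSpec,
    max_dist_mm: float,
) -> tuple[dict[str, bool], np.ndarray]:
    """ROI-level TP flags and a per-cluster is-FP mask.

    A cluster within ``max_dist_mm`` of any ROI center is not a false
    positive; one cluster may validate several ROIs (logged when it does).
    """
    roi_centers = np.array([roi.center for roi in network.rois])
    if clusters.n_clusters == 0:
        return {roi.name: False for roi in network.rois}, np.zeros(0, dtype=bool)
    d = np.linalg.norm(
        roi_centers[:, None, :] - clusters.centers[None, :, :], axis=2
    ) * 1e3  # mm, (n_rois, n_clusters)
    within = d <= max_dist_mm
    roi_tp = {roi.name: bool(within[i].any()) for i, roi in enumerate(network.rois)}
    fp_mask = ~within.any(axis=0)
    multi = within.sum(axis=0) > 1
    if multi.any():
        logger.info(
            "%d cluster(s) validate more than one ROI (double-validation)",
            int(multi.sum()),
        )
    return roi_tp, fp_mask


def compute_metrics(
    clusters: ClusterSet,
    network: NetworkSpec,
    roi_dipole_sets: dict[str, np.ndarray],
    sources_true: SourceSpace,
    max_dist_mm: float,
) -> EvalResult:
    """Sensitivity, precision, localization error and spatial dispersion."""
    roi_tp, fp_mask = classify_clusters(clusters, network, max_dist_mm)
    tp = sum(roi_tp.values())
    fn = len(network.rois) - tp
    fp = int(fp_mask.sum())
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan

    per_locerr: dict[str, float] = {}
    per_disp: dict[str, float] = {}
    for i, roi in enumerate(network.rois):
        if not roi_tp[roi.name]:
            continue
        d = (
            np.linalg.norm(clusters.centers - roi.center[None, :], axis=1) * 1e3
            if clusters.n_clusters
            else np.empty(0)
        )
        near = d <= max_dist_mm
        per_locerr[roi.name] = float(d[near].mean())
        v_roi = roi_dipole_sets[roi.name].size * sources_true.per_dipole_volume_mm3
        v_clusters = float(clusters.volumes_mm3[near].sum())
        per_disp[roi.name] = (v_clusters - v_roi) / v_roi
    locerr = float(np.mean(list(per_locerr.values()))) if per_locerr else np.nan
    disp = float(np.mean(list(per_disp.values()))) if per_disp else np.nan
    return EvalResult(
        tp=tp,
        fn=fn,
        fp=fp,
        sensitivity=sensitivity,
        precision=precision,
        localization_error_mm=locerr,
        spatial_dispersion=disp,
        max_dist_mm=max_dist_mm,
        per_roi_locerr_mm=per_locerr,
        per_roi_dispersion=per_disp,
        roi_is_tp=roi_tp,
        n_clusters=clusters.n_clusters,
    )


def evaluate(
    erp_evoked: SourceEstimate,
    noise_evoked: SourceEstimate,
    network: NetworkSpec,
    sources: SourceSpace,
    params: EvalParams = EvalParams(),
    sources_true: SourceSpace | None = None,
) -> EvalResult:
    """Full scoring pipeline for one reconstruction.

    ``sources`` is the grid the reconstruction lives on; ``sources_true``
    (defaulting to ``sources``) is the grid the truth was simulated on and
    defines the ROI dipole sets and volumes.
    """
    sources_true = sources_true or sources
    diff = condition_difference(erp_evoked, noise_evoked, params.window_ms)
    mask = threshold_top_fraction(diff, params.top_fraction)
    threshold_used = float(diff[mask].min())
    clusters = cluster_adjacent(
        mask,
        sources,
        params.adjacency_mm,
        params.min_size,
        values=diff,
        weighted_centers=params.weighted_centers,
        params=params,
        threshold_used=threshold_used,
    )
    roi_sets = {
        roi.name: select_roi_dipoles(sources_true, roi) for roi in network.rois
    }
    return compute_metrics(
        clusters, network, roi_sets, sources_true, params.max_dist_mm
    )
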