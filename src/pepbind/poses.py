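"""Trajectory-ensemble state assignment.

Pose ensembles (ligand coordinates after superposition of the receptor)
are reduced to per-frame RMSD against a reference pose, clustered
hierarchically on the pairwise-RMSD matrix, and classified bound/unbound
against a cutoff derived from the most native-like cluster:

    cutoff = mean RMSD-to-reference of the native-like cluster
           + maximum pairwise RMSD within that cluster.

A frame at or below the cutoff counts as properly bound (the bound state
is the inclusive one).  An ensemble of replicas then yields the unbound
fraction as a function of time, the observable the kinetics module fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .kinetics import ConcentrationSeries

__all__ = [
    "PoseEnsemble",
    "ClusterResult",
    "StateSeries",
    "superpose_kabsch",
    "rmsd_to_reference",
    "pairwise_rmsd_matrix",
    "cluster_poses",
    "derive_bound_cutoff",
    "assign_states",
    "ensemble_unbound_fraction",
]


@dataclass
class PoseEnsemble:
    """Superposed ligand poses over time plus the reference pose."""

    times: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    reference: np.ndarray  # (n_atoms, 3)
    atom_selection: str = "CA"
    true_labels: np.ndarray | None = None  # planted truth, if synthetic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.reference.shape[0]:
            raise ValueError("frames and reference must have the same atom count")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and frames must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")


@dataclass
class ClusterResult:
    """Partition of frames plus per-cluster statistics."""

    labels: np.ndarray  # per-frame cluster id, 0-based
    mean_rmsd_to_reference: np.ndarray | None  # per cluster, A
    max_within_cluster_distance: np.ndarray  # per cluster, A
    occupancy: np.ndarray  # per cluster, sums to 1
    native_like_cluster_id: int | None

    @property
    def n_clusters(self) -> int:
        return len(self.occupancy)


@dataclass
class StateSeries:
    """Per-frame bound/unbound calls against an RMSD cutoff."""

    times: np.ndarray
    bound: np.ndarray
    cutoff_angstrom: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        if self.times.shape != self.bound.shape:
            raise ValueError("times and bound must have equal length")
        if self.cutoff_angstrom <= 0:
            raise ValueError("cutoff must be positive")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time": self.times, "bound": self.bound.astype(int)}).to_csv(
            path, sep="\t", index=False
        )


def superpose_kabsch(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``mobile @ rotation.T + translation`` best fits
    ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be n x 3")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for a unique superposition")
    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rot, _rssd = Rotation.align_vectors(tgt_c, mob_c)
    rotation = rot.as_matrix()
    translation = target.mean(axis=0) - mobile.mean(axis=0) @ rotation.T
    # recompute from coordinates: the solver's rssd loses precision to
    # cancellation when the fit is near-exact
    rmsd = float(np.sqrt(np.mean(np.sum((mobile @ rotation.T + translation - target) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd_to_reference(ensemble: PoseEnsemble) -> np.ndarray:
    """Per-frame RMSD to the reference, without refitting: the receptor
    frame is already fixed by construction of the ensemble."""
    diff = ensemble.coords - ensemble.reference[None, :, :]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def pairwise_rmsd_matrix(ensemble: PoseEnsemble) -> np.ndarray:
    """Symmetric matrix of frame-frame RMSDs (no refitting)."""
    x = ensemble.coords
    n = x.shape[0]
    flat = x.reshape(n, -1)
    sq = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=2)
    return np.sqrt(sq / x.shape[1])


def cluster_poses(
    pairwise_rmsd: np.ndarray,
    rmsd_to_ref: np.ndarray | None = None,
    linkage: str = "average",
    threshold_angstrom: float = 3.0,
) -> ClusterResult:
    """Agglomerative clustering of frames, cut at ``threshold_angstrom``.

    ``linkage`` is ``"single"`` or ``"average"``.  Per-cluster statistics
    (mean RMSD to the reference, maximum within-cluster pairwise RMSD,
    occupancy) are computed from the inputs; the native-like cluster is the
    one with the smallest mean RMSD to the reference, ties resolved toward
    larger occupancy, then smaller cluster id.  Cluster ids are assigned by
    first frame occurrence, so the partition is deterministic.
    """
    d = np.asarray(pairwise_rmsd, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("pairwise matrix must be symmetric")
    if linkage not in ("single", "average"):
        raise ValueError("linkage must be 'single' or 'average'")
    n = d.shape[0]
    if n == 1:
        raw = np.zeros(1, dtype=int)
    else:
        condensed = squareform(d, checks=False)
        tree = scipy_linkage(condensed, method=linkage)
        raw = fcluster(tree, t=threshold_angstrom, criterion="distance") - 1
    # relabel by first occurrence for determinism under frame order
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        order.setdefault(lab, len(order))
        labels[i] = order[lab]
    k = len(order)

    occupancy = np.array([(labels == c).mean() for c in range(k)])
    max_within = np.zeros(k)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) > 1:
            max_within[c] = d[np.ix_(members, members)].max()
    mean_ref = None
    native_id = None
    if rmsd_to_ref is not None:
        rmsd_to_ref = np.asarray(rmsd_to_ref, dtype=float)
        if rmsd_to_ref.shape[0] != n:
            raise ValueError("rmsd_to_ref length must match matrix size")
        mean_ref = np.array([rmsd_to_ref[labels == c].mean() for c in range(k)])
        native_id = min(
            range(k), key=lambda c: (mean_ref[c], -occupancy[c], c)
        )
    return ClusterResult(
        labels=labels,
        mean_rmsd_to_reference=mean_ref,
        max_within_cluster_distance=max_within,
        occupancy=occupancy,
        native_like_cluster_id=native_id,
    )


def derive_bound_cutoff(clusters: ClusterResult) -> float:
    """Bound-state RMSD cutoff: mean RMSD-to-reference of the native-like
    cluster plus its maximum within-cluster pairwise distance.

    A singleton native-like cluster contributes a zero within-cluster term.
    """
    if clusters.native_like_cluster_id is None:
        raise ValueError("cluster result lacks reference RMSD statistics")
    c = clusters.native_like_cluster_id
    return float(
        clusters.mean_rmsd_to_reference[c] + clusters.max_within_cluster_distance[c]
    )


def assign_states(
    times: np.ndarray, rmsd_series: np.ndarray, cutoff_angstrom: float
) -> StateSeries:
    """Bound where RMSD <= cutoff (boundary counts as bound)."""
    rmsd_series = np.asarray(rmsd_series, dtype=float)
    return StateSeries(
        times=np.asarray(times, dtype=float),
        bound=rmsd_series <= cutoff_angstrom,
        cutoff_angstrom=cutoff_angstrom,
    )


def ensemble_unbound_fraction(
    series_list: list[StateSeries], time_grid: np.ndarray
) -> ConcentrationSeries:
    """Fraction of replicas unbound at each grid time.

    Each replica is sampled at the most recent frame at or before t
    (replicas must start at or before the first grid point).
    """
    if not series_list:
        raise ValueError("need at least one state series")
    time_grid = np.asarray(time_grid, dtype=float)
    n_unbound = np.zeros(len(time_grid))
    for s in series_list:
        idx = np.searchsorted(s.times, time_grid, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("grid extends before the first frame of a replica")
        n_unbound += ~s.bound[idx]
    return ConcentrationSeries(time_grid, n_unbound / len(series_list))
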