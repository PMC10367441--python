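"""Per-subject functional connectivity matrices.

Order of operations follows the validated pipeline: parcel-average the
BOLD signal, Pearson-correlate every node pair per run, average usable
runs on the r scale, then apply the Fisher r-to-z transform. Node
coverage is harmonized across the cohort before masks are applied.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import ConnectivityMatrix, NetworkMask, NodeTimeSeries


def parcellate(
    voxel_data: np.ndarray,
    labels: np.ndarray,
    atlas_labels=None,
    repetition_time: float = 1.0,
    subject=None,
    run=None,
) -> tuple[NodeTimeSeries, set[int]]:
    """Average voxel time courses within each atlas parcel.

    Parameters
    ----------
    voxel_data : (X, Y, Z, T) array
    labels : (X, Y, Z) integer volume, 0 = background
    atlas_labels : iterable of int, optional
        Full expected label set; labels with zero voxels are returned as
        missing rather than silently dropped. Defaults to the labels
        actually present.

    Returns
    -------
    (NodeTimeSeries over the present labels, set of missing labels)
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = np.asarray(labels)
    if voxel_data.ndim != 4:
        raise ValueError("voxel data must be 4-D (X, Y, Z, T)")
    if labels.shape != voxel_data.shape[:3]:
        raise ValueError(
            f"label volume shape {labels.shape} does not match data {voxel_data.shape[:3]}"
        )
    if (labels < 0).any():
        raise ValueError("labels must be nonnegative (0 = background)")
    present = sorted(int(v) for v in np.unique(labels) if v > 0)
    if not present:
        raise ValueError("label volume contains no nonzero parcels")
    if atlas_labels is None:
        atlas_labels = present
    atlas_labels = sorted(int(v) for v in atlas_labels)
    missing = set(atlas_labels) - set(present)
    kept = [l for l in atlas_labels if l not in missing]

    T = voxel_data.shape[3]
    flat_labels = labels.reshape(-1)
    flat = voxel_data.reshape(-1, T)
    means = np.empty((T, len(kept)))
    for t in range(T):
        means[t, :] = ndimage.mean(flat[:, t], labels=flat_labels, index=kept)
    ts = NodeTimeSeries(
        values=means,
        node_ids=tuple(kept),
        repetition_time=repetition_time,
        subject=subject,
        run=run,
    )
    return ts, missing


def correlation_matrix(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every node pair; diagonal stored as 0."""
    sd = ts.values.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        bad = [ts.node_ids[i] for i in zero_var]
        raise ValueError(f"zero-variance node(s): {bad}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, scale="r", node_ids=ts.node_ids, subject=ts.subject)


def average_runs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of r-scale matrices across usable runs.

    A single-run list returns that matrix unchanged (subjects with one
    usable run contribute that run's matrix alone).
    """
    if not matrices:
        raise ValueError("no matrices to average")
    ref = matrices[0]
    for m in matrices:
        if m.scale != "r":
            raise ValueError("run averaging operates on the r scale, before Fisher z")
        if m.node_ids != ref.node_ids:
            raise ValueError("node ids differ across runs; harmonize first")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(values=mean, scale="r", node_ids=ref.node_ids, subject=ref.subject)


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z (atanh) off the diagonal; applied after run averaging."""
    if m.scale != "r":
        raise ValueError("fisher_z expects an r-scale matrix")
    off = ~np.eye(m.n_nodes, dtype=bool)
    at_unity = off & (np.abs(m.values) >= 1.0)
    if at_unity.any():
        i, j = np.argwhere(at_unity)[0]
        raise ValueError(
            f"|r| = 1 at edge ({m.node_ids[i]}, {m.node_ids[j]}); z is infinite"
        )
    z = np.zeros_like(m.values)
    z[off] = np.arctanh(m.values[off])
    return ConnectivityMatrix(values=z, scale=m.scale.replace("r", "z"), node_ids=m.node_ids, subject=m.subject)


def harmonize_nodes(
    cohort: list[ConnectivityMatrix],
    missing: list[set[int]] | None = None,
) -> tuple[list[ConnectivityMatrix], tuple[int, ...]]:
    """Drop, from every subject, any node missing in any subject.

    ``missing`` holds per-subject sets of 1-based node labels with no
    coverage; nodes absent from a subject's matrix are treated as missing
    too. Returns the reduced cohort and the kept node labels.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if missing is None:
        missing = [set() for _ in cohort]
    all_ids = sorted(set().union(*(set(m.node_ids) for m in cohort)))
    union_missing = set().union(*missing)
    for m in cohort:
        union_missing |= set(all_ids) - set(m.node_ids)
    kept = tuple(i for i in all_ids if i not in union_missing)
    if not kept:
        raise ValueError("all nodes missing in at least one subject; empty cohort")
    reduced = []
    for m in cohort:
        idx = np.array([m.index_of(i) for i in kept])
        reduced.append(
            ConnectivityMatrix(
                values=m.values[np.ix_(idx, idx)],
                scale=m.scale,
                node_ids=kept,
                subject=m.subject,
            )
        )
    return reduced, kept


def restrict_mask(mask: NetworkMask, kept) -> tuple[NetworkMask, int]:
    """Remove mask edges with either endpoint outside the kept node set."""
    kept = set(int(i) for i in kept)
    edges = frozenset(e for e in mask.edges if e[0] in kept and e[1] in kept)
    restricted = NetworkMask(edges=edges, polarity=mask.polarity, atlas_size=mask.atlas_size)
    return restricted, restricted.n_edges
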