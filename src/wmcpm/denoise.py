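"""Node-level confound regression, temporal filtering, and motion QC.

Implements the nuisance model applied to parcellated BOLD series before
connectivity estimation: 24 motion regressors (6 rigid-body parameters,
their backward-difference temporal derivatives, and the squares of both),
mean white-matter / CSF / global signals, one-hot spike regressors for
high-motion volumes, and a discrete-cosine high-pass basis, all removed
in a single joint least-squares projection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("white_matter", "csf", "global_signal")

#: Head radius (mm) used to convert rotational displacement to arc length
#: (Power et al. convention).
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Per-volume framewise-displacement threshold (mm) flagging spike volumes.
SPIKE_FD_MM = 0.90

#: Run-mean framewise-displacement threshold (mm) for subject exclusion.
MEAN_FD_EXCLUSION_MM = 0.15

#: High-pass cutoff (Hz) implemented as a discrete-cosine basis.
DEFAULT_HIGHPASS_HZ = 0.01


def compute_fd(motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement per volume.

    Parameters
    ----------
    motion : (T, 6) array
        Columns: 3 translations (mm) then 3 rotations (radians).
    head_radius_mm : float
        Radius used to convert rotations to millimetres of arc.

    Returns
    -------
    (T,) array; the first volume has no predecessor and is assigned 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    delta = np.diff(motion, axis=0)
    fd = np.abs(delta[:, :3]).sum(axis=1) + head_radius_mm * np.abs(delta[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def flag_spikes(fd: np.ndarray, threshold_mm: float = SPIKE_FD_MM) -> np.ndarray:
    """0-based indices of volumes with FD >= threshold (inclusive)."""
    if threshold_mm <= 0:
        raise ValueError("spike threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    return np.flatnonzero(fd >= threshold_mm)


def dct_basis(n_timepoints: int, repetition_time: float, highpass_hz: float) -> np.ndarray:
    """Discrete-cosine high-pass basis (SPM convention).

    Number of columns is floor(2 * T * TR * cutoff); each column is
    cos(pi * (2t + 1) * k / (2T)) for k = 1..K, unit-normalised.
    """
    if highpass_hz < 0:
        raise ValueError("highpass cutoff must be nonnegative")
    n_basis = int(np.floor(2.0 * n_timepoints * repetition_time * highpass_hz))
    if n_basis >= n_timepoints:
        raise ValueError(
            f"run too short ({n_timepoints} volumes) for {n_basis} cosine basis columns"
        )
    t = np.arange(n_timepoints)
    cols = [
        np.sqrt(2.0 / n_timepoints) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_timepoints))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_timepoints, 0))


def _motion_expansion(motion: np.ndarray) -> np.ndarray:
    """24-parameter expansion: params, backward-difference derivatives
    (first row 0), and squares of both."""
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    return np.hstack([motion, deriv, motion**2, deriv**2])


def build_design(
    confounds: pd.DataFrame,
    spikes: np.ndarray | None = None,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    repetition_time: float = 1.0,
) -> pd.DataFrame:
    """Assemble the full confound design matrix for one run.

    Columns: 24 motion, 3 tissue signals, one one-hot column per spike
    volume, and the discrete-cosine high-pass basis. The intercept is not
    included (the regression adds it).
    """
    missing = [c for c in MOTION_COLUMNS if c not in confounds.columns]
    if missing:
        raise ValueError(f"confound table missing motion columns: {missing}")
    T = len(confounds)
    motion = confounds.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    blocks = {}
    expansion = _motion_expansion(motion)
    names = (
        list(MOTION_COLUMNS)
        + [f"{c}_derivative1" for c in MOTION_COLUMNS]
        + [f"{c}_power2" for c in MOTION_COLUMNS]
        + [f"{c}_derivative1_power2" for c in MOTION_COLUMNS]
    )
    for name, col in zip(names, expansion.T):
        blocks[name] = col
    for c in TISSUE_COLUMNS:
        if c in confounds.columns:
            blocks[c] = confounds[c].to_numpy(dtype=float)
    if spikes is not None:
        for idx in np.asarray(spikes, dtype=int):
            onehot = np.zeros(T)
            onehot[idx] = 1.0
            blocks[f"spike_{idx:04d}"] = onehot
    basis = dct_basis(T, repetition_time, highpass_hz)
    for k in range(basis.shape[1]):
        blocks[f"cosine{k:02d}"] = basis[:, k]
    return pd.DataFrame(blocks)


def regress_confounds(values: np.ndarray, design: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Residualize each node series against [intercept | design].

    Uses a minimum-norm least-squares solve, so a rank-deficient design
    (e.g. duplicated columns) still yields residuals orthogonal to every
    design column; a warning is emitted rather than an error.
    """
    values = np.asarray(values, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != values.shape[0]:
        raise ValueError(
            f"design has {X.shape[0] if X.ndim == 2 else '?'} rows, time series has {values.shape[0]}"
        )
    X = np.column_stack([np.ones(values.shape[0]), X])
    beta, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"confound design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "redundant columns contribute nothing",
            stacklevel=2,
        )
    return values - X @ beta


def motion_gate(fd: np.ndarray, mean_threshold_mm: float = MEAN_FD_EXCLUSION_MM) -> tuple[float, bool]:
    """Mean FD over the run and whether it meets the exclusion rule.

    Exclusion is inclusive: mean FD >= threshold excludes the subject.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD sequence")
    mean_fd = float(fd.mean())
    return mean_fd, mean_fd >= mean_threshold_mm


# fMRIPrep-dialect synonyms accepted on load, mapped to canonical names.
_FMRIPREP_ALIASES = {
    "csf": "csf",
    "white_matter": "white_matter",
    "global_signal": "global_signal",
    "framewise_displacement": "framewise_displacement",
}


def load_confounds(path, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> pd.DataFrame:
    """Read an fMRIPrep-style confounds TSV.

    Ensures the six motion columns are present and recomputes
    ``framewise_displacement`` from them when the column is absent
    (fMRIPrep leaves the first row as n/a; it is read as 0).
    """
    table = pd.read_csv(path, sep="\t", na_values=["n/a", "NA"])
    missing = [c for c in MOTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing motion columns {missing}")
    if "framewise_displacement" not in table.columns:
        table["framewise_displacement"] = compute_fd(
            table.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float), head_radius_mm
        )
    else:
        table["framewise_displacement"] = table["framewise_displacement"].fillna(0.0)
    return table
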