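"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: disjoint
high/low edge masks over the atlas, cohorts of Fisher-z connectivity
matrices whose mask strengths couple linearly to a behavioral outcome,
multivariate-normal node time series with a target correlation
structure, fMRIPrep-dialect confound tables with motion spikes, and
trial-level behavioral records (N-back, emotion-regulation choice,
Likert questionnaires with a target reliability).

The planted signal shifts the mean of each subject's masked edges by a
subject-level latent offset, so the strength score the pipeline measures
is controlled directly. Default scales mirror a healthy older-adult
cohort performing an in-scanner N-back: high-mask strength ~ 0.09 (SD
0.03), low-mask strength ~ 0.00 (SD 0.02), behavior ~ 0.80 (SD 0.09)
with a population strength-behavior correlation near 0.36.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, NetworkMask, StrengthScores
from .denoise import compute_fd
from .strength import strength_scores


@dataclass
class SimulationConfig:
    """Cohort-level generator settings; one seed fixes everything."""

    n_subjects: int = 104
    n_nodes: int = 268
    n_timepoints: int = 455
    repetition_time: float = 1.0
    n_high_edges: int = 1674
    n_low_edges: int = 1203
    #: slope of behavior on combined strength (outcome units per z unit)
    coupling: float = 0.87
    #: residual SD of behavior around the linear coupling
    noise_sd: float = 0.084
    #: probability per volume of a motion spike
    spike_rate: float = 0.0
    seed: int = 0
    # calibration of the planted connectivity structure
    high_strength_mean: float = 0.09
    high_strength_sd: float = 0.03
    low_strength_mean: float = 0.0
    low_strength_sd: float = 0.02
    background_mean: float = 0.05
    edge_noise_sd: float = 0.25
    behavior_mean: float = 0.80

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_timepoints", "n_high_edges", "n_low_edges"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_pairs = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_high_edges + self.n_low_edges > n_pairs:
            raise ValueError(
                f"{self.n_high_edges}+{self.n_low_edges} mask edges exceed the "
                f"{n_pairs} available node pairs"
            )
        if self.noise_sd < 0 or not 0 <= self.spike_rate <= 1:
            raise ValueError("noise_sd must be >= 0 and spike_rate in [0, 1]")

    @property
    def combined_strength_sd(self) -> float:
        """SD of the realized combined strength across subjects (latent
        shifts plus averaged edge noise)."""
        return math.sqrt(
            self.high_strength_sd**2
            + self.low_strength_sd**2
            + self.edge_noise_sd**2 * (1.0 / self.n_high_edges + 1.0 / self.n_low_edges)
        )

    def population_pearson(self) -> float:
        """Population Pearson correlation of combined strength with behavior."""
        num = self.coupling * self.combined_strength_sd
        return num / math.sqrt(num**2 + self.noise_sd**2)

    def population_spearman(self) -> float:
        """Population Spearman correlation under bivariate normality:
        (6 / pi) * asin(r / 2)."""
        return (6.0 / math.pi) * math.asin(self.population_pearson() / 2.0)


def _all_pairs(n_nodes: int) -> np.ndarray:
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack([iu[0] + 1, iu[1] + 1])


def gen_masks(n_nodes: int, n_high: int, n_low: int, seed: int) -> tuple[NetworkMask, NetworkMask]:
    """Two disjoint random edge masks over an n-node atlas."""
    pairs = _all_pairs(n_nodes)
    if n_high + n_low > len(pairs):
        raise ValueError(
            f"requested {n_high}+{n_low} edges but only {len(pairs)} pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_high + n_low, replace=False)
    high_edges = frozenset(map(tuple, pairs[chosen[:n_high]]))
    low_edges = frozenset(map(tuple, pairs[chosen[n_high:]]))
    return (
        NetworkMask(edges=high_edges, polarity="high", atlas_size=n_nodes),
        NetworkMask(edges=low_edges, polarity="low", atlas_size=n_nodes),
    )


def gen_cohort(
    config: SimulationConfig,
    masks: tuple[NetworkMask, NetworkMask] | None = None,
) -> tuple[list[ConnectivityMatrix], np.ndarray, list[StrengthScores]]:
    """Cohort of z-scale matrices plus a behavior coupled to strength.

    behavior_i = intercept + coupling * combined_i + N(0, noise_sd), with
    combined_i the realized combined strength of subject i's matrix; the
    returned StrengthScores are recomputed from the matrices themselves.
    """
    rng = np.random.default_rng(config.seed)
    if masks is None:
        masks = gen_masks(
            config.n_nodes,
            config.n_high_edges,
            config.n_low_edges,
            int(rng.integers(2**31)),
        )
    high, low = masks
    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    pair_index = {(i + 1, j + 1): k for k, (i, j) in enumerate(zip(*iu))}
    high_idx = np.array([pair_index[e] for e in high.edges])
    low_idx = np.array([pair_index[e] for e in low.edges])

    intercept = config.behavior_mean - config.coupling * (
        config.high_strength_mean - config.low_strength_mean
    )
    matrices, truth = [], []
    for s in range(config.n_subjects):
        upper = rng.normal(config.background_mean, config.edge_noise_sd, size=len(iu[0]))
        shift_high = rng.normal(0.0, config.high_strength_sd)
        shift_low = rng.normal(0.0, config.low_strength_sd)
        upper[high_idx] += config.high_strength_mean - config.background_mean + shift_high
        upper[low_idx] += config.low_strength_mean - config.background_mean + shift_low
        values = np.zeros((n, n))
        values[iu] = upper
        values += values.T
        m = ConnectivityMatrix(
            values=values, scale="z", node_ids=tuple(range(1, n + 1)), subject=f"sub-{s + 1:03d}"
        )
        matrices.append(m)
        truth.append(strength_scores(m, high, low))
    combined = np.array([t.combined for t in truth])
    behavior = intercept + config.coupling * combined + rng.normal(
        0.0, config.noise_sd, size=config.n_subjects
    )
    return matrices, behavior, truth


def gen_time_series(target_correlation, n_timepoints: int, seed: int, repetition_time: float = 1.0):
    """T x N draws from a zero-mean MVN with the given correlation.

    ``target_correlation`` is an r-scale ConnectivityMatrix (zero
    diagonal, set to 1 internally; a NodeTimeSeries is returned) or a
    plain correlation matrix with unit diagonal (a T x N array is
    returned). Raises on a non-PSD target.
    """
    node_ids = None
    subject = None
    if isinstance(target_correlation, ConnectivityMatrix):
        if target_correlation.scale != "r":
            raise ValueError("target must be on the r scale")
        corr = target_correlation.values.copy()
        np.fill_diagonal(corr, 1.0)
        node_ids = target_correlation.node_ids
        subject = target_correlation.subject
    else:
        corr = np.asarray(target_correlation, dtype=float).copy()
    if not np.allclose(corr, corr.T):
        raise ValueError("target correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("target correlation must have unit diagonal")
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise ValueError(
            f"target correlation is not positive semidefinite "
            f"(smallest eigenvalue {eigvals.min():.3e}); cannot factorize"
        )
    factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_timepoints, corr.shape[0])) @ factor.T
    if node_ids is not None:
        from .core import NodeTimeSeries

        return NodeTimeSeries(
            values=values,
            node_ids=node_ids,
            repetition_time=repetition_time,
            subject=subject,
        )
    return values


def gen_confounds(
    n_timepoints: int,
    repetition_time: float = 1.0,
    spike_rate: float = 0.0,
    seed: int = 0,
    translation_step_mm: float = 0.015,
    rotation_step_rad: float = 0.00025,
    spike_jump_mm: float = 1.5,
) -> pd.DataFrame:
    """fMRIPrep-dialect confound table with random-walk motion.

    Motion parameters follow a smooth random walk calibrated so mean FD
    lands near 0.07 mm; spikes are persistent translation jumps large
    enough to exceed the 0.90 mm flagging threshold, occurring with
    probability ``spike_rate`` per volume.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_timepoints, 6))
    steps[1:, :3] = rng.normal(0.0, translation_step_mm, size=(n_timepoints - 1, 3))
    steps[1:, 3:] = rng.normal(0.0, rotation_step_rad, size=(n_timepoints - 1, 3))
    if spike_rate > 0:
        spikes = rng.random(n_timepoints - 1) < spike_rate
        steps[1:, 0] += spikes * spike_jump_mm * rng.choice([-1.0, 1.0], size=n_timepoints - 1)
    motion = np.cumsum(steps, axis=0)
    table = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )
    for col in ("white_matter", "csf", "global_signal"):
        table[col] = rng.normal(0.0, 1.0, size=n_timepoints)
    table["framewise_displacement"] = compute_fd(motion)
    return table


def _likert_thresholds(n_categories: int) -> np.ndarray:
    from scipy import stats as _st

    return _st.norm.ppf(np.arange(1, n_categories) / n_categories)


def gen_behavioral_cohort(
    n_subjects: int,
    choice_params: tuple[float, float, float, float] = (0.6, -0.4, 0.0, 0.0),
    nback_params: dict | None = None,
    reliability: float = 0.91,
    n_items: int = 36,
    item_bounds: tuple[int, int] = (1, 5),
    moderator: np.ndarray | None = None,
    nback_ability: dict | None = None,
    choice_subject_sd: float = 1.5,
    nback_subject_logit_sd: float = 0.5,
    rt_means: dict | None = None,
    rt_sd: float = 150.0,
    seed: int = 0,
) -> dict:
    """Trial-level behavioral records for a cohort.

    Emotion-regulation choices follow a mixed logistic model
    P(acceptance) = logistic(b0 + u_i + b1 * intensity + b2 * moderator_i
    + b3 * moderator_i * intensity) with intensity coded 0 = low,
    1 = high. N-back correctness is Bernoulli per condition with
    subject-level ability on the logit scale. Likert items come from a
    one-factor model whose loading is calibrated to the target alpha
    (5-point discretization attenuates the realized alpha slightly).
    """
    if nback_params is None:
        nback_params = {"0-back": 0.84, "2-back": 0.80}
    if rt_means is None:
        rt_means = {"0-back": 1009.0, "2-back": 1180.0}
    rng = np.random.default_rng(seed)
    if moderator is None:
        moderator = rng.normal(0.0, 1.0, size=n_subjects)
    moderator = np.asarray(moderator, dtype=float)
    b0, b1, b2, b3 = choice_params

    subjects = [f"sub-{i + 1:03d}" for i in range(n_subjects)]

    # --- N-back: 2 runs x 8 blocks x 10 trials, conditions alternate
    nback_rows = []
    conditions = ["0-back", "2-back"] * 4
    ability = {
        cond: (
            np.asarray(nback_ability[cond], dtype=float)
            if nback_ability and cond in nback_ability
            else rng.normal(0.0, nback_subject_logit_sd, size=n_subjects)
        )
        for cond in nback_params
    }
    rt_offset = rng.normal(0.0, rt_sd, size=n_subjects)
    for s, subject in enumerate(subjects):
        for run in (1, 2):
            for block, cond in enumerate(conditions, start=1):
                base = nback_params[cond]
                logit = math.log(base / (1.0 - base)) + ability[cond][s]
                p = 1.0 / (1.0 + math.exp(-logit))
                correct = rng.random(10) < p
                rts = np.maximum(
                    rng.normal(rt_means[cond] + rt_offset[s], rt_sd, size=10), 200.0
                )
                for trial in range(10):
                    nback_rows.append(
                        {
                            "subject": subject,
                            "run": run,
                            "block": block,
                            "condition": cond,
                            "trial": trial + 1,
                            "correct": bool(correct[trial]),
                            "rt": float(rts[trial]),
                        }
                    )

    # --- ERC: 24 trials, 12 per intensity
    erc_rows = []
    u = rng.normal(0.0, choice_subject_sd, size=n_subjects)
    for s, subject in enumerate(subjects):
        intensities = ["low"] * 12 + ["high"] * 12
        for trial, intensity in enumerate(intensities, start=1):
            code = 1.0 if intensity == "high" else 0.0
            eta = b0 + u[s] + b1 * code + b2 * moderator[s] + b3 * moderator[s] * code
            accept = rng.random() < 1.0 / (1.0 + math.exp(-eta))
            erc_rows.append(
                {
                    "subject": subject,
                    "trial": trial,
                    "intensity": intensity,
                    "choice": "acceptance" if accept else "suppression",
                }
            )

    # --- Likert items from a one-factor model at the target reliability
    rho = reliability / (n_items - (n_items - 1) * reliability)
    loading = math.sqrt(rho)
    factor = rng.normal(0.0, 1.0, size=n_subjects)
    latent = loading * factor[:, None] + math.sqrt(1.0 - rho) * rng.normal(
        0.0, 1.0, size=(n_subjects, n_items)
    )
    lo, hi = item_bounds
    thresholds = _likert_thresholds(hi - lo + 1)
    responses = lo + np.searchsorted(thresholds, latent).astype(int)
    item_rows = [
        {"subject": subjects[s], "item": j + 1, "response": int(responses[s, j])}
        for s in range(n_subjects)
        for j in range(n_items)
    ]

    return {
        "nback": pd.DataFrame(nback_rows),
        "erc": pd.DataFrame(erc_rows),
        "items": pd.DataFrame(item_rows),
        "moderator": moderator,
    }


def nearest_correlation(matrix: np.ndarray, eps: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix
    by alternating eigenvalue clipping and unit-diagonal restoration."""
    corr = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(corr, 1.0)
    for _ in range(max_iter):
        eigvals, eigvecs = np.linalg.eigh(corr)
        if eigvals.min() >= eps:
            break
        corr = (eigvecs * np.clip(eigvals, eps, None)) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def gen_moderation_cohort(
    n_subjects: int = 104,
    intercept: float = 64.66,
    intensity_effect: float = -9.86,
    moderator_effect: float = 0.0,
    interaction: float = 0.0,
    moderator_sd: float = 0.04,
    subject_sd: float = 22.0,
    residual_sd: float = 29.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced long table for the moderation model with known effects.

    Outcome scale mirrors percentage acceptance use; subject and residual
    SDs produce a realistic within/between split for a cohort of ~100.
    """
    rng = np.random.default_rng(seed)
    moderator = rng.normal(0.0, moderator_sd, size=n_subjects)
    moderator -= moderator.mean()
    u = rng.normal(0.0, subject_sd, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        for intensity in (0, 1):
            mu = (
                intercept
                + intensity_effect * intensity
                + moderator_effect * moderator[s]
                + interaction * moderator[s] * intensity
                + u[s]
            )
            rows.append(
                {
                    "subject": f"sub-{s + 1:03d}",
                    "intensity": intensity,
                    "moderator": moderator[s],
                    "outcome": mu + rng.normal(0.0, residual_sd),
                }
            )
    return pd.DataFrame(rows)
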