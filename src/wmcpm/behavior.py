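"""Behavioral task and questionnaire scoring with exclusion rules.

Covers the N-back working-memory task (block-wise accuracy, run-level
exclusion at <= 0.50 mean accuracy), the emotion-regulation-choice (ERC)
task (percentage acceptance use overall and by image intensity), Likert
questionnaires (DERS, CES-D, BAI) with reverse keying, Cronbach's alpha
with a Feldt confidence interval, and the CES-D eligibility gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_BLOCKS = 8
TRIALS_PER_BLOCK = 10
ERC_TRIALS = 24
ERC_PER_INTENSITY = 12

#: Run-mean accuracy at or below which an N-back run is excluded.
RUN_ACCURACY_CUTOFF = 0.50

#: CES-D total at or above which a participant is ineligible.
CESD_ELIGIBILITY_CUTOFF = 20

# Published 11 reverse-keyed DERS items (1-based).
DERS_REVERSE_ITEMS = frozenset({1, 2, 6, 7, 8, 10, 17, 20, 22, 24, 34})


@dataclass(frozen=True)
class Instrument:
    name: str
    n_items: int
    bounds: tuple[int, int]
    reverse_keyed: frozenset = field(default_factory=frozenset)

    @property
    def score_range(self) -> tuple[int, int]:
        lo, hi = self.bounds
        return lo * self.n_items, hi * self.n_items


INSTRUMENTS = {
    "DERS": Instrument("DERS", 36, (1, 5), DERS_REVERSE_ITEMS),
    "CES-D": Instrument("CES-D", 20, (0, 3)),
    "BAI": Instrument("BAI", 21, (0, 3)),
}


def _check_nback_structure(trials: pd.DataFrame) -> None:
    required = {"block", "condition", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"N-back trials missing columns: {sorted(missing)}")
    counts = trials.groupby("block").size()
    if len(counts) != N_BLOCKS or (counts != TRIALS_PER_BLOCK).any():
        raise ValueError(
            f"expected {N_BLOCKS} blocks of {TRIALS_PER_BLOCK} trials, "
            f"got blocks {dict(counts)}"
        )
    per_block_cond = trials.groupby("block")["condition"].nunique()
    if (per_block_cond != 1).any():
        raise ValueError("each block must have a single condition")


def score_nback_run(trials: pd.DataFrame) -> dict:
    """Score one N-back run.

    Accuracy is computed block by block, then averaged over each
    condition's four blocks; the run mean accuracy averages all eight
    blocks. RT summaries use response trials only (missing RT ignored).
    """
    _check_nback_structure(trials)
    block_acc = trials.groupby(["condition", "block"])["correct"].mean()
    out: dict = {"conditions": {}}
    for cond, acc in block_acc.groupby(level="condition"):
        cond_trials = trials[trials["condition"] == cond]
        rts = cond_trials["rt"].dropna() if "rt" in cond_trials else pd.Series(dtype=float)
        out["conditions"][cond] = {
            "block_accuracies": tuple(acc.to_numpy(dtype=float)),
            "accuracy": float(acc.mean()),
            "mean_rt": float(rts.mean()) if len(rts) else float("nan"),
        }
    all_blocks = trials.groupby("block")["correct"].mean()
    out["run_accuracy"] = float(all_blocks.mean())
    return out


def apply_nback_exclusions(
    run_summaries: dict,
    cutoff: float = RUN_ACCURACY_CUTOFF,
    rule: str = "pooled",
) -> tuple[list, bool]:
    """Run-level and subject-level N-back exclusion.

    A run is excluded when its mean accuracy is <= cutoff (inclusive);
    the subject is excluded only when every run fails. ``rule`` selects
    the accuracy pooled over all 8 blocks (default) or the 2-back blocks
    only.
    """
    if not run_summaries:
        raise ValueError("subject has no N-back runs")
    if rule not in ("pooled", "2-back"):
        raise ValueError("rule must be 'pooled' or '2-back'")
    usable = []
    for run_id, summary in run_summaries.items():
        acc = (
            summary["run_accuracy"]
            if rule == "pooled"
            else summary["conditions"]["2-back"]["accuracy"]
        )
        if acc > cutoff:
            usable.append(run_id)
    return usable, len(usable) == 0


def nback_subject_summary(run_summaries: list[dict]) -> dict:
    """Average per-condition accuracy and RT across usable runs."""
    if not run_summaries:
        raise ValueError("no usable runs to summarize")
    conditions = run_summaries[0]["conditions"].keys()
    out = {}
    for cond in conditions:
        accs = [r["conditions"][cond]["accuracy"] for r in run_summaries]
        rts = [
            r["conditions"][cond]["mean_rt"]
            for r in run_summaries
            if np.isfinite(r["conditions"][cond]["mean_rt"])
        ]
        out[cond] = {
            "accuracy": float(np.mean(accs)),
            "mean_rt": float(np.mean(rts)) if rts else float("nan"),
        }
    return out


def score_erc(trials: pd.DataFrame) -> dict:
    """Percentage acceptance use: overall and per image intensity.

    Requires the balanced 24-trial design (12 low, 12 high intensity).
    0% and 100% are valid scores, never treated as outliers.
    """
    required = {"intensity", "choice"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"ERC trials missing columns: {sorted(missing)}")
    if len(trials) != ERC_TRIALS:
        raise ValueError(f"expected {ERC_TRIALS} ERC trials, got {len(trials)}")
    counts = trials["intensity"].value_counts()
    if set(counts.index) != {"low", "high"} or (counts != ERC_PER_INTENSITY).any():
        raise ValueError("expected 12 low- and 12 high-intensity trials")
    accept = trials["choice"] == "acceptance"
    low = 100.0 * accept[trials["intensity"] == "low"].mean()
    high = 100.0 * accept[trials["intensity"] == "high"].mean()
    return {
        "overall_pct": 100.0 * accept.mean(),
        "low_pct": float(low),
        "high_pct": float(high),
    }


def score_scale(instrument: str | Instrument, responses, reverse_keyed=None) -> int:
    """Total questionnaire score with reverse keying.

    A reverse-keyed item r becomes (min + max) - r before summing. No
    imputation: missing or out-of-bounds responses raise.
    """
    inst = INSTRUMENTS[instrument] if isinstance(instrument, str) else instrument
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (inst.n_items,):
        raise ValueError(
            f"{inst.name} expects {inst.n_items} responses, got {responses.shape}"
        )
    if np.isnan(responses).any():
        raise ValueError(f"{inst.name}: missing item responses (no imputation)")
    lo, hi = inst.bounds
    if (responses < lo).any() or (responses > hi).any():
        raise ValueError(f"{inst.name}: responses outside bounds [{lo}, {hi}]")
    rev = inst.reverse_keyed if reverse_keyed is None else frozenset(reverse_keyed)
    keyed = responses.copy()
    for item in rev:
        keyed[item - 1] = (lo + hi) - keyed[item - 1]
    return int(round(keyed.sum()))


def cronbach_alpha(items: np.ndarray, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha with the Feldt F-based confidence interval.

    ``items`` is subjects x items. alpha = k/(k-1) * (1 - sum of item
    variances / variance of total scores).
    """
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 subjects")
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = (k / (k - 1)) * (1.0 - item_var.sum() / total_var)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    tail = (1.0 - ci_level) / 2.0
    lower = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - tail, df1, df2)
    upper = 1.0 - (1.0 - alpha) * stats.f.ppf(tail, df1, df2)
    return float(alpha), (float(lower), float(upper))


def eligibility_gate(cesd_total: float, threshold: float = CESD_ELIGIBILITY_CUTOFF) -> bool:
    """True (excluded) when the CES-D total is >= threshold (inclusive)."""
    return bool(cesd_total >= threshold)
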