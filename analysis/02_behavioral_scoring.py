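"""Step 2: score the behavioral data of the simulated study.

Reads the trial tables written by step 1, scores the N-back task per run
and per subject, applies the run- and subject-level accuracy exclusions,
scores the emotion-regulation choice task, and estimates the internal
consistency (Cronbach's alpha with a Feldt interval) of the questionnaire
items. Writes results/behavioral_scores.csv.

Run:  python analysis/02_behavioral_scoring.py [--data data/synthetic]
"""

import argparse
from pathlib import Path

import pandas as pd

from wmcpm import behavior as beh

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("data/synthetic"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

nback = pd.read_csv(args.data / "behavior" / "nback_trials.csv")
erc = pd.read_csv(args.data / "behavior" / "erc_trials.csv")
items = pd.read_csv(args.data / "behavior" / "ders_items.csv")

rows = []
for subject, sub_trials in nback.groupby("subject"):
    runs = {
        run: beh.score_nback_run(run_trials)
        for run, run_trials in sub_trials.groupby("run")
    }
    usable, excluded = beh.apply_nback_exclusions(runs)
    row = {"subject": subject, "n_usable_runs": len(usable), "excluded": excluded}
    if not excluded:
        summary = beh.nback_subject_summary([runs[r] for r in usable])
        row["acc_0back"] = summary["0-back"]["accuracy"]
        row["acc_2back"] = summary["2-back"]["accuracy"]
    erc_scores = beh.score_erc(erc[erc.subject == subject])
    row.update(
        erc_overall_pct=erc_scores["overall_pct"],
        erc_low_pct=erc_scores["low_pct"],
        erc_high_pct=erc_scores["high_pct"],
    )
    responses = (
        items[items.subject == subject].sort_values("item")["response"].tolist()
    )
    row["ders_total"] = beh.score_scale("DERS", responses)
    rows.append(row)

scores = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
scores.to_csv(args.out / "behavioral_scores.csv", index=False)

wide = items.pivot(index="subject", columns="item", values="response")
alpha, (lo, hi) = beh.cronbach_alpha(wide.to_numpy(dtype=float))

n_excluded = int(scores["excluded"].sum())
print(f"scored {len(scores)} subjects; {n_excluded} excluded by the accuracy rule")
print(
    f"2-back accuracy: mean {scores['acc_2back'].mean():.3f}, "
    f"sd {scores['acc_2back'].std(ddof=1):.3f}"
)
print(f"acceptance use overall: {scores['erc_overall_pct'].mean():.1f}%")
print(f"DERS alpha = {alpha:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
print(f"wrote {args.out / 'behavioral_scores.csv'}")
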