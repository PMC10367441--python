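"""Step 1: simulate a complete synthetic study on disk.

Writes node time series, motion confounds, behavioral trial tables, the
two network masks, and the generating ("truth") strength table. Later
steps read only the on-disk study, never the truth table, except for the
final recovery check in step 4.

Run:  python analysis/01_simulate_cohort.py [--data data/synthetic] [--seed N]
"""

import argparse
from pathlib import Path

from wmcpm import synth
from wmcpm.pipeline import simulate_study

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("data/synthetic"))
parser.add_argument("--subjects", type=int, default=16)
parser.add_argument("--seed", type=int, default=2024)
args = parser.parse_args()

# a scaled-down atlas keeps the worked example fast while preserving every
# structural feature of the full 268-node problem
config = synth.SimulationConfig(
    n_subjects=args.subjects,
    n_nodes=40,
    n_timepoints=150,
    n_high_edges=60,
    n_low_edges=45,
    spike_rate=0.01,
    seed=args.seed,
)
tables = simulate_study(config, args.data, n_runs=2)

truth = tables["truth"]
print(f"wrote study for {args.subjects} subjects to {args.data}/")
print(f"planted population Pearson r = {config.population_pearson():.3f}")
print(
    "true combined strength: "
    f"mean {truth['combined'].mean():.4f}, sd {truth['combined'].std(ddof=1):.4f}"
)
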