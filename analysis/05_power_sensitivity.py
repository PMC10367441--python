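"""Step 5: a priori power and post hoc sensitivity analyses.

These are closed-form design calculations; they do not depend on the
simulated data. The a priori question: how many subjects are needed to
detect a correlation of 0.37 at alpha = .05 with 80% power? The post hoc
questions: at the achieved sample size, what is the smallest detectable
correlation, and the smallest detectable interaction effect (Cohen's f)
in a three-predictor regression?

Run:  python analysis/05_power_sensitivity.py [--n 104]
"""

import argparse

from wmcpm import stats as st

parser = argparse.ArgumentParser()
parser.add_argument("--n", type=int, default=104, help="achieved sample size")
parser.add_argument("--r", type=float, default=0.37, help="expected correlation")
args = parser.parse_args()

n_required = st.power_n_for_r(args.r, alpha=0.05, power=0.80)
r_min = st.min_detectable_r(args.n, alpha=0.05, power=0.80)
f_min = st.min_detectable_f(args.n, n_predictors=3, test_df=1, alpha=0.05, power=0.80)

print(
    f"a priori: detecting r = {args.r} (alpha .05, power .80) "
    f"requires n = {int(n_required.answer)}"
)
print(f"sensitivity at n = {args.n}: minimum detectable r = {r_min.answer:.2f}")
print(
    f"sensitivity at n = {args.n}: minimum detectable interaction f = "
    f"{f_min.answer:.2f} (1-df test, 3 predictors)"
)
achieved = st.correlation_power(args.n, args.r, alpha=0.05)
print(f"achieved power for r = {args.r} at n = {args.n}: {achieved:.3f}")
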