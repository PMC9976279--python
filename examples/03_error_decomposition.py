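"""Score predictions with the RMSE = sqrt(SDEP^2 + bias^2) decomposition.

The bias (mean displacement) is the systematic part of the error — a
constant that could be subtracted from all predictions — while SDEP is the
random scatter the model cannot explain.  A model whose RMSE exceeds the SD
of the experimental values is worse than predicting the mean (null model).
"""

import numpy as np

from solqspr.stats import PredictionSet, evaluate, null_model_flag, range_restrict

rng = np.random.default_rng(3)
y_exp = rng.uniform(-7, -1, 40)
y_calc = y_exp + 0.35 + rng.normal(0, 0.6, 40)  # biased, noisy predictor

p = PredictionSet(ids=[f"m{i}" for i in range(40)], y_calc=y_calc, y_exp=y_exp)
st = evaluate(p)
print(f"R2 {st.r2:.2f}   RMSE {st.rmse:.2f}   SDEP {st.sdep:.2f}   "
      f"bias {st.bias:+.2f}   within 0.5 log: {st.pct_within_half:.0f}%")
print(f"identity: sqrt({st.sdep:.3f}^2 + {st.bias:+.3f}^2) = "
      f"{np.hypot(st.sdep, st.bias):.3f} = RMSE")
print(f"worse than null model? {null_model_flag(st, float(y_exp.std()))}")

# compare on a common experimental range (strict bounds), as one does when
# two test sets span different solubility ranges
reduced = range_restrict(p, -6.79, -1.18)
print(f"range (-6.79, -1.18) retains {len(reduced)}/{len(p)} molecules; "
      f"RMSE there {evaluate(reduced).rmse:.2f}")
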