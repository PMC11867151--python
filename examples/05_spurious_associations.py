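"""Spurious trait-diversification associations and the ROC summary.

Analyses S2 trees (speciation doubled in state 1) twice: once with the
effect trait the rates actually depend on, and once with a neutral
medium-rate trait simulated on the same trees. The posterior probability
P(lambda1 > lambda0) is the association statistic; neutral traits acting
as positives are false detections.
"""

import numpy as np

import fossilbisse as fb
import fossilbisse.summarize as sz

n_rep, q_neutral = 4, 0.1
settings = fb.MCMCSettings(iterations=1500, target_samples=400)
spec = fb.NeutralTraitSpec(q_neutral, "medium")

effect, neutral = [], []
for r in range(n_rep):
    rng = np.random.default_rng(50 + r)
    ds = fb.generate_replicate(fb.SCENARIOS["S2"], 0.0, [spec], 100, rng)
    tr_eff = fb.run_mcmc(ds.extant, "bisse", settings=settings, seed=60 + r)
    tr_neu = fb.run_mcmc(ds.extant, "bisse", settings=settings, trait="medium", seed=70 + r)
    effect.append(sz.prob_greater(tr_eff, "lambda1", "lambda0"))
    neutral.append(sz.prob_greater(tr_neu, "lambda1", "lambda0"))
    print(f"rep {r}: P(l1>l0 | effect trait) = {effect[-1]:.3f}, "
          f"P(l1>l0 | neutral trait) = {neutral[-1]:.3f}")

roc = sz.roc_points(effect, neutral)
print(f"\nROC area (effect vs neutral): {roc.attrs['auc']:.2f}")

# The effect trait is flagged in essentially every replicate. The
# neutral trait's probability is replicate-dependent: near 1 when the
# minority neutral state happens to occupy a fast-diversifying clade (a
# spurious detection), near 0 when the free root-state probability lets
# the model blame state 0 instead. The ROC area summarises how well the
# statistic still separates real from spurious associations.
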