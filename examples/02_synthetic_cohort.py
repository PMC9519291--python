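"""Generate a small synthetic cohort and inspect its label correlation.

Each mouth draws a caries propensity from Beta(2,2); a contagion sweep then
raises the caries odds of teeth whose K=3 neighbors are carious. The
intra-class correlation within mouths is 1/(alpha+beta+1) = 0.2 when the
contagion is off, and higher with it on.
"""

import numpy as np

from cariesctx import SyntheticConfig, sample_labels

for contagion in (0.0, 1.0):
    cfg = SyntheticConfig(
        n_radiographs=2000, contagion=contagion, missing_rate=0.0, seed=7
    )
    maps = sample_labels(cfg)
    flat = np.array([v for m in maps for v in m.values()], dtype=float)
    per_mouth = np.array([np.mean(list(m.values())) for m in maps])
    # crude ICC: variance of mouth means relative to total Bernoulli variance
    p = flat.mean()
    icc = (per_mouth.var() - p * (1 - p) / 20) / (p * (1 - p))
    print(
        f"contagion {contagion:.1f}: caries rate {p:.3f}, "
        f"within-mouth ICC ~ {icc:.3f}"
    )

print(
    "\nAt contagion 0 the ICC sits near the beta-binomial value 0.2; the\n"
    "contagion sweep adds neighbor-specific correlation on top, which is\n"
    "exactly the signal the context-aware classifier can exploit."
)
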