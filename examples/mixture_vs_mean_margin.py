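"""Compare a distribution-valued margin with its collapsed mean.

Averaging a panel's acceptable differences into one number discards the
between-expert variability; the point-mass (degenerate-margin) mode lets
the two choices be compared directly on the same posterior.  The gap grows
with the spread of the margin distribution.

Run:  python examples/mixture_vs_mean_margin.py
"""

import numpy as np

from seqsafe.decision import ArmPrior, PosteriorPair, prob_exceeds_margin
from seqsafe.mixtures import BetaMixture

posterior = PosteriorPair(
    control=ArmPrior(35.0, 128.0),       # ~58/162 events
    experimental=ArmPrior(59.0, 104.0),  # ~92/162 events
)

print(f"{'spread':>8} {'P(mixture)':>11} {'P(mean)':>9} {'gap':>7}")
for ess in (400.0, 100.0, 25.0, 10.0):
    # same mean difference (0.05), increasing between-expert spread
    mixture = BetaMixture(shapes=((0.05 * ess, 0.95 * ess),), weights=(1.0,))
    sd = float(np.sqrt(0.05 * 0.95 / (ess + 1)))
    p_mix, _ = prob_exceeds_margin(posterior, mixture, n_samples=400_000, seed=1)
    p_mean, _ = prob_exceeds_margin(posterior, mixture.mean(), n_samples=400_000, seed=2)
    print(f"{sd:8.3f} {p_mix:11.4f} {p_mean:9.4f} {p_mix - p_mean:7.4f}")
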