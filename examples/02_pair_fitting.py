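"""Recover a planted conformer pair by exhaustive scale-optimized scanning.

A synthetic "experimental" difference curve is built from one hidden
(Pr, Pfr) pair plus 1% noise; every pair of the two candidate ensembles is
then scored by the scale-optimized sum of squared errors over 0.5-2.5 nm^-1.
"""

import numpy as np

from trxs.pairfit import pairwise_scan, top_fraction, scores_to_frame
from trxs.synthetic import make_difference_experiment, make_ensembles

pr, pfr, _ = make_ensembles(n_pr=12, n_pfr=12, seed=7)
true_pair = (4, 9)
dexp, truth = make_difference_experiment(pr, pfr, true_pair, k_true=1.7,
                                         noise_sigma=0.01, seed=7)

scores = pairwise_scan(pr, pfr, dexp)
best = top_fraction(scores, count=5)
print(scores_to_frame(best).to_string(index=False,
                                      float_format=lambda v: f"{v:.4g}"))
rank = [(s.pr_index, s.pfr_index) for s in scores].index(true_pair) + 1
print(f"\nplanted pair {true_pair} (k_true = {truth['k_true']}) "
      f"ranks {rank} of {len(scores)}")
print("-> a top rank with k near k_true means the scan identified the")
print("   planted structural change; sse is the scale-optimized residual.")
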