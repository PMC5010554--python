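"""Predict solution scattering for two synthetic conformers and their difference.

Builds a two-domain hinge model in its resting and photoactivated states,
computes Debye-equation scattering curves, and locates the positive feature of
the difference curve — the fingerprint of the domain rearrangement.
"""

import numpy as np

from trxs import debye_scattering, difference_curve
from trxs.synthetic import make_ensembles

pr, pfr, truth = make_ensembles(n_pr=1, n_pfr=1, jitter_deg=0.0, seed=1)
q = np.linspace(0.1, 3.0, 146)

s_pr = debye_scattering(pr.members[0], q)
s_pfr = debye_scattering(pfr.members[0], q)
delta = difference_curve(s_pfr, s_pr)

q_peak = q[np.argmax(delta.delta)]
print(f"planted change: bend {truth['bend_true_deg']} deg, "
      f"twist {truth['twist_true_deg']} deg")
print(f"forward intensity I(q->0):  {s_pr.intensity[0]:.1f} (a.u.)")
print(f"positive difference peak at q = {q_peak:.2f} nm^-1")
print("-> the peak position reports the length scale (~2*pi/q nm) of the")
print("   light-induced rearrangement; ~0.8 nm^-1 means a ~8 nm scale motion.")
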