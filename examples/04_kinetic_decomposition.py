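"""Decompose a time-resolved series into two components and fit half-times.

A synthetic photocycle series (fast microsecond decay + slow millisecond rise,
2% noise) is decomposed onto basis patterns taken from the series itself —
the early-time curve and the steady-state average — and each amplitude trace
is fit with a half-time exponential.
"""

import numpy as np

from trxs.kinetics import decompose, extract_basis, fit_halftime
from trxs.models import DifferenceCurve
from trxs.synthetic import KineticSpec, make_timeseries

q = np.linspace(0.5, 2.5, 81)
fast_pattern = DifferenceCurve(q=q, delta=np.sin(2 * np.pi * q) * np.exp(-q))
slow_pattern = DifferenceCurve(q=q, delta=np.cos(1.5 * np.pi * q))

spec = KineticSpec(noise_sigma=0.02, seed=3)  # truth: 20 us decay, 10 ms rise
series, truth = make_timeseries(spec, fast_pattern, slow_pattern)

basis = extract_basis(series, early_time=3e-6, late_window=(0.1, 2.0))
traces = decompose(series, basis)
slow_fit = fit_halftime(series.times, traces.late, model="rise")
fast_fit = fit_halftime(series.times, traces.early, model="decay")

print(f"time points: {len(series.times)} spanning "
      f"{series.times[0]:.0e}-{series.times[-1]:.0f} s")
print(f"slow component rise half-time: {slow_fit.halftime_s * 1e3:.2f} ms "
      f"(truth {spec.slow_halftime_s * 1e3:.0f} ms)")
print(f"fast component decay half-time: {fast_fit.halftime_s * 1e6:.1f} us "
      f"(truth {spec.fast_halftime_s * 1e6:.0f} us)")
print("-> the slow rise tracks photoproduct formation; the fast transient is")
print("   treated purely as a basis pattern, not assigned a mechanism.")
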