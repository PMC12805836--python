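"""Fit a noisy simulated assay trace and recover the kinetic parameters.

Generates a dithionite trace for a partially reconstituted vesicle
population (70% active vesicles, slow scrambling), adds measurement noise
and a raw-signal baseline, then normalizes, fits a double exponential and
maps the fitted eigen-rates back to the microscopic probe and scrambling
rate constants.
"""

import math

import numpy as np

from scramblekit import assay, fitting, synthetic
from scramblekit.types import AssayParams

kp = math.log(2) / 12.0
ks = 0.0018  # s^-1 slow scrambling
params = AssayParams(probe="dithionite", k_probe=kp, k_scramble=ks,
                     fraction_active=0.7)

times = np.arange(-60.0, 2200.0, 1.0)  # 60 s baseline before the probe
raw = synthetic.generate_assay_trace(
    params, times, noise_sd=0.01, seed=42, baseline=3.2
)
trace = fitting.normalize_trace(raw)
fit = fitting.fit_decay(trace, model="bi")

print(f"converged: {fit.converged}")
print(f"plateau:   {fit.plateau:.3f}  (model predicts {assay.plateau(params):.3f})")
print(f"fast t1/2: {fit.half_times_s[0]:6.1f} s  (probe reaction)")
print(f"slow t1/2: {fit.half_times_s[1]:6.1f} s  (scrambling phase)")
fa = assay.fraction_active_from_plateau(1.0 - fit.plateau, "dithionite")
print(f"fraction of scramblase-active vesicles from plateau: {fa:.2f} (true 0.70)")

print(
    "\nThe fast phase tracks the dithionite reduction (t1/2 ~ 12 s); the"
    "\nslow phase reports scrambling; the plateau depth reports how many"
    "\nvesicles carry a functional scramblase."
)
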