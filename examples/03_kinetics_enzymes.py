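"""Degradation kinetics and enzyme-activity correlation.

Simulates a first-order decay of 2-methylnaphthalene from 5 mg/kg with the
rate that halves ~59.8% of it by day 7, fits the rate constant from noisy
replicated measurements, and correlates a lignin-peroxidase activity panel
(planted linear relation) with removal.
"""

import math

import numpy as np

import sipracs as sp

k_true = math.log(5.0 / 2.01) / 7.0  # rate giving C(7) = 2.01 mg/kg
design = sp.DecayDesign(c0=5.0, k=k_true, times=(0.0, 3.0, 7.0, 14.0), seed=1)
series = sp.make_decay_series(design)

fit = sp.fit_first_order(series)
print(f"true k = {k_true:.4f} /day; fitted k = {fit.k:.4f} /day "
      f"(95% CI {fit.ci95_k[0]:.4f} - {fit.ci95_k[1]:.4f})")
print(f"half-life = {fit.half_life:.1f} days")

means = series.replicate_means
for t, m in zip(series.times, means):
    pct = sp.format_percent(sp.removal_percent(means[0], m))
    print(f"  day {t:4.0f}: {m:.2f} {series.units}  ({pct}% removed)")

removals = np.array([sp.removal_percent(means[0], m) for m in means])
panel = sp.make_enzyme_panel(
    slope=0.15, intercept=1.0, noise_sd=0.3, removals=removals, seed=2, enzyme="LiP"
)
corr = sp.correlate_activity_removal(panel, removals)
print(f"LiP activity vs removal: R^2 = {corr.r_squared:.2f}, p = {corr.p_value:.3g}")

# The fitted first-order constant recovers the planted rate within its CI;
# removal reaches ~60% by day 7 and ~84% by day 14, and the enzyme panel's
# planted linear dependence on removal shows up as a high Pearson R^2.
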