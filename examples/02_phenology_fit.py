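"""Double-logistic fitting and phenological metrics for one pixel.

Samples a reed-like annual NDVI trajectory (season from about day 150
to day 300) on the default optical calendar with observation noise,
fits the 6-parameter double-logistic model and extracts the six
phenological metrics used as classification features.
"""

import numpy as np

from marshphen import extract_pheno_metrics, fit_double_logistic
from marshphen.phenology import double_logistic
from marshphen.synthetic import DEFAULT_OPTICAL_DATES

rng = np.random.default_rng(7)
days = np.asarray(DEFAULT_OPTICAL_DATES, dtype=float)
truth = dict(x1=150.0, x2=10.0, x3=300.0, x4=12.0, c0=0.10, c1=0.60)
ndvi = truth["c0"] + truth["c1"] * double_logistic(
    days, truth["x1"], truth["x2"], truth["x3"], truth["x4"]
) + 0.04 * rng.standard_normal(days.size)

fit = fit_double_logistic(days=days, values=ndvi)
metrics = extract_pheno_metrics(fit)

print(f"converged: {fit.converged}  (rss {fit.rss:.4f} over {fit.n_obs} obs)")
print(f"inflections x1/x3    : {fit.x1:6.1f} / {fit.x3:6.1f}  (true 150 / 300)")
print(f"SOS / EOS            : {metrics.sos:6.1f} / {metrics.eos:6.1f} days")
print(f"BV / MV              : {metrics.bv:6.3f} / {metrics.mv:6.3f} NDVI")
print(f"ROI / ROD            : {metrics.roi:.5f} / {metrics.rod:.5f} NDVI/day")
# SOS/EOS are the 50%-amplitude crossings of the fitted curve; ROI/ROD
# the 20-80% secant slopes on the green-up and senescence limbs.
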