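"""Calibrate ACMG/AMP evidence thresholds and translate scores to evidence.

The calibration finds the smallest very-strong odds of pathogenicity X such
that every ACMG/AMP evidence-combining rule reaches its required posterior
probability (prior 0.10), with evidence levels carrying odds X^(1/2^k).
Scores are then converted to log10 likelihood ratios of pathogenicity via
Gaussian densities fitted to reference-variant scores.
"""

import numpy as np

from mavemap import calibration as cal

th = cal.calibrate_acmg_thresholds(prior=0.10)
print("log10 LLR thresholds:",
      {k: round(v, 2) for k, v in th.as_dict().items()
       if k in ("PVSt", "PSt", "PM", "PSu", "BSu", "BSt")})
print(f"very-strong odds X = {th.odds_pvst:.1f}; "
      f"binding rule: {th.binding_rule}")

# densities fitted to (synthetic) pathogenic/benign reference scores:
rng = np.random.default_rng(0)
dens = cal.fit_density_pair(rng.normal(0.15, 0.20, 50),   # pathogenic-like
                            rng.normal(0.95, 0.15, 15))   # benign-like
for f in (0.0, 0.5, 1.0):
    llr = float(cal.llrp(f, dens))
    print(f"score {f:.1f}: LLRp = {llr:+.2f} -> {cal.assign_evidence(llr, th)}")
# A deeply damaging score (0.0) earns strong-or-better pathogenic evidence;
# a wild-type-like score (1.0) earns benign evidence; mid-range scores are
# indeterminate.
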