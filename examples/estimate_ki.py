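"""Estimate an in vivo OATP1B Ki from biomarker interaction data.

First recovers a known Ki from a simulated AUCR (forward-inverse check),
then fits a noisy synthetic biomarker profile by least squares.  The fitted
in vivo Ki is the value a new inhibitor would need in a victim-drug PBPK
model to reproduce the observed biomarker interaction.
"""

import numpy as np

from cpipbpk import core, ddi, ki
from cpipbpk.io import load_builtin_inhibitor
from cpipbpk.params import PhysiologyRef, cp1_reference
from cpipbpk.synthetic import generate_ddi_dataset

phys = PhysiologyRef.reference(70.0)
cp1 = cp1_reference(core.calibrate_hepatic_scaler(cp1_reference(), phys, {"fe": 0.10}))
inhibitor, regimen = load_builtin_inhibitor("rifampicin_like")

# --- ratio matching: simulate at a known Ki, then invert the AUCR
true_ki = 0.05  # uM, ~3-fold below the in vitro 0.16
truth = inhibitor.with_ki(
    {t: k * true_ki / inhibitor.ki["OATP1B1"] for t, k in inhibitor.ki.items()}
)
out = ddi.simulate_ddi(cp1, truth, regimen, phys, (0, 24), keep_profiles=False)
est = ki.estimate_ki_from_ratio(out.auc_ratio, "AUCR", cp1, inhibitor, regimen, phys)
print(f"simulated AUCR at true Ki {true_ki} uM: {out.auc_ratio:.3f}")
print(f"re-estimated in vivo Ki: {est.ki_in_vivo:.4f} uM "
      f"({est.convergence['iterations']:.0f} simulations, "
      f"residual {est.convergence['residual']:.1e})")

# --- profile fit on noisy synthetic data
times = [0, 1, 2, 4, 6, 8, 12, 24]
df, data_truth = generate_ddi_dataset(
    cp1, inhibitor, regimen, phys, true_ki_scale=true_ki / inhibitor.ki["OATP1B1"],
    sampling_times=times, cv_residual=0.15, seed=7,
)
obs = df[df.arm == "treatment"].sort_values("time_h").conc_nM.to_numpy()
fit = ki.estimate_ki_from_profile(times, obs, cp1, inhibitor, regimen, phys)
lo, hi = 10 ** (np.log10(fit.ki_in_vivo) - 1.96 * fit.convergence["se_log10_ki"]), \
         10 ** (np.log10(fit.ki_in_vivo) + 1.96 * fit.convergence["se_log10_ki"])
print(f"\nprofile fit to 15 % noisy data: Ki = {fit.ki_in_vivo:.4f} uM "
      f"(95 % CI {lo:.4f}-{hi:.4f}; truth {true_ki})")
print("the CI reflects residual noise propagated through the objective curvature")
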