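"""Estimate FvCB leaf parameters from gas exchange + fluorescence.

Builds a 13-point A/Ci curve with matched fluorescence and a 5-point
low-O2 light-response curve for a high-capacity hybrid-rice leaf (with a
little instrument noise), then runs the full estimation chain:
alpha*beta / Rd calibration -> variable-J mesophyll conductance ->
A/Ci -> A/Cc transformation -> nonlinear FvCB fit.
"""
import canophot as cp

truth = cp.LeafPhotoParams(Vcmax25=140.4, Jmax25=214.7, TPU25=12.3,
                           Rd25=1.0, gm25=0.25)
aci = cp.synth_aci_curve(cp.SyntheticConfig(truth=truth, noise_sd_A=0.3,
                                            seed=42))
low_o2 = cp.synth_low_o2_light_response(
    cp.SyntheticConfig(truth=truth, noise_sd_A=0.1, seed=43))

res = cp.estimate_leaf_parameters(aci, low_o2)
cal, fit = res["calibration"], res["fit"]

print(f"alpha*beta = {cal.alphabeta:.3f}   (truth {truth.alphabeta})")
print(f"Rd         = {cal.Rd:.2f} umol m-2 s-1   (truth {truth.Rd25})")
print(f"gm         = {res['gm']:.3f} mol m-2 s-1  (truth {truth.gm25})")
print(f"Vcmax      = {fit.Vcmax:.1f} +- {fit.se['Vcmax']:.1f}  (truth {truth.Vcmax25})")
print(f"Jmax       = {fit.Jmax:.1f} +- {fit.se['Jmax']:.1f}  (truth {truth.Jmax25})")
print(f"TPU        = {fit.TPU:.1f} +- {fit.se['TPU']:.1f}    (truth {truth.TPU25})")
print("limiting states along the curve:", " ".join(fit.limiting_states))
print("\nEach estimate sits within a few percent of the generating value;")
print("the curve walks through rubisco- -> RuBP- -> TPU-limited points as")
print("CO2 rises, which is what makes all three capacities identifiable.")
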