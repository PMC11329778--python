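"""fBV and PS from a simulated contrast-enhancement time course.

Simulates the linear macromolecular-contrast model
C_t = C_blood * (fBV + PS * t) with measurement noise, then fits it by
ordinary least squares of C_t/C_blood against t over the first 15 min.
The intercept estimates fBV (fractional blood volume, vessel density);
the slope estimates PS (permeability surface-area product, 1/min).
"""

from detensio import KineticsSpec, fit_fbv_ps, simulate_kinetics

spec = KineticsSpec(
    fbv_true=0.05, ps_true_per_min=0.003, noise_sd=0.002, seed=4
)
series, (fbv_true, ps_true) = simulate_kinetics(spec)
fit = fit_fbv_ps(series, window_min=15.0)

print(f"true   fBV = {fbv_true:.4f}, PS = {ps_true:.4f} /min")
print(f"fitted fBV = {fit.fBV:.4f}, PS = {fit.PS_per_min:.4f} /min "
      f"(r^2 = {fit.r2:.3f}, nonphysical = {fit.nonphysical})")
print("\nWith 15 one-minute samples at this noise level the estimates "
      "should sit within a few percent of the generating values.")
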