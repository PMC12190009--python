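"""Fit a biexponential decay and report the tension lifetime.

Simulates a TCSPC histogram like one acquired from a flipper-probe FLIM
ROI (tau1 = 6 ns carrying 80% of photons, tau2 = 2 ns, 1e5 photons), fits
it by Poisson maximum likelihood, and prints the recovered components.
The longer lifetime tau1 is the membrane-tension readout: higher tension
-> longer lifetime.
"""

from ermech_quant import flim, synthetic

hist, truth = synthetic.gen_decay_histogram(
    tau1_ns=6.0, tau2_ns=2.0, frac1=0.8, n_photons=100_000, seed=1
)
fit = flim.fit_biexponential(hist)
tau_report, flag = flim.report_tension_lifetime(fit)

print(f"true lifetimes: tau1 = 6.000 ns, tau2 = 2.000 ns")
print(f"fitted:         tau1 = {fit.tau1_ns:.3f} ns, tau2 = {fit.tau2_ns:.3f} ns")
print(f"photon fraction in tau1 component: {fit.photon_fraction_1:.3f} (true 0.8)")
print(f"reduced chi^2: {fit.reduced_chi2:.3f} (~1 means the model fits the noise)")
print(f"tension lifetime reported: {tau_report:.3f} ns [{flag}]")
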