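"""Single-site ITC: derive entropies from measured data, then simulate
and refit an isotherm.

First block: for each published titration of a TBM against TMEM55B, derive
dG = RT ln Kd and dS = 1000 (dH - dG)/T at 293.15 K and compare with the
printed entropy.  Second block: forward-simulate a noisy isotherm at the
RILPL1 run-(i) concentrations (0.45 mM syringe into 0.06 mM cell,
19 x 2 uL) and recover (N, Kd, dH) by least squares.
"""

from tbmkit.datasets import itc_thermodynamics
from tbmkit.itc import derive_thermo, fit_single_site, wiseman_c
from tbmkit.synth import make_synthetic_isotherm

table = itc_thermodynamics()
print("protein   run  Kd(nM)  dH      dS(printed)  dS(derived at 293.15 K)")
for row in table.itertuples():
    derived = derive_thermo(row.kd_nM * 1e-9, row.dh_kcal_per_mol, 293.15)
    print(
        f"{row.protein:9s} {row.run:4s} {row.kd_nM:6.0f} {row.dh_kcal_per_mol:7.1f} "
        f"{row.ds_cal_per_K_mol:11.1f} {derived.ds:10.2f}"
    )

print()
iso, protocol, truth = make_synthetic_isotherm(
    preset="RILPL1_i", noise_sd=0.1, seed=42
)
fit = fit_single_site(iso, protocol)
c, _ = wiseman_c(fit.n, fit.kd, protocol.cell_conc)
print(f"simulated truth: N = {truth.n:.2f}, Kd = {truth.kd*1e9:.0f} nM, "
      f"dH = {truth.dh:.1f} kcal/mol")
print(f"refit estimate:  N = {fit.n:.2f} +/- {fit.n_se:.2f}, "
      f"Kd = {fit.kd*1e9:.0f} +/- {fit.kd_se*1e9:.0f} nM, "
      f"dH = {fit.dh:.2f} +/- {fit.dh_se:.2f} kcal/mol  (c = {c:.0f})")
print("A fit recovering the generating parameters within error confirms the")
print("forward model and fitter are mutually consistent.")
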