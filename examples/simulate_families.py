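"""Forward pedigree simulation as a brute-force check of the closed forms.

Simulates sibling families under a small model point (x=10 dominant loci,
n=3 of 11 required, full penetrance), conditions on an affected, HLA-carrier
proband, and compares the simulated sibling recurrence and HLA transmission
with the analytic predictions.
"""
import mssusmod as m

params = m.ModelParameters.with_composition(
    n=3, r=2, x=10, composition=(1, 0, 0), Pt0_star=1.0, Pt1_star=1.0)
cfg = m.SimulationConfig(params=params, n_families=200_000, seed=11)
ped = m.simulate_pedigrees(cfg)

share = m.carrier_sharing_estimate(ped, proband_carrier=True)
print("Sibling HLA carriage | carrier proband:")
print("  simulated %.4f   printed formula 0.6200   exact enumeration %.4f"
      % (share["estimate"], m.sibling_carrier_exact(params.a_h, True)))

rec = m.recurrence_estimate(ped, proband_hla=True)
closed = m.recurrence_risk(params, m.RelativeClass.SIBLING, True)
print("Sibling recurrence | affected HLA+ proband (%d families):" % rec["n"])
print("  simulated %.3f   closed form %.3f   (signed gap %+.1f%% relative)"
      % (rec["estimate"], closed, 100 * (closed - rec["estimate"]) / rec["estimate"]))

cohort = m.simulate_cohort(m.SimulationConfig(params=params, n_families=200_000, seed=5))
print("Cohort prevalence: simulated %.4f   closed form %.4f"
      % (cohort.affected.mean(), m.prevalence(params)))
print()
print("Reading: the generative model matches the prevalence formula exactly;")
print("the printed recurrence forms are acknowledged approximations (single")
print("transmitting parent), so they overshoot the simulated truth.")
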