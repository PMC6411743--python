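"""Melting-curve analysis: Tm shifts and protein-complex co-melting.

Simulates a melting-range experiment (ten temperatures, vehicle vs
treated, two replicates) containing ligand-stabilized proteins and two
five-subunit complexes whose members share a melting template.  Fits
plateau sigmoids, reports melting-point shifts, and runs the
randomization test for co-melting of complex subunits.
"""

import thermsol as ts
from thermsol.melting import complex_comelt_test

cfg = ts.SimConfig.tpp_tr(n_proteins=80, noise_cv=0.02, seed=3,
                          n_complexes=2, complex_size=5, complex_jitter=0.005)
sim = ts.simulate_tpp_tr(cfg)

curves = ts.run_tpp_tr(sim.quant, sim.samples)
m = curves.set_index("protein_id").join(sim.truth.set_index("protein_id"))
stab = m[(m.effect_class == "stabilized") & m.delta_tm.notna()]
null = m[(m.effect_class == "null") & m.delta_tm.notna()]

print(f"proteins with valid vehicle+treated fits: {m.delta_tm.notna().sum()}/{len(m)}")
print(f"median delta-Tm, stabilized proteins : {stab.delta_tm.median():+.2f} degC "
      f"(true median {stab.true_tm_shift.median():+.2f})")
print(f"median delta-Tm, unaffected proteins : {null.delta_tm.median():+.2f} degC")
print()

profiles = ts.melting_profiles(sim.quant, sim.samples)
vehicle = {p: prof for (p, c), prof in profiles.items() if c == "vehicle"}
background = list(vehicle.values())
for cid, grp in sim.truth[sim.truth.complex_id != ""].groupby("complex_id"):
    members = [vehicle[p] for p in grp["protein_id"]]
    res = complex_comelt_test(members, background, n_rand=999, seed=0)
    print(f"complex {cid}: mean pairwise distance {res.observed:.4f}, "
          f"p = {res.p_value:.3f}, {res.proximity_pairs}/{res.n_pairs} pairs "
          f"below the 0.02 proximity cutoff")
print()
print("Subunits of a co-melting complex have nearly identical melting")
print("profiles, so their mean pairwise distance is far below that of")
print("random protein sets, giving randomization p-values near 1/(n_rand+1).")
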