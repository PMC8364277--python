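"""Monte Carlo photopeak and total efficiencies of the NaI(Tl) crystal.

Reproduces the broad-beam validation numbers: eps_tot 0.80 / 0.62 / 0.71 at
1 / 6 / 20 MeV, alongside the closed-form attenuation value.
"""

import linacspec as ls

crystal = ls.CrystalGeometry()
print("energy  beam    eps_p    eps_tot  (analytic eps_tot)")
for energy in (1.0, 6.0, 20.0):
    for diameter in (ls.BROAD_BEAM_CM, ls.PENCIL_BEAM_CM):
        grid = ls.EnergyGrid(lower=0.0, width=0.2,
                             n_bins=int((energy + 0.4) // 0.2) + 1)
        run = ls.simulate_depositions(
            crystal, ls.BeamGeometry(diameter=diameter), energy,
            100_000, seed=8, grid=grid)
        eff = ls.efficiency_from_simulation(run)
        analytic = ls.analytic_total_efficiency(crystal, energy)
        print(f"{energy:5.1f}  {diameter:4.1f}cm  {eff.eps_p:.3f}    "
              f"{eff.eps_tot:.3f}    ({analytic:.3f})")
print("\neps_p counts full-energy deposits (one 0.2 MeV bin); it falls with")
print("energy as escape of scattered and annihilation photons grows, while")
print("the pencil beam keeps more of the scatter inside the crystal.")
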