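"""Photon interaction data and the closed-form detection efficiency.

Looks up bundled NaI and water coefficients and evaluates the broad-beam
total efficiency of the 7.6 cm x 7.6 cm crystal, 1 - exp(-mu rho t).
"""

import linacspec as ls

crystal = ls.CrystalGeometry()

print("NaI mass attenuation (cm^2/g), coherent excluded:")
for energy in (0.5, 1.0, 6.0, 20.0):
    total = ls.mu_over_rho("NaI", energy, "total")
    pair = ls.mu_over_rho("NaI", energy, "pair")
    eps = ls.analytic_total_efficiency(crystal, energy)
    print(f"  {energy:5.1f} MeV: total {total:.4f}  pair {pair:.4f}"
          f"  -> broad-beam eps_tot {eps:.2f}")

print("\nwater mu_en/rho at 1.25 MeV (60Co mean):",
      f"{ls.mu_en_over_rho('water', 1.25):.4f} cm^2/g")
print("A photon that interacts is not necessarily counted in the photopeak;")
print("eps_tot above is the fraction of incident photons registering at all.")
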