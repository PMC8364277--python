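"""End-to-end synthetic measurement and Gold unfolding.

Generates a 6 MV bremsstrahlung-like truth spectrum (mode 0.5 MeV, mean
1.7 MeV), folds it through the broadened detector response, draws Poisson
counts at the realistic 4.3e5 total, and unfolds with 2000 Gold iterations.
"""

import numpy as np

import linacspec as ls

response = ls.build_response_matrix(
    ls.CrystalGeometry(), ls.BeamGeometry(diameter=0.5),
    n_histories_per_column=20_000, seed=1)
response = ls.broaden_response(response, ls.ResolutionModel())

truth = ls.generate_true_spectrum()
per_incident = float(response.total_efficiency @ truth.values)
expected = ls.forward_fold(truth, response,
                           ls.DEFAULT_TOTAL_COUNTS / per_incident)
measured = ls.sample_counts(expected, seed=2)

result = ls.gold_unfold(measured, response, iterations=2000)
recovered = result.spectrum.normalize()

print(f"truth mean energy      : {ls.mean_energy(truth):.3f} MeV")
print(f"raw (folded) mean      : {ls.mean_energy(measured):.3f} MeV")
print(f"unfolded mean          : {ls.mean_energy(recovered):.3f} MeV")
print(f"refold residual        : {result.final_residual:.1f} counts "
      f"(started at {result.initial_residual:.1f})")

report = ls.compare_spectra_tests(recovered, truth)
print(f"rank-sum / chi2 / KS p : {report.p_ranksum:.2f} / "
      f"{report.p_chi2:.2f} / {report.p_ks:.2f}")
print("\nThe Compton continuum drags the raw mean down; unfolding restores")
print("the incident spectrum, statistically indistinguishable from truth.")
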