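# linacspec

Direct measurement of a clinical linac's megavoltage X-ray energy spectrum
with a NaI(Tl) scintillation detector requires three computational pieces
this package provides:

1. **a detector response matrix** — the distribution of deposited energy per
   incident photon energy, computed by Monte Carlo photon transport in the
   cylindrical crystal (7.6 cm diameter x 7.6 cm, density 3.67 g/cm³);
2. **resolution broadening** — the simulated response has sharp full-energy
   peaks, while a real scintillator spreads them into Gaussians with
   FWHM/E = K/√E (K = 9.53, i.e. 11.7% at the 0.662 MeV ¹³⁷Cs line);
3. **spectrum unfolding** — the Gold algorithm, a multiplicative,
   non-negativity-preserving deconvolution

   n_i^(m+1) = n_i^(m) · c_i / Σ_j a_ij n_j^(m)

   that recovers the incident fluence spectrum *n* from the measured
   pulse-height spectrum *c* through the response matrix *a*.

Around this core sit the working tools of the measurement: channel
calibration and 25-channel rebinning of raw MCA spectra (8 keV/channel →
0.2 MeV bins), background subtraction, photopeak/total efficiency
estimators (ε_p = C_p/C_I), the closed-form broad-beam total efficiency
1 − exp(−μρt), a dose-rate budget Ḋ = Φ̇_prim·f_p·Σ p(hν)·hν·μ_en/ρ for
pile-up-free counting (≤1 photon per pulse), TPR₂₀,₁₀ beam-quality checks,
depth-dose rRMSD, and nonparametric spectrum-comparison tests (Wilcoxon
rank-sum, χ², two-sample K-S). Bundled NIST-grade photon cross sections for
NaI, water and lead drive both the transport and the dosimetry.

The intended users are medical physicists and detector modellers who want a
self-contained, scriptable version of this workflow; no measured data is
required — a synthetic-measurement module generates 6 MV bremsstrahlung-like
ground truth (mode 0.5 MeV, mean 1.7 MeV) and simulated measurements with
Poisson counting noise, so the whole chain is testable end to end.

## Worked example

```python
import linacspec as ls

# 1. response matrix of the collimated 0.5 cm beam, broadened with K=9.53
response = ls.build_response_matrix(
    ls.CrystalGeometry(), ls.BeamGeometry(diameter=0.5),
    n_histories_per_column=20_000, seed=1)
response = ls.broaden_response(response, ls.ResolutionModel(K=9.53))

# 2. synthetic 6 MV measurement at realistic counting statistics
truth = ls.generate_true_spectrum()
per_incident = float(response.total_efficiency @ truth.values)
expected = ls.forward_fold(truth, response, 430_000 / per_incident)
measured = ls.sample_counts(expected, seed=2)

# 3. unfold and compare
result = ls.gold_unfold(measured, response, iterations=2000)
print(ls.mean_energy(measured), ls.mean_energy(result.spectrum))
```

prints

```
1.1665750123291367 1.701788511301508
```

The raw pulse-height spectrum is soft-biased (mean 1.17 MeV) because the
Compton continuum shifts counts below the incident energy; unfolding
restores the incident spectrum's mean to within 0.2% of the true
1.70 MeV. Running `ls.compare_spectra_tests(result.spectrum, truth)` on this
pair gives rank-sum/χ²/K-S p-values of 0.98/1.00/1.00 — no significant
difference at the 0.05 level.

The `examples/` directory holds one short script per capability
(cross sections, response building, efficiencies, unfolding, dosimetry);
each prints the numbers it computes and what they mean. A thin CLI mirrors
the library: `linacspec build-response | unfold | simulate-measurement |
efficiency | compare | rrmsd | plan-dose-rate | run-pipeline`.

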