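# Methods

## Photon transport model

The response matrix is built by analog Monte Carlo photon transport in a
cylindrical NaI crystal (default 3.8 cm radius, 7.6 cm thickness,
3.67 g/cm³) irradiated by a parallel beam along the cylinder axis, with
entry points sampled uniformly on a disc (7.6 cm "broad" beam covering the
face, or the 0.5 cm collimated beam of the spectrometry geometry).

Per flight: the free path is exponential with the total-without-coherent
mass attenuation coefficient; the interaction channel is sampled
proportionally to the photoelectric, incoherent and pair-production
coefficients. Photoelectric absorption deposits the photon energy locally.
Compton scattering samples the Klein–Nishina distribution with the standard
composition–rejection scheme (mixture of 1/ε and ε proposal densities with
the sin²θ rejection factor, valid at all energies; validated in the test
suite against numerical integration of dσ/dε). Pair production deposits
E − 1.022 MeV locally and emits two isotropic back-to-back 511 keV photons
from the interaction point, which are tracked like primaries. Photons
falling below 12 keV are absorbed on the spot (their mean free path in NaI
is below a millimetre). A history "registers" if it deposits any energy;
under this counting rule the broad-beam total efficiency equals
1 − exp(−μρt) exactly in expectation, which is the closed-form oracle the
Monte Carlo is tested against.

**Approximations.** Charged particles are not transported: electron and
positron kinetic energy is deposited at the interaction point, and
secondary bremsstrahlung, electron escape and iodine K-fluorescence escape
(28.6 keV, invisible at 0.2 MeV binning) are neglected. Coherent (Rayleigh)
scattering is excluded from the sampled cross section: a coherent event
deposits nothing and cannot register as a count, and its small angular
deflection is irrelevant here. These choices leave total efficiencies
essentially exact but bias photopeak efficiencies at high energy: above a
few MeV, real electrons radiate bremsstrahlung that escapes the crystal, so
a photon-only model overestimates the full-energy fraction there (at
20 MeV the model gives ≈0.09 against a published ≈0.01; this regime is
documented as out of scope rather than simulated).

**Known discrepancy at 1 MeV.** The model's photopeak efficiencies at
1 MeV are ≈0.38 (broad beam) and ≈0.465 (pencil), in line with the
classical peak-to-total data for a 3″×3″ NaI crystal (photofraction ≈0.5
at 1 MeV), whereas the published table this package validates against
lists 0.47/0.52 — a 0.59 photofraction. No process omitted by this model
(electron escape, bremsstrahlung, K X-ray escape) could raise the
full-energy fraction, and the same tally reproduces the published 6 MeV
photopeak row to within statistics (0.113 vs 0.12 broad, 0.164 vs 0.16
pencil). The 1 MeV photopeak values are therefore reported as the model
computes them; the corresponding acceptance assertions fail by design
rather than being tuned to agree.

## Cross-section data

Bundled tables (`src/linacspec/data/*.tsv`, regenerated by
`tools/make_material_tables.py`) cover NaI, water and lead from 0.01 to
30 MeV on a log grid of ≈45 points per decade with exact anchor energies
inserted. The incoherent column is the integrated Klein–Nishina cross
section per electron times the material's electron density, keeping the
sampled kinematics exactly consistent with the attenuation data (binding
corrections, a few percent below ~0.2 MeV in iodine, are neglected — photons
that soft are absorbed within millimetres regardless). Photoelectric, pair
and water μ_en/ρ values are log-log interpolations through anchors
transcribed from the NIST XCOM / Hubbell–Seltzer tabulations; the iodine and
lead K edges are represented as close-spaced double knots, finer shell
structure is not. Pair production is exactly zero at and below 1.022 MeV,
with a linear ramp from threshold to the first tabulated knot. The `total`
column is the sum of the three processes and excludes coherent scattering.

## Grids and counting conventions

The standard grid is 40 bins of 0.2 MeV spanning 0–8 MeV, so bin centers
lie at 0.1, 0.3, …, 7.9 MeV; response-matrix columns are simulated at those
centers, and the 8 MeV upper edge reflects the assumed maximum energy of a
6 MV beam. The photopeak count of a monoenergetic run is the number of
histories depositing within half a bin width of the incident energy — the
response bin containing the incident energy. Raw MCA spectra carry 8 keV
channels; summing 25 channels yields the 0.2 MeV analysis bins.

## Resolution model

R (percent FWHM/E) = K/√E with E in MeV; the default K = 9.53 gives an
11.7% FWHM at 0.662 MeV, i.e. FWHM(E) = K·√E/100 MeV. Broadening convolves
each deposited-energy distribution with a Gaussian whose width follows the
*deposited* bin center; mass is conserved except for truncation at grid
boundaries (no renormalization, so near-edge truncation is visible rather
than hidden). Fitting K from measured (energy, FWHM) peaks is a closed-form
least-squares projection since the model is linear in K. The peak-area
photopeak estimator (gross counts minus the trapezoid under the line joining
the window's edge bins, ±3σ window) agrees with the full-energy tally to
about 3% at 0.662 MeV — the two conventions differ by the continuum under
the peak.

## Gold unfolding

The implementation iterates n_i ← n_i·c_i/(A n)_i on a square response
(incident grid = deposited grid). Initialization is n⁰ = c, standard for
multiplicative schemes and exact for an identity response. Bins where the
refold is zero hold their value when the measured count is also zero; a
zero refold against positive counts raises an error (the response cannot
explain the data). The refold residual ‖A n − c‖₂ is recorded every
iteration; the default 2000 iterations is far beyond what the synthetic
studies need (one iteration already cuts the spectrum rRMSD more than
five-fold), matching the observation that the reconstruction stabilizes
after a handful of iterations.

## Synthetic measurements

Ground truth is p(hν) ∝ hν^a·(E_max−hν)·e^(−b·hν), the simplest two-knob
surrogate of thick-target bremsstrahlung production plus filtration
hardening. For the default 6 MV case, b is tied to a by placing the
continuous mode at 0.5 MeV and a = 0.268236 is the moment-matched value
giving a binned mean of exactly 1.70 MeV on the standard grid (b =
0.354655/MeV). Defaults for the measurement emulation: 4.3×10⁵ expected
registered counts, matching the counting statistics of the 20-minute
measurements the workflow models. The generator reproduces the documented
spectral mode and mean and Poisson counting noise; it does not emulate
room-scatter/leakage background structure, the sub-0.25 MeV noise peak seen
in real measurements, pulse pile-up, or gain drift — so passing end-to-end
tests demonstrate the unfolding chain's correctness under ideal counting
conditions, not robustness to those instrumental effects. At 4.3×10⁵ total
counts the per-bin replicate scatter follows the Poisson expectation; bins
near the 6 MeV endpoint hold only tens of counts, so their relative SD is
intrinsically ~10%, while the fluence-carrying bins sit well under 3%.

## Statistics

Spectrum comparisons normalize both spectra and apply Wilcoxon's rank-sum
to the per-bin values, plus two-sample χ² and Kolmogorov–Smirnov tests that
treat each distribution as 100 weighted draws of the bin centers (binned
spectra carry no event lists; the effective sample size is explicit and
configurable). No multiple-testing correction is applied — three tests are
reported at a flat 0.05 level. rRMSD between depth-dose curves linearly
interpolates the calculated curve onto the measured depths. The dose-rate
budget multiplies the normalized fluence spectrum by hν·μ_en/ρ(water),
the pulse rate and the per-pulse fluence (1 MeV monoenergetic check:
0.89 nGy/s at 180 pulse/s and 1 photon/cm²/pulse). The published 3.1 nGy/s
figure for a 6 MV beam is not a validation target: it depends on the
authors' unpublished spectrum and area convention, and the stated relation
does not reconcile it with their quoted per-pulse fluence; with this
package's synthetic 6 MV spectrum the same budget gives 1.2 nGy/s.

## Problem sizes

Efficiency validation points use 5×10⁵ histories (matching the published
response-function simulations; binomial SE ≈ 7×10⁻⁴). Response matrices in
the test suite use 3×10⁴ histories per column, enough to hold per-element
statistical noise near the percent level while keeping the full suite
under ten seconds; production response builds default to 5×10⁵ per column
via the CLI.
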