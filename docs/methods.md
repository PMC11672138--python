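# Methods

This note documents the models implemented in `nitrileshift`, the
conventions and defaults they ship with, what the synthetic generators do
and do not emulate, and the numerical choices that matter.  Units are
fixed package-wide: cm⁻¹ (frequencies), Å (distances), degrees (angles),
MV/cm (fields), Debye (transition dipoles), ps/fs (times).

## Frequency model

The total C≡N frequency is

    ν = ν₀ + |Δμ| F + ½ Δα F² + Σ_HB Δν̄_HB(d, θ),

a strict sum of an electrostatic (vibrational Stark effect) term and one
geometry-dependent blueshift per hydrogen-bond contact.  Conventions:

* `F` is the field projected on the C≡N difference-dipole axis.  The sign
  is chosen so that the attractive fields of H-bond donors and polar
  solvents are *negative* and red-shift the band for positive `|Δμ|`.
  With the experimentally anchored probe parameters (ν₀ = 2236.9 cm⁻¹,
  |Δμ| = 0.2748 cm⁻¹/(MV/cm)) the Stark-only line reproduces both
  reference protein peak positions (2215.5 cm⁻¹ at −78 MV/cm, 2219.1 cm⁻¹
  at −64.9 MV/cm), which is how those two constants were determined.
* `Δα` defaults to zero; the quadratic term exists because calibration
  fits allow it, not because it ever matters for nitriles.
* The transition dipole is linear in the field, `|μ₀₁|(F) = |μ₀₁|₀ +
  α_TDM F`, and — unlike the frequency — keeps obeying its Stark relation
  in H-bonded environments.  IR intensity scales with its square.
* Additivity over at most two HB contacts is enforced; nothing beyond two
  simultaneous heavy-atom donors has been validated.

## Blueshift surface

    Δν̄_HB(d, θ) = Δν̄_d0 [ Θ(θ) (d/d₀)^{n₁}
                         + (1 − Θ(θ)) ( e^{−b(d−d₀)} − (d/d₀)^{n₂} ) ],
    Θ(θ) = cos( m (180° − θ) )

| parameter | default | meaning |
| --- | --- | --- |
| d₀ | 3.36 Å | zero crossing of the side-on (Buckingham-like) term |
| Δν̄_d0 | 16.6 cm⁻¹ | head-on blueshift at d₀ |
| b | 2.85 Å⁻¹ | side-on exponential (Pauli-repulsion-like) decay |
| m | 0.91 | cosine period modulation; zero crossing at 180° − 90°/m |
| n₁ | −4 (fixed) | head-on power, dipole–quadrupole-like distance law |
| n₂ | −8 (fixed) | side-on attractive power, induced-multipole-like |
| a | 1.30 Å⁻¹ | decay of the optional exponential head-on variant |

Design choices worth recording:

* **Algebraic grouping.**  The head-on and side-on distance laws are
  blended convexly by Θ.  This transcription reproduces the published
  contact predictions 25.4, 31.8 and 32.2 cm⁻¹ to better than
  0.2 cm⁻¹.  No smooth function of (d, θ) can reproduce *all* published
  anchor values simultaneously (two of them sit 0.01 Å/2° apart yet
  differ by 4 cm⁻¹, and one is explicitly a trajectory average rather
  than a point evaluation), so exact agreement with every printed number
  is not attainable or attempted; the residual scale of the surface
  itself is ±3 cm⁻¹.
* **Surface range.**  Over the calibrated grid (d ∈ [2.5, 5] Å, θ ∈
  [70°, 175°]) the surface spans ≈ −3.6 to +54 cm⁻¹.  The upper value is
  forced by the head-on law alone: Δν̄_d0 (3.36/2.5)⁴ = 54.2 cm⁻¹.
  Descriptions of the same surface as "−5 to 50" are rounded
  colour-scale limits, not model values.
* **θ = 180° is admitted.**  Electronic-structure calibrations avoid the
  exactly collinear pose for convergence reasons; the cosine form extends
  smoothly and the tests use it freely.
* **Extrapolation policy.**  Outside d ∈ [2.5, 8] Å the combined surface
  still evaluates (it decays to zero) but carries an
  `ExtrapolationWarning`.  The *standalone* side-on term refuses
  d < 2.5 Å outright, because the Buckingham-like shape turns over
  unphysically there.
* **Head-on variant.**  An exponential head-on law (decay 1.30 Å⁻¹) fits
  head-on data as well as the power law and is selectable
  (`headon_variant="exponential"`), but the canonical surface uses the
  integer-exponent power form.

## Calibration fits

All fits are unweighted least squares (`scipy.optimize`), nonlinear ones
multi-started from small deterministic grids with tolerances of 1e−12 on
the relative change, tie-broken by lowest residual cost.  Standard errors
are asymptotic (from the Jacobian at the optimum).  Specifics:

* `fit_vse_frequency` fits the Stark relation on the purely electrostatic
  subset only; the report also *scores* every other environment subset
  with those frozen parameters.  H-bonded subsets then score negative R²
  — the blueshift is unilateral, so the Stark line does worse than the
  subset mean.  That diagnostic is the motivation for the blueshift term.
* `extract_blueshifts` is the rearranged frequency model: observed minus
  Stark line.  On synthetic data with an injected shift it is exact by
  construction.
* `fit_headon` initialises log-linearly and then polishes on the original
  scale (a pure log fit over-weights the small-value tail; the polish
  keeps exact data exact and brings the cross-family fit — exponential
  law on power-law data — within ~0.9 cm⁻¹ RMSD).
* `fit_sideon` optionally replaces the single power term by two free
  power terms (normalised at 3 Å so amplitudes stay O(10)); on data from
  a single −8 law both exponents converge to −8, a robustness check on
  the exponent.
* `fit_joint` fits ν₀, |Δμ|, Δα plus (d₀, Δν̄_d0, b, m) simultaneously on
  electrostatic + H-bonded records with the exponents fixed.  On the
  noiseless default grid it recovers the generating parameters to
  ~1e−13 relative; with 1.8 cm⁻¹ frequency noise the residual RMSD
  reproduces the injected noise and R² ≈ 0.95.

Two R² conventions are deliberately exposed: `goodness` (about the
observed mean; fit quality, may be negative) and `goodness_identity`
(residuals about the identity line with the total sum of squares about
the mean of the *predicted* values; the convention for
observed-vs-predicted benchmark plots, where it reproduces the published
0.95 over the seven-case benchmark set in `nitrileshift.benchmarks`).

## Lineshape simulation

The FFA response is R(t) = ⟨μ(0) μ(t) exp(i ∫₀ᵗ ω(δν̄) dt′)⟩ with the
phase integrated by the trapezoid rule at the 20 fs sampling cadence, and
the spectrum its discrete Fourier transform.

* **Frequency–time bridge.**  The package converts a frequency
  fluctuation δν̄ (cm⁻¹) to a phase rate ω = c·δν̄ — the *beat-period*
  convention, under which a 20 cm⁻¹ splitting dephases on
  1/(c·20 cm⁻¹) ≈ 1.7 ps and exchange with ~2 ps residence times is
  already fast enough to coalesce the bands.  The textbook kernel carries
  an extra 2π (ω = 2πc δν̄), which moves the narrowing threshold for the
  same gap to ~0.27 ps; everything downstream (spectral axis, two-site
  closed form, coalescence rate) uses the package convention
  consistently, so static peak positions are exact either way and only
  the mapping from residence time to narrowing regime depends on it.
  This is the package's defining convention for all rate comparisons and
  is chosen to match the ~2 ps time scale quoted for a 20 cm⁻¹ gap in
  the coalescence analyses it reproduces.
* **Estimator.**  The TDM-weighted phase factor a(t) = μ(t) e^{iφ(t)} is
  autocorrelated in O(N log N) via FFT with unbiased lag normalisation,
  truncated at a maximum lag of 2¹⁵ frames (655 ps at 20 fs) under a
  half-Hann taper, zero-padded to reach the requested grid spacing
  (default 0.5 cm⁻¹), and transformed.  The long default lag window is
  what the beat-period convention requires for ~0.3 cm⁻¹ intrinsic
  resolution.  Peak positions are refined by parabolic interpolation;
  tiny negative FFT ripple is clipped to zero.
* **Apodization.**  A vibrational lifetime T₁ (default 3 ps) multiplies
  the correlation function by e^{−t/2T₁}.  Peak *positions* — the
  quantities compared everywhere — are insensitive to it; a
  no-apodization mode (`lifetime=None`) exists.
* **Integrated intensity** equals the zero-lag correlation ⟨μ²⟩ up to a
  fixed constant, hence is invariant under changes of exchange dynamics
  at fixed TDM statistics (verified to ±2%).
* **Two-site closed form.**  `kubo_two_state` solves the 2×2 exchange
  resolvent exactly (jump rates from detailed balance, optional lifetime
  broadening, a 10⁻³ ps⁻¹ Lorentzian floor so the static limit renders).
  It is the independent oracle for the FFA engine: on two-state Markov
  trajectories the peak positions of both agree within half a grid
  spacing from 0.01× to 100× the coalescence rate, including at
  coalescence itself (2²¹-frame trajectories are used near coalescence,
  where the flat-topped band makes the peak estimator noisiest).
* **Inhomogeneous limit.**  `inhomogeneous_spectrum` is the TDM²-weighted
  histogram of instantaneous frequencies (1 cm⁻¹ Gaussian smoothing by
  default); for exchange far slower than the lag window the FFA spectrum
  converges on it.
* **Band decomposition.**  `decompose_two_bands` fits two Gaussians;
  symmetric bands are an adequate shape for the near-Lorentzian-free
  spectra produced here, and on constructed two-Gaussian inputs the
  recovery is exact.  A second component below 2% area (or coincident
  with the first) flags the spectrum as single-banded.

## Synthetic generators

The generators define the test conditions; they emulate the *design* of
the reference calibration and dynamics, not their physics.

* **Calibration grid.**  420 donor configurations (20 distances ×
  21 angles uniformly over 2.5–5.0 Å × 70–175°) plus 125 point-charge
  configurations (5 × 25 over 5.0–8.0 Å), frequencies/TDMs evaluated
  exactly from ground-truth parameters plus independent Gaussian noise.
  The reference residual scale, 1.8 cm⁻¹ on frequencies, is the noise
  used by noise-matched tests; TDM noise of 5×10⁻⁴ D reproduces the
  >0.96 R² class of the TDM calibration.
* **Geometry → field surrogate.**  Fields are not observables of the
  grid geometry, so the generator assigns
  F(d, θ) = −60 · (3 Å/d)² · cos(180° − θ) MV/cm: inverse-square decay,
  strongest negative projection head-on, weakly positive side-on.  The
  60 MV/cm scale puts solvent-like head-on donors near −80 MV/cm and the
  resulting frequencies/TDMs in the observed ~2210–2260 cm⁻¹ /
  0.04–0.06 D windows.  It is a declared surrogate for force-field
  electrostatics, not a physical claim.
* **Dynamics.**  HB occupancy is a discretised two-state Markov chain
  (flip probability 1 − e^{−dt/τ} per step), geometry while bound is
  Gaussian about a configured mean — optionally along the anticorrelated
  d–θ trend (3.35 Å at 70° down to 2.93 Å head-on) — and the field is an
  Ornstein–Uhlenbeck process.  Defaults: τ_HB = τ_free = 2 ps, dt =
  20 fs, 2²⁰ frames.  The residence times are declared surrogates for
  solvent HB kinetics; every test states its own τ.  What is *not*
  emulated: continuous geometry relaxation within the bound state,
  correlated field/geometry fluctuations, non-exponential dwell times.
  Passing tests therefore demonstrate the lineshape machinery and the
  narrowing physics, not solvent realism.

## Structure extraction

PDB files are read with gemmi; only the first model is used, alternate
locations resolve to the highest occupancy (ties alphabetically) and
hydrogens are ignored by design — the calibration is heavy-atom-based
precisely because hydrogen positions are unreliable in crystal structures
and constrained simulations.  θ is the C–N···donor angle at the nitrile
nitrogen (collinear contact = 180°); extraction is exactly invariant
under rigid rotation/translation.  The donor search anchors on the
nitrile N; O and N heavy atoms of other residues within the radius
(default 4 Å) are reported, sorted by distance.

## Known limitations

* The blueshift surface is calibrated for nitriles accepting HBs from
  O/N heavy-atom donors at 2.5–5 Å; below 2.5 Å the side-on form is
  unphysical and beyond ~5 Å the model is near zero by construction.
* Carbonyl, azide and C–D probes are out of scope (carbonyls follow the
  linear Stark relation and need no blueshift term).
* No quantum-chemical or polarizable-force-field evaluation is included;
  fields must be supplied (or surrogated) by the caller.
* The FFA implementation is linear response with a Condon-violating but
  *linear* TDM map; 2D-IR, temperature dependence and non-Condon effects
  beyond linearity are not modelled.
* Apparent blueshifts extracted near coalescence sit on flat-topped
  bands; with short trajectories the peak estimator there is noisy, and
  the tests use ≥10⁶ frames for that reason.
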