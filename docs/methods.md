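# Methods

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators emulate, and the
known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Solvent composition

A hydrated DES is a 1:2:*n* salt:HBD:water mole mixture; the package
converts to weight percent water as
`wt% = 100·n·M_w / (M_salt + 2·M_HBD + n·M_w)` and back by the
closed-form inverse. Defaults: choline chloride 139.62, glycerol 92.09,
urea 60.06, water 18.015 g/mol (IUPAC 2021 atomic weights at 2 d.p.);
all overridable. With these masses the urea-system labels (2.7, 6.5,
58.1, 0.24 wt %) reproduce at their printed rounding, while the
glycerol-system labels at n ≥ 1 do not (e.g. n = 20 computes to 52.67
against a commonly quoted 53.4, and the residual n = 0.065 to 0.360
against "ca. 0.37"). The origin of those quoted values is unknown, so a
composition can carry a *stated* label verbatim next to the computed
value; a mismatch beyond 0.2 percentage points triggers a warning, never
a silent substitution. Residual water in nominally dry solvents
(n = 0.065 glycerol, 0.034 urea systems) is added to the nominal n only
when explicitly requested.

## Second-derivative UV-vis

Derivatives are Savitzky–Golay local-polynomial fits; default 9-point
cubic on 0.5 nm grids. The filter is exact for polynomials up to the
fit order (affine signals are annihilated to round-off) but attenuates
sharp features: for σ = 3 nm Gaussian bands the default window
attenuates the second derivative by roughly 4 %, which cancels in the
Tyr/Trp amplitude *ratio* but matters for absolute amplitudes; a
9-point quintic or 5-point cubic tracks a dense-grid finite-difference
oracle to ≲ 1 % RMS. Non-uniform grids are refused rather than
silently interpolated — resampling is an explicit caller decision.

Feature extraction searches the Tyr window 283–291 nm and Trp window
291–299 nm (around the ~287 / ~295 nm positions of the two
chromophores) for the most negative local minimum, refined by 3-point
parabolic interpolation. The amplitude convention was genuinely open:
measuring each trough to its nearest *red-side* maximum makes the two
features structurally asymmetric, because the Trp trough's red-side
neighbor is its own outer satellite while the Tyr trough's is the
inter-band saddle that mixes both chromophores (for two equal bands the
resulting ratio is ~1.1, not 1). The default therefore measures each
trough to its **outward-side** satellite maximum — short-wavelength
side for Tyr, long-wavelength side for Trp — which is exactly symmetric
for equal bands and linear in each band's own height. An `extremum`
mode (|minimum| itself) is provided as the alternative convention.

The center of spectral mass is the intensity-weighted mean wavelength
over the closed 305–380 nm window, computed in the wavelength domain
with no wavenumber conversion. It is exactly translation-equivariant
when the window shifts with the spectrum.

## CD deconvolution

Raw ellipticity (mdeg) converts to mean residue ellipticity as
`[θ] = θ / (10·l·c·N)` with path length l in cm, molar concentration c
and residue count N (a per-bond N − 1 convention is available; vendors
differ). Secondary structure is estimated by nonnegative least squares
of the MRE spectrum against four motif basis curves (α-helix, β-sheet,
turn, unordered) over 200–250 nm, then renormalizing the coefficients
to sum to one. Renormalization rather than a sum-to-one constraint
makes the fractions invariant to absolute-scale calibration errors.
The packaged basis is *synthetic*: Gaussian-lobe idealizations of the
canonical band shapes (α: +192 truncated at the range edge, −208, −222;
β: +196, −216; turn weak; unordered −198). Its condition number over
200–250 nm is ~33, so at 2 % noise single-spectrum fractions scatter by
~0.02–0.03 while replicate-averaged fractions are accurate to < 0.01.
The basis is for simulation and self-consistent testing; analysis of
measured spectra should load an experimentally derived basis (the
`CDBasisSet` text format). Solvents opaque in the far UV are handled by
restricting `fit_range` (e.g. 210–250 nm). Fold changes against a
reference switch from ratios to flagged absolute differences when the
reference fraction is below 0.01.

## Two-state thermal analysis

The signal model and ΔG_D expression are in the README. Fitting is
bounded trust-region least squares over the six parameters, weighted by
point uncertainties when present. Initialization: T_m at the extremum
of the smoothed dy/dT; baselines by ordinary least squares on the outer
20 % of the temperature span on each side (the exact windows are a
package default, not a claim about any particular instrument
protocol); ΔH_m from the provisional fraction-denatured slope via
`ΔH_m = 4RT_m²·(df_D/dT)|_Tm`. The fraction denatured is computed from
the fitted baselines, clipped to [0, 1] with a clipping-count
diagnostic; baselines crossing inside the span raise a degenerate-
baseline error (during fitting this falls back to the model-evaluated
f_D and flags the fit). Transition counting smooths f_D (7-point
quadratic), differentiates, and counts peaks with prominence ≥ 10 % of
the derivative maximum; curves with more than one transition are still
fitted but flagged "approximated as a two-state transition".
ΔCp defaults to 0 (pure van't Hoff): extrapolation distances from T_m
to the 63.2 °C reference are small; the full Gibbs–Helmholtz form is
available through the `dcp` field. Temperatures are kelvin internally;
readers accept °C with an explicit flag (63.2 °C ≡ 336.35 K).

## SANS

The Guinier fit is an iteratively re-windowed weighted linear fit of
ln I vs q², keeping points with q·R_g ≤ 1.3 and iterating to
self-consistency. Note the truncation bias: on an exact sphere the
q·R_g ≤ 1.3 window overestimates R_g by ~1.7 % (the Guinier
approximation error, not a fitting artifact); narrower windows reduce
it at the cost of noise sensitivity. The normalized Kratky transform
`q²I·R_g²/I(0)` vs `q·R_g` is pointwise with no smoothing.

The IFT discretizes p(r) on 101 nodes (hat functions, 4-point
Gauss–Legendre element integrals), pins both endpoints to zero, weights
by σ(q), and augments the system with √α times the second-difference
operator before nonnegative least squares. α defaults to the maximum-
curvature corner of the L-curve (log residual vs log penalty over a
15-point logarithmic grid); an explicit α overrides. Reported
uncertainties on p(r) are the diagonal of the regularized-solution
covariance (active-set effects ignored). D_max selection scans
candidates and takes the smallest whose reduced χ² is within 5 % of the
scan minimum and whose p(r) tail (last 5 % of r) stays below 2 % of the
peak; because a physical p(r) can remain above that tail level right up
to the true maximum dimension (the solid sphere does), the selector
errs a few Å high — a deliberate, conservative bias, so scans should
use a step no coarser than ~4 % of the expected size. N_agg is defined
as the concentration-normalized I(0) ratio against a monomer reference
(forward scattering ∝ c·M makes this the apparent weight-average mass
ratio); a model-based monomer reference can be supplied instead of a
measured one. No instrument resolution smearing or absolute-intensity
calibration is applied (pinhole geometry assumed).

## Activity assays

The initial lysis rate is the negative ordinary-least-squares slope
over an initial window: by default from t = 0 until the cumulative
absorbance decay first reaches 10 % of A(0) (minimum 4 points). The
default window intentionally trades a small curvature bias for noise
robustness — for an exponential decay with k = 0.05 min⁻¹ it sits
about 5 % below the true A₀k; an explicit window recovers the
instantaneous rate to ≲ 2 %. Because the window rule references A(0),
strict offset invariance of the rate holds for explicit windows.
Specific activity uses the standard turbidimetric unit
1 IU = 0.001 ΔA₄₅₀/min (configurable); relative activity is the ratio
of specific activities against the aqueous-buffer reference.

## Hydration statistics

Regimes default to low < 10 wt %, intermediate 10–40 wt %, high
> 40 wt % — round values for boundaries that are only approximate
("ca. 8–10" and "ca. 40") in practice, hence configurable; a sample at
36.5 wt % is "intermediate" by default even though native recovery can
begin there. The dome statistic is nested isotonic/unimodal
regression: the unimodal fit scans every peak split (isotonic
increasing on the prefix, decreasing on the suffix), a family that
contains both monotone fits as edge cases, so its SSE never exceeds the
monotone SSE by construction. The ≥ 20 % relative-improvement
threshold for calling a dome is a package default — no quantitative
criterion exists in the literature for this solvent system — and the
test reports the raw SSEs so users can apply their own. No p-value is
attached; formal significance testing of unimodality is out of scope.
The r₁ vs N_agg parametric relation is ordinary least squares with an
explicit exclusion set (e.g. the anhydrous solvent, which does not
follow the hydrated-series correlation).

## Synthetic generators

Each generator emulates one input class at study-like conditions and
returns a `GroundTruth` record of every parameter plus the seed; the
same seed reproduces outputs bit-identically
(`numpy.random.default_rng`). Defaults: aromatic absorbance bands at
287/295 nm with σ = 2.2 nm (FWHM ≈ 5 nm, the sharp fine-structure
regime where the two features are individually resolvable) on a 0.5 nm
grid; CD mixtures of the packaged basis on 200–250 nm; melts over
290–380 K at 1 K with baselines (−20, −0.01, −2, −0.002) and optional
multi-transition mixtures; SAS curves from sphere assemblies (monomer,
tangent dimer, linear tangent tetramer — centers at 0, 2R, 4R, 6R,
chosen for a closed-form Debye sum, not as a structural claim) on a
120-point logarithmic q-grid 0.006–0.45 Å⁻¹ with heteroscedastic noise
σ(q) = 0.02·I(q) + 10⁻⁴·I(0); log-normal-shaped emission peaks whose
mode is exactly the nominal position for any asymmetry; exponential
lysis decays with plateau.

What the generators do *not* emulate — and therefore what passing
round-trip tests cannot show about measured data: real aromatic band
shapes and solvent baseline drifts, protein-specific CD basis spectra,
aggregation during melting, interparticle structure factors and
instrument smearing in SANS, photobleaching or inner-filter effects in
fluorescence, and substrate depletion in lysis kinetics. The tests
demonstrate that each analysis inverts its own forward model correctly
at realistic noise; accuracy on experimental data depends on how well
that forward model applies.

## Numerical choices and degenerate inputs

Uniform-grid tolerance 10⁻⁶ nm; NNLS for every nonnegative fit;
least-squares tolerances 10⁻¹⁵ for the thermal fit (noise-free round
trips recover parameters to ~10⁻⁶ relative); parabolic refinement for
all sub-grid extremum positions, degrading gracefully to the grid point
when the three-point curvature vanishes. Zero spectra raise explicit
undefined-result errors (CSM, deconvolution); a zero scattering curve
inverts to p ≡ 0 with R_g = I(0) = 0 and no r₁. Fold changes against
near-zero references switch to absolute differences rather than
dividing. The pipeline collects per-stage exceptions in the report
instead of aborting, and derives per-sample, per-stage seeds by hashing
(seed, sample label, stage) so removing one sample leaves the others'
results bit-identical.

Test-suite and acceptance problem sizes (50-seed fit studies, 100-seed
CD recovery, ~20-candidate D_max scans at 120 q-points) were chosen so
statistical claims stabilize while the whole suite remains quick on a
single CPU.
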