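# desfold

Multi-probe analysis of protein conformation, stability and activity in
hydrated deep eutectic solvents (DESs).

Proteins dissolved in DESs such as 1:2 choline chloride:glycerol behave
non-monotonically with hydration: as water is added to the solvent the
protein first unfolds further, then refolds, returning toward its native
state at high water content — a *re-entrant, dome-shaped* response over
weight percent water. Establishing that behavior requires several
independent probes to agree. `desfold` implements the complete analysis
chain for each probe, plus a seeded synthetic-data generator so every
stage is verifiable end to end without any experimental data:

| probe | module | quantities |
|---|---|---|
| solvent composition | `desfold.solvent` | 1:2:*n* mole ratio ↔ wt % water |
| second-derivative UV-vis | `desfold.uvvis` | Tyr feature position λ(d²Abs,Tyr), Tyr/Trp amplitude ratio |
| Trp fluorescence | `desfold.uvvis` | center of spectral mass, CSM = Σλ·I(λ)/ΣI(λ) over 305–380 nm |
| far-UV CD | `desfold.cd` | mean residue ellipticity, secondary-structure fractions (NNLS over 200–250 nm), fold changes |
| thermal denaturation | `desfold.thermal` | f_D(T), T_m, van't Hoff ΔH_m, ΔG_D(T) |
| SANS | `desfold.sans` | Guinier R_g and I(0), normalized Kratky transform, regularized p(r) inversion, D_max, r₁, N_agg |
| lysis assays | `desfold.assays` | initial rate, specific activity (IU/mg), relative activity |
| hydration statistics | `desfold.hydration` | regime classification, dome test, r₁ vs N_agg regression |
| synthetic data | `desfold.synthetic` | seeded generators with ground-truth records for every input type |

## Core models

**Two-state unfolding.** The melting signal is
`y(T) = [y_N(T) + y_D(T)·K(T)] / (1 + K(T))` with linear baselines
`y_N = a_N + b_N·T`, `y_D = a_D + b_D·T` and the van't Hoff equilibrium
constant `K(T) = exp[−(ΔH_m/R)(1/T − 1/T_m)]`. The free energy of
denaturation is `ΔG_D(T) = ΔH_m(1 − T/T_m)` (ΔCp = 0 by default;
positive values mean the native state is favored).

**p(r) inversion.** The scattering curve and the pair-distance
distribution are related by `I(q) = 4π ∫₀^Dmax p(r) sin(qr)/(qr) dr`.
`desfold` expands p(r) on 101 linear spline nodes with
`p(0) = p(D_max) = 0` and minimizes `χ² + α‖Δ²p‖²` subject to `p ≥ 0`
(nonnegative least squares on the stacked system), with α chosen at the
L-curve corner. Derived parameters: `I(0) = 4π∫p dr`,
`R_g² = ∫r²p dr / 2∫p dr`, D_max by a scan criterion, and r₁, the first
interior maximum of p(r). The aggregation number is the
concentration-normalized forward-scattering ratio
`N_agg = (I(0)/c) / (I(0)/c)_monomer-reference`.

**Dome detection.** For a series of (wt % water, observable) points the
package fits the best monotone sequence (pool-adjacent-violators, both
directions) and the best unimodal up-then-down sequence; a relative
improvement of the unimodal SSE over the best monotone SSE ≥ 20 % flags
a dome, with the peak location read from the unimodal fit.

## Worked example

```sh
python examples/sans_pr_inversion.py
```

```
Guinier:  R_g = 33.0 A, I(0) = 149.7
IFT:      D_max = 115 A (scan), R_g = 33.7 A, r_1 = 32.9 A, chi^2 = 0.96
N_agg  = 1.50  (true weight-average: 0.5*1 + 0.5*2 = 1.5)
Kratky peak at qR_g = 1.95 (a globular scatterer peaks near sqrt(3) = 1.73)
```

The script synthesizes a 50:50 mass mixture of 30 Å sphere monomers and
tangent dimers (1 % noise), scans D_max, inverts to p(r) and reads off
the conformational parameters. The recovered D_max ≈ 115 Å brackets the
true dimer extent of 120 Å, r₁ ≈ 33 Å sits at the monomer's internal
distance peak (0.525 × 60 Å), and N_agg recovers the generating
weight-average mass ratio of 1.5 exactly. The other scripts in
`examples/` walk through one probe each; `examples/full_pipeline.py`
runs all probes over a synthetic hydration series and prints the dome
summary per observable.

A thin command line mirrors the library
(`desfold solvent wt --system glyc --n 0.4`, `desfold sans ift ...`,
`desfold run config.yaml`); every subcommand parses delimited text files
and prints JSON.

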