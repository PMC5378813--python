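# Methods

## Kinetic model

The package models CO rebinding to a hexacoordinate globin as a linear
four-state system: CO-bound (HbCO), ligand docked inside the protein matrix
(Hb:CO), pentacoordinate deoxy (Hb_p), and bis-histidyl hexacoordinate
(Hb_h). With a = k₋₂[CO] the populations obey

    d(docked)/dt = -(k₋₁ + k₂) docked + a·penta
    d(penta)/dt  =  k₂ docked - (a + k_on,H) penta + k_off,H hexa
    d(hexa)/dt   =  k_on,H penta - k_off,H hexa
    d(bound)/dt  =  k₋₁ docked

Solvent CO re-enters the docking site (not the bound state directly); the
docked ligand then either binds (k₋₁) or escapes again (k₂). This topology
is what makes the overall bimolecular association constant
k_on,CO = k₋₂ k₋₁/(k₋₁+k₂): the committor factor k₋₁/(k₋₁+k₂) is exactly
the geminate amplitude F_gem, so k₋₂ = k_on,CO / F_gem. The observed signal
in photolysis is the deoxy fraction, docked + penta + hexa.

Assumptions: pseudo-first-order CO (no solvent depletion), no
interconversion between conformers of two-conformer proteins (they are
treated as parallel, non-exchanging populations whose weights partition the
initial state), photolysis quantum yield 1 (all molecules start docked;
overridable via the initial state), a single internal docking site, and no
temperature dependence. Units are fixed package-wide: time s,
concentrations μM, bimolecular rates μM⁻¹ s⁻¹.

## Propagation

Rates span ~10 decades (k_gem ≈ 10⁸ s⁻¹ against His decays of 10⁻¹–10²
s⁻¹), so the system is stiff and is solved in closed form rather than
time-stepped. The bound state is absorbing — its column of the generator is
zero — so the three deoxy states evolve autonomously. Their 3×3
sub-generator is eigen-decomposed (numpy `eig`), and bound(t) is the exact
complement 1 − Σ deoxy(t), which makes population conservation hold to
rounding by construction while the deoxy accuracy is verified against an
independent stiff integrator (scipy `solve_ivp`, Radau, rtol 1e-10) to
better than 1e-6 in the tests. If the eigenvector matrix is
near-defective (condition number above 1e9, i.e. eigenvalues degenerate to
within ~1e-9 relative) or eigen-accuracy degrades, the propagator falls
back to a per-time-point matrix exponential (`scipy.linalg.expm`), which is
exact for a linear system at any stiffness; this replaces an explicit
t·e^{−λt} limiting branch and needs no hand-maintained degenerate-case
algebra. The fallback is deterministic, so identical inputs always produce
identical traces.

## Synthetic traces

* **Flash photolysis**: deoxy fraction on a log-spaced grid, default
  10 ns – 10 s at 60 points/decade (the experiment spans 8+ decades; no
  published grid exists). Note that with k_gem ≈ 10⁸ s⁻¹ a little geminate
  rebinding has already occurred by 10 ns, so the first sample sits
  slightly below 1 — as in the real experiment.
* **Stopped flow**: ΔA(t) = −A_T (F_P e^{−k_on,CO[CO]t} + F_H e^{−k_obs t}),
  linear grid over 2 s (1000 points, dead time 0 by default). The slow
  exponent is k_obs evaluated at that trace's [CO], times t — not
  k_obs·[CO]·t, which would be dimensionally inconsistent and could not
  saturate. By default
  the generator uses this model form so that stopped-flow round trips are
  exact; `full_scheme=True` propagates the four-state scheme from the His
  equilibrium instead, to probe the det/trace approximation gap (< 10%
  over the published parameter sets at [CO] ≤ 800 μM, ~1.4% for LjGlb1-1).
* **NO consumption**: [NO] rises linearly to the donor plateau (defaults
  6 μM for DEA, 2 μM for GSNO over 240 s), holds, then decays
  exponentially with rate k_nod·[Hb] after globin addition at t_add; the
  ferric flag suppresses consumption entirely. The effective consumption
  constant defaults to k_nod = 0.1 μM⁻¹ s⁻¹, chosen so that a 1 μM globin
  consumes a 6 μM plateau on the ~10 s timescale an NO electrode can
  follow; no published rate constant exists for this assay, only relative
  activities.

Noise is additive, Gaussian, i.i.d. and homoscedastic — the weakest model
consistent with unweighted least squares, since no residual noise level is
published (default stand-in: 0.005 of full scale). What passing tests on
these traces demonstrate is that the *analysis* is unbiased and
self-consistent; they do not capture instrument response, photoselection,
shot noise, electrode drift, or baseline error in real data.

## Multi-exponential fitting

`fit_multiexp` uses variable projection: only the log-rates are optimized
(`scipy.optimize.least_squares`, trust-region, xtol/ftol 1e-14); the
amplitudes are solved linearly at every iteration. Log-rates enforce
positivity; amplitudes are unconstrained in sign because eigen-mode
amplitudes of the hexacoordination transient can be negative. 16
deterministic starts (one even log-spread plus fixed-seed log-uniform
draws over the trace's inverse-time span) guard against local minima;
ties break by lowest SSR, then fewest amplitude sign changes. Photolysis
traces are resampled onto a log-uniform grid before fitting (no-op for the
default generator grid) so every time decade carries equal weight — over 8
decades a linear grid would let the final decade dominate the residual.
On noiseless model data the residual reaches ~1e-29.

Phase classification across a [CO] ladder (≥ 3 concentrations) matches
components by rate rank and applies:

* geminate — fastest component, rate and amplitude coefficient of
  variation < 20%;
* bimolecular (and bimolecular_2 for four-component fits) — rate linear in
  [CO] with positive slope and R² > 0.9;
* his_decay — slowest component, amplitude anticorrelated with [CO], rate
  *sublinear* in [CO] (log-log slope < 0.5).

The sublinearity criterion replaces a plain CV cut for the slow phase
deliberately: below saturation the apparent His-decay rate does vary with
[CO] (for LjGlb1-1 it moves from ~10.5 to ~24.6 s⁻¹ between 50 and 800 μM,
CV ≈ 27%), but it grows far more slowly than linearly, which cleanly
separates it from a bimolecular phase. Components matching no rule are
labeled outliers (e.g. an impurity with [CO]-independent rate and
amplitude); classification fails loudly if the fastest/slowest components
do not behave like geminate/His phases. All thresholds are arguments.

k_on,CO is the OLS slope of the bimolecular rate against [CO]; the
intercept is reported, not constrained to zero (it absorbs the
k_on,H + k_off,H offset of the effective relaxation). Because the exact
middle eigenvalue is slightly convex in [CO], the recovered slope sits
~1% low for LjGlb1-1 — an inherent property of the slope read-out, not a
fitting artifact. F_gem and k_gem are the geminate component's amplitude
fraction and rate averaged over the ladder.

## Stopped-flow fitting

The per-trace biexponential fit enforces F_P + F_H = 1 (implied by the
total amplitude at t = 0; relaxable via a flag) and orders the rates by a
ratio parameterization (k_fast = k_obs · ratio, ratio > 1), multi-started
over ratio guesses {3, 10, 100, 1000} with lmfit/leastsq at xtol/ftol
1e-15. Rates within 10% of each other, or a vanishing fraction, flag the
point as degenerate (warning, not an exception — a fully hexacoordinate
protein legitimately produces a single exponential). The saturation fit
holds k_on,CO at the photolysis value, frees the two His rates, and
propagates standard errors to K_H and F_H through the full covariance;
k_off,H errors above 100% trigger a non-saturation warning. Proteins with
two hexacoordination kinetics are handled per conformer at generation and
per rate pair in the bundled fixtures.

## NOD initial rates

The initial rate is the sign-flipped OLS slope of [NO] over
[t_add, t_add + window], divided by [Hb]. Default window 10 s (no
published window exists). For a pseudo-first-order decay the slope bias is
≈ k_nod[Hb]·window/2, so short windows trade points for fidelity; the
tests verify 5% recovery at a 1 s window.

## Published-table consistency

K_H and F_H are always recomputed from the rate pair. One published row
(LjGlb1-1 C78S) prints K_H = 56.8 while its own rates give 288/5.1 = 56.5;
the package keeps the recomputed value and records the discrepancy — the
fixture marks the printed value as discrepant, and the test suite asserts
the mismatch rather than papering over it. The conformer weights for
LjGlb1-2 C79S are not published and default to 50/50 (configurable);
LjGlb2 uses the published 70/30 split.

## Known limitations

* No CO depletion, ligand migration among multiple internal cavities, or
  temperature dependence.
* The two-conformer treatment forbids conformer exchange on the
  experimental timescale.
* Stopped-flow model-matched generation is idealized (no dead-time
  artifacts, no flow noise); full-scheme generation covers only the
  approximation gap, not instrument effects.
* The NOD module estimates initial rates only; met-Hb re-reduction,
  autoxidation, and Cys nitrosylation chemistry are out of scope.
* The literature panel for cross-species comparisons ships as an empty
  template — non-Lotus rate constants belong to their original
  publications and must be entered by the user.
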