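# Methods

## The model

An *O*-glycosidic linkage torsion angle phi is modelled as a single-state von
Mises distribution

    p(phi | mu, kappa) = exp(kappa cos(phi - mu)) / (360 I0(kappa)),

with location `mu` (the circular mean, degrees) and concentration `kappa`.
Dispersion is reported as the circular standard deviation (CSD)

    s = sqrt(-2 ln R),  R = I1(kappa)/I0(kappa),

in degrees. The CSD <-> kappa mapping is inverted numerically (Brent's method
on the monotone Bessel ratio); kappa is clamped at 1e4 (CSD ~ 0.57 deg), far
below anything resolvable from couplings measured to 0.1 Hz. A
small-dispersion convention `s ~ 1/sqrt(kappa)` is available behind a switch
(`convention="approx"`); the two agree to <1 deg for CSD <= 20 deg and
diverge slowly above, which is why fitted CSDs above ~25 deg should not be
over-interpreted at the degree level.

Each NMR J-coupling constraint is a truncated Fourier (Karplus-type)
equation

    J(phi) = a0 + sum_n [a_n cos(n phi) + b_n sin(n phi)],

parameterized by ordinary least squares on a DFT-style (phi, psi, J, energy)
grid after (i) removing structures above a 10 kcal/mol relative-energy
cutoff and any flagged as geometrically distorted ("trimmed" equations), and
(ii) optionally restricting psi to its experimentally supported window under
closed circular containment ("constrained" equations). The fit residual RMSD
reflects the coupling's secondary psi dependence. Distortion detection is not
computed here — it arrives as a boolean mask in the grid file, because it is
a structure-inspection judgement upstream of this package.

The ensemble-averaged coupling under the torsion model has the closed form

    <J> = a0 + sum_n A_n(kappa) [a_n cos(n mu) + b_n sin(n mu)],
    A_n(kappa) = I_n(kappa)/I_0(kappa),

used as the default fast path; 0.5-deg fixed-grid quadrature of
`integral J(phi) p(phi) dphi` and Monte-Carlo averaging over von Mises draws
are kept as independent slow paths and are cross-checked against the closed
form in the test suite (agreement to 1e-6 Hz and 3 Monte-Carlo standard
errors respectively).

## The fit

Given >= 2 measured couplings with matching equations, the fit minimizes the
unweighted RMSD (Hz, denominator = number of couplings) between measured and
ensemble-averaged couplings over (mu, CSD). The search is Monte Carlo
multi-start: `n_starts` (default 200, RNG seed 1234) uniform random
candidates over mu x CSD in [1, 120] deg are scored with the closed form,
the best `n_refine` (default 10) are polished by bounded
`scipy.optimize.least_squares` in (mu, log kappa), and the best polished
candidate wins; candidates tied within 1e-6 Hz resolve to the smaller CSD.
Refining only the top-scoring candidates keeps large replicate studies fast;
the objective is a smooth two-parameter surface and the result matches an
exhaustive 0.5 x 0.5 deg grid search on every test problem (where the valley
floor is flatter than 1 mHz across grid cells, tied cells are treated as one
minimum). A pure random search (`method="mc"`) is available for comparison
with the refined search.

CSD bounds are [1, 120] deg: below ~1 deg the kappa mapping saturates, above
~120 deg the model is indistinguishable from uniform. The mean search covers
the full circle by default; `mu_bounds` can restrict it to a chemically
motivated window. For glycosidic phi of beta-pyranosides the analyses here
use the syn window (-60 to +120 deg) favoured by the exo-anomeric effect,
because coupling sets averaged over near-uniform distributions can
accidentally match the measured values in regions the molecule does not
populate.

Measurements carry signed values (sigma 0.1 Hz by default). When a
measurement's sign was assumed rather than determined, the fit is repeated
with the sign flipped and the lower-RMSD branch is reported with a flag.

The RMSD profile (`rmsd_profile`) evaluates the objective on a dense
(mu, CSD) grid and reports the CSD interval over which the mu-minimized RMSD
stays within a tolerance (default 0.1 Hz, the per-measurement uncertainty)
of the global minimum. A wide interval means the coupling set cannot
discriminate dispersions — the diagnostic behind inflated CSDs when only
conventional couplings constrain phi.

## Coupling groups

Four phi-sensitive couplings per disaccharide are used in three
combinations: Group I (conventional trans-glycosidic 2JCOC, 3JCOCC, 3JCOCH),
Group II (the nonconventional geminal 2JCCH replacing 2JCOC), Group III (all
four). The geminal 2JCCH across the C2'-C1'-H1' pathway is usable as a phi
constraint only when the donor residue carries an N-acetyl group or no
substituent at C2', which removes its secondary C-O rotational dependence.

## Synthetic data

The generators fabricate every upstream input with the statistical structure
the analysis assumes, so the pipeline is testable without quantum-chemistry
or MD runs.

Truth curves are fixed low-order constructions per coupling kind, chosen
once from the documented torsional behaviour and held fixed:

* `2JCCH`: positive, bimodal; maxima near 120 and 300 deg (~6.4 and ~6.9
  Hz), minima below 1 Hz near 0 and 180 deg; the rise from the 0-deg minimum
  through the populated syn region is sinusoidal (convex), which is what
  gives this coupling its dispersion-discriminating power.
* `2JCOC`: negative everywhere, plateau near -2.1 to -2.9 Hz across phi =
  0-180 deg (slope in [20, 160] deg below 25% of the global maximum slope),
  rising toward ~-0.2 Hz around 270 deg.
* `3JCOCH`, `3JCOCC`: classic A cos^2 + B cos + C Karplus shapes in their
  own pathway torsion; the 3JCOCC pathway (C2'-C1'-O1'-Cx) is offset +105
  deg from the H1'-referenced phi (the exact projection angle depends on
  ring geometry; the offset is chosen so the curve value in the populated
  region matches the observed 2.9-3.2 Hz while the mean sits on the curve's
  quasi-linear flank).

A seeded jitter (+-5% amplitudes, +-3 deg phases) produces
compound-to-compound variants that still satisfy the shape constraints,
which are re-verified at construction time.

Torsion grids are full 24 x 24 matrices at 15-deg spacing (576 rows). The
psi-scatter added to J is a smooth two-harmonic function of psi normalized to
a prescribed SD (defaults per kind: 0.40 Hz for 2JCOC, 0.20 for 2JCCH, 0.15
for the 3J kinds — the geminal COC coupling carries the largest secondary
dependence). The relative-energy surface is a generic two-term periodic
function with its minimum in the exo-anomeric syn region (phi ~ 60, psi ~ 0),
scaled so a configurable fraction (default 20%) of cells exceed the
10 kcal/mol cutoff; a configurable fraction (default 2%) is flagged
distorted. Only the energy surface's role (excluding high-energy cells away
from the populated region) matters, not its realism.

Pseudo-experiments add Gaussian noise (default 0.1 Hz) to the exact ensemble
averages of a planted model. MD-like traces draw from the model's von Mises
marginal, optionally with AR(1) frame-to-frame correlation through a
Gaussian copula that leaves the marginal exact.

What the generators do **not** emulate: real DFT secondary-dependence
structure (the psi-scatter is a smooth proxy), multimodal torsion
populations, ring-pucker excursions, force-field artefacts, and — most
importantly — the true per-compound coupling equations. Passing recovery and
mechanism tests therefore demonstrates correctness of the inference
machinery under the stated model, not the accuracy of any particular
published coefficient set.

## Published-data analyses

The four measured couplings per compound (values in Hz, +-0.1 Hz) and the
published per-compound fit statistics and MD summaries are frozen in
`maat.datasets`. Reproducing the published per-compound fits requires the
original constrained equation coefficients, which are distributed in the
study's supplementary material and are not redistributable here; the package
defines a JSON transcription format (`load_equations`) and the corresponding
checks in `tests/test_acceptance.py` run whenever a transcription is placed
at `data/esi_constrained_equations.json` (they fail, by design, while it is
absent). When the synthetic stand-in equations are used instead
(`scripts/acceptance.py`), fitted means land in the published 33-40 deg
range but fitted CSDs are not comparable: CSD is sensitive to the local
curvature of the true coupling equations, which stand-ins cannot supply.

## Numerical choices and degenerate inputs

* Bessel functions are evaluated in exponentially scaled form (`i0e`, `ive`)
  so the closed-form average and pdf are stable to kappa = 1e4.
* The pdf integrates to 1 to 1e-8 on a 0.05-deg Riemann grid (periodic
  integrand, spectral accuracy).
* A CSD at the uniform limit maps to kappa = 0 with a warning, not an error;
  a sample with zero mean resultant length yields (NaN, inf) from
  `circular_summary`, flagged rather than raised.
* Fourier fits require >= 2N+1 points and a full-rank design; rank
  deficiency (too few distinct phi) raises.
* Histogram overlays renormalize the model density on the bin grid so both
  columns integrate to exactly 1 and are directly comparable.
* MD CSDs default to the circular convention; a linear SD of angles unwrapped
  about the circular mean is available (`convention="linear"`), the two
  agree closely for narrow unimodal distributions.

## Problem sizes used in validation

The recovery study uses 100 replicates of 4-coupling pseudo-experiments at
truth (37, 15) deg and 0.1 Hz noise; oracle cross-checks use 50 random
(equation, model) pairs with 1e6-draw Monte Carlo and 20 fit-vs-grid-search
problems; the discriminability study uses 20 replicates per coupling set at
truth (38, 14) deg; MD-trace round trips use 1e6 frames. These sizes give
stable medians while keeping the full validation run in the
tens-of-seconds range.

## Known limitations

* Single-state (unimodal) models only; no mixture fitting.
* No propagation of equation-parameterization uncertainty into CSD error
  bars — fits report point estimates, and fitted CSDs behave as upper
  limits: systematic error in the equations broadens the fitted
  distribution (verified in the test suite), so small fitted CSDs are more
  trustworthy than large ones.
* psi itself is not fitted; psi windows for constrained parameterization are
  inputs.
* The synthetic stand-in equations support method validation, not
  quantitative reproduction of published per-compound CSDs.
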