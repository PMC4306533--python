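# Methods

## The binding model

A cap analogue L binding a single site on an eIF4E-family protein P at
equilibrium obeys mass action,

    K_as = [PL] / ([P][L]),      [P] = [P0_act] − [PL],   [L] = [L0] − [PL],

where `[P0_act]` is the concentration of *binding-competent* protein and
`[L0]` the total added ligand. At the protein concentrations used in cap
titrations (0.1–0.2 μM) and dissociation constants down to ~2 nM, bound
ligand is not a negligible fraction of total at the low end of the
titration, so the free-ligand approximation `[L] ≈ [L0]` fails and `[PL]`
must be taken as the physical root of the quadratic

    [PL] = (s − sqrt(s² − 4·[P0_act][L0])) / 2,   s = [P0_act] + [L0] + 1/K_as.

`complex_concentration` evaluates the algebraically equivalent,
cancellation-free form `2ab/(s + sqrt(s² − 4ab))`, which stays accurate to
~1e−13·[P0_act] up to the stoichiometric regime (K_as → 1e9 μM⁻¹); the
direct subtractive form loses all significant digits there.

The observable is total fluorescence of the solution:

    F([L0]) = f0 − Δf·[PL] + f_L·([L0] − [PL])

with `f0` the zero-ligand emission (absorbing both active and inactive
apo-protein; the two are not separately identifiable from a titration),
`Δf = f_Pact − f_PL ≥ 0` the quench amplitude per μM of complex, and
`f_L ≥ 0` the emission efficiency of free ligand, which dominates the
signal at high ligand. Raw intensities are corrected for dilution by
scaling to the reference (first-point) volume and for the inner filter
effect with the standard half-path form `10^((A_ex + A_em)/2)`; both
corrections are the identity when the optional columns are absent.

Assumptions: one binding site, no cooperativity, equilibrium at every
point, homogeneous active fraction, and wavelength-independent
coefficients. Kinetics, anisotropy, and multi-site models are out of scope.

## Fitting and pooling

`fit_titration` estimates {K_as, [P0_act], f0, Δf, f_L} by
trust-region-reflective least squares (scipy) with an analytic Jacobian —
the derivatives of `[PL]` with respect to K_as and [P0_act] come from
implicit differentiation of the mass-action equation — and physical bounds
K_as > 0, 0 < [P0_act] ≤ 2× nominal, Δf ≥ 0, f_L ≥ 0. Starting values are
physics-informed (f0 from the first point, f_L from the terminal slope, Δf
from the apparent plateau); K_as is multi-started on the log grid
{0.1, 1, 10, 100} μM⁻¹ and the best converged start kept, because tight
binders place the optimum in a shallow valley where a single start can
stall. On noiseless model-generated curves the generating parameters are
recovered to ≲1e−14 relative.

Standard errors are the square roots of the diagonal of
`σ²·(JᵀJ)⁻¹` with `σ² = RSS/(n−p)`, computed from an SVD of J that keeps
*every* numerically nonzero direction. This matters: in the weak-binding
regime ([P0_act]·K_as ≪ 1) the data constrain essentially only the product
Δf·[P0_act], so JᵀJ is severely ill-conditioned, and truncating the small
singular values (as generic covariance code does) underreports the K_as
uncertainty badly — measured coverage of ±2·SE intervals drops from ~95% to
~55%. Fitting [P0_act] at very low K_as is intrinsically poorly identified;
this surfaces as a large reported SE rather than being silently resolved.
`FitSettings(fix_p0=True)` pins it at the nominal concentration instead.

Replicates of one protein×ligand×buffer cell are pooled by inverse-variance
weighting, `K = Σ(k_i/σ_i²)/Σ(1/σ_i²)`, `SE = sqrt(1/Σ(1/σ_i²))`. Because
the weights use *estimated* SEs, which correlate with the estimates
themselves, pooling a tight binder is biased slightly low (a few percent at
1% noise with 4–6 replicates); the Monte-Carlo suite quantifies this and it
is accepted as the cost of matching the standard pooling scheme.

## Free energies, ratios, charges

ΔG° = −RT·ln(K_as·1e6), converting μM⁻¹ to the molar scale (standard state
1 M), with R = 1.9872041e−3 kcal mol⁻¹ K⁻¹ and T defaulting to 293.15 K
(20 °C); both overridable. Ligand transitions for one protein are
ΔΔG°(A→B) = −RT·ln(K_B/K_A) — the concentration scale cancels, the sign
convention makes a tighter destination negative ("energy gain") — with
first-order propagation of independent relative errors,
σ_ΔΔG = RT·sqrt((σ_A/K_A)² + (σ_B/K_B)²). ΔΔG° and affinity ratios are
computed within one buffer tag unless a cross-buffer comparison is
requested explicitly (`allow_cross_buffer`), since 10% glycerol alone
shifts association constants by tens of percent.

`build_ddg_table` emits an explicit gap row when either ligand of a
transition is unmeasured for a protein×buffer cell, so report formatting
can print a dash rather than dropping the row. Ratio columns carry both the
raw value and a two-decimal display rounding (banker's rounding). Note that
recomputing ratio or ΔΔG° values from a table whose K_as entries are
themselves rounded to 2–3 significant digits can disagree with values
computed from unrounded inputs by about one unit in the last printed digit;
the bundled `kas_table.tsv` has exactly this character.

Cap net charge at a given pH is the fully protonated reference charge plus
independent Henderson–Hasselbalch fractional deprotonation per ionizable
group (N1 proton of the 7-alkylguanine ring, pK_a1; secondary proton of the
terminal phosphate, pK_a2). Site–site coupling and pK_a prediction are out
of scope. The shipped catalogue's pK_a values are **illustrative** defaults
from general nucleotide chemistry — the charge-vs-pH output is meant for
trend plots (charge becoming more negative with phosphate count), not for
quantitative electrostatics, until experimental pK_a values are supplied.

## Synthetic data

`simulate_titration` draws F_i = model(L_i)·(1 − d·i/(n−1)) + N(0, s·f0):
homoscedastic Gaussian noise with SD a fraction `s` of f0 (default 1%;
photon-count detail is not modeled), and an optional linear-in-index signal
drift losing a total fraction `d` at zero ligand (0.10–0.25 emulates an
unstable apo protein; real drift is a time course, but point timing is not
modeled, so linearity in index is a documented simplification). Identical
seeds give bit-identical curves; replicate studies spawn per-curve seeds
deterministically from one integer.

The default ligand schedule is a zero point plus 24 log-spaced in-cuvette
totals from 0.02 to 50 μM. Titrations of this design add aliquots from a
stock series spanning roughly 2 μM to 5 mM; what matters for inference is
that the resulting in-cuvette totals bracket the binding transition of a
0.1–0.2 μM protein across the full affinity range studied (K_d ≈ 2 nM–30
μM). A schedule whose first nonzero total already saturates the protein
leaves K_as unidentifiable, so the defaults are chosen to span the
transition: that is the regime the method itself requires.

A deliberate negative control is wired in as a regression test: with 25%
drift and no drift term in the fitted model, recovered K_as is biased low
by ≳10%. That is the quantitative reason unstable apo proteins must be
stabilized (glycerol, N-terminal truncation) *before* titration rather
than corrected afterwards.

What passing on synthetic data does not show: real titrations have
heteroscedastic photon noise, wavelength structure, pipetting error
correlated with the schedule, and drift that is neither linear nor
index-locked. Replicate scatter in real studies need not match the
fit-reported SEs, so pooled synthetic SEs say nothing about any particular
instrument.

`simulate_family_alignment` plants a chosen number of family-discriminating
columns on a shared backbone, with optional within-family substitution
noise. It produces gap-free, equal-length toys — no indels, no phylogenetic
correlation — sufficient for validating the discrimination scan against
exhaustive enumeration, not for benchmarking on real alignments.

## Sequence discrimination

A discriminating position is an alignment column whose within-family modal
residue reaches a conservation threshold in *both* families while the two
modal residues differ. The threshold default is 1.0 (strict identity);
0.875 (7 of 8 sequences) is the documented relaxed alternative for
eight-pair alignments. Gap handling is explicit: under the default
`strict` policy any gap in a family disqualifies the column; the `ignore`
policy drops gapped rows before counting. Reports give 1-based positions in
the ungapped coordinates of a designated reference sequence, and an
editable YAML annotation (cap-pocket and partner-binding residues keyed to
human eIF4E1a numbering) tags hits within a small window of functional
sites. Orthologue numbering conventions that differ by a constant shift
(the frog 1a convention runs 4 residues behind) are handled by a bundled
offset table.

N-terminal charge is the formal count (+1 K/R, −1 D/E, histidine
configurable 0/+1) over a window defaulting to 27 residues — the
unstructured leader preceding the globular domain, acidic in the canonical
family and basic in the oocyte-enriched one.

## Problem sizes and numerical choices

The statistical validation uses 200 simulated curves per condition at
K_as ∈ {0.3, 7.8, 68.4} μM⁻¹ and 1% noise (median signed relative bias
≤ ~3%, ±2·SE coverage ≥ ~90%), a 10⁴-point grid for the isotherm-vs-
bisection oracle (agreement ≤ 1.5e−13·[P0_act]), and ten 6-replicate
studies for the end-to-end ratio recovery (median within ~4% of the planted
3.11). These sizes were chosen so the whole validation runs in about a
minute on one core while keeping Monte-Carlo error well below the
tolerances being checked. Optimizer tolerances are xtol = ftol = 1e−12;
ties between multi-start solutions resolve to the lowest residual sum of
squares; degenerate inputs (flat curves, < 6 points, zero replicate SEs)
raise typed errors rather than returning garbage.

## Known limitations

* f0 absorbs the inactive-protein emission; an independent active-fraction
  assay cannot be replaced by the fit.
* Inverse-variance pooling with estimated SEs is slightly biased low for
  tight binders (see above).
* The charge catalogue's pK_a values are placeholders pending experimental
  numbers; charge-vs-pH output is qualitative.
* The discrimination scan treats columns independently; covarying
  substitutions and indel structure are invisible to it.
* Cross-buffer comparisons are only as good as the buffer tags supplied;
  nothing detects an unlabeled buffer change.
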