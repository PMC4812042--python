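# Methods

## Data model and diagnostics

The basic datum is a triple (μ_k(A), μ_k(B), μ_k(A or B)) per item k. Two
semantics occur in practice and the package handles both:

- **Collapse probabilities**: each column is a distribution over the n items
  (the probability that the concept "collapses" to item k when one best
  member must be chosen) and sums to one. The packaged 24-item reference
  table has this form; its printed 4-decimal columns sum to 0.9999–1.0001,
  which is why the default column-sum tolerance is 0.003.
- **Membership weights**: per-item probabilities with no cross-item
  constraint (`normalized=False` tables; the classical synthetic regime).

Raw 7-point ratings (−3…+3) convert to collapse probabilities by shifting
+3, averaging over participants per item, and dividing by the sum over
items. The conversion is treated as interchangeable with the direct
best-member experiment; no quantitative mapping between the two is
available, so none is modeled.

The classicality rule implemented by `classify_item` uses disjunction
semantics: classical iff max(μ_A, μ_B) ≤ μ_AorB ≤ min(1, μ_A+μ_B);
below the max is underextension (below the min, double underextension);
above the additive bound is overextension. The `double-overextension` label
exists in the enum for completeness but is unreachable under this rule — it
names the conjunction-side phenomenon (combination above both components)
and is kept so that reports from conjunction data can reuse the type. The
rule is exposed generically; note that applying it to collapse-probability
columns (distributions over items) is a diagnostic convention, not a
theorem about per-item membership weights.

Items with μ_A = 0 or μ_B = 0 are flagged at load time
(`zero_component_items`): the phase construction divides by √(μ_A μ_B).

## Hilbert construction

Phases: cos φ_k = (μ_AorB − (μ_A+μ_B)/2) / (c_k √(μ_A μ_B)). Conventions:
the A-side coordinate phases α_k and basis phases γ_k are set to zero, so
the B-side coordinate phase β_k equals φ_k; phases are stored and printed
in degrees (radians internally). The sign of φ_k is ε_k from the greedy
scheme: budgets λ_k sorted descending (ties broken by original item order,
stable sort), first sign +1, then subtract whenever the running sum stays
≥ 0, else add. Every partial sum is non-negative by construction. The
overlap of the rank-1 item,

    c_m = √[((S_n − λ_m)² + (μ_AorB − (μ_A+μ_B)/2)²) / (μ_A μ_B)],

closes the sine-sum orthogonality residual exactly; all other c_k = 1.
Vector A has coordinates √μ_k(A) (phase 0) and 0 in the extra (n+1)-th
coordinate; vector B has √μ_k(B) e^{iφ_k} for k ≠ m and splits item m as
b_m c_m e^{iφ_m} on coordinate m plus b_m √(1−c_m²) (phase 0) on the extra
coordinate, with ã_25 = 0 and the free split phase set to zero.

On the packaged reference table this construction yields the published
per-item columns: note the published concept-vector listing prints the
rank-1 (Tomato) coordinate with the *unsplit* modulus b_m and the c=1
phase, which is not unit-norm as printed; the package follows the split
construction (modulus b_m·c_m, phase from c_m), and the regression
tolerance (±0.5°) absorbs the listing's 0.1° rounding differences
elsewhere (e.g. Yam 98.1° vs 98.0°).

Numerical choices: a relative slack of 1e−12 at the arccos/sqrt domain edge
absorbs float round-off; genuinely infeasible items (|interference| >
√(μ_A μ_B), or required c_m > 1) abort with an error naming the items —
the construction has no provision for overlaps above one, and silent
clamping would fake a model where none exists. Concept-vector unit norm is
enforced to 1e−9 for exactly normalized input and to twice the
normalization tolerance for rounded printed input (the squared norm
inherits the column-sum residual).

The identity reconstruction (predict) uses the interference formula; an
independent route evaluates ⟨ψ|M_k|ψ⟩ on the explicit superposition vector
(1-D projectors per item, 2-D for the rank-1 item) and agrees to machine
precision — kept as an internal consistency check between the angle-level
and vector-level representations.

## Wave-field illustration

Densities are |ψ|² = D·exp(−(x²/(2σ_x²) + y²/(2σ_y²))): D is the *peak
density*, and probabilities are recovered as μ = δ_eff · |ψ|², where the
effective cell weight δ_eff approximates the integral over an item's small
cell by cell-area × center density. δ_eff = 0.1 is fixed by calibration:
0.1 · D_A equals the peak Fruits probability (Apple, at the packet-A
center) and 0.1 · D_B the peak Vegetables probability (Broccoli) with the
published amplitudes. (An erratum note: the prose near the published
solution states a cell weight of 0.01, which is inconsistent with its own
parameter table; 0.1 is the value that reproduces the tables and is used
throughout.)

Item locations solve δ_eff|ψ_A|² = μ_A and δ_eff|ψ_B|² = μ_B — the
intersection of two axis-aligned ellipses. The A-ellipse is parametrized by
angle and the B-residual root-found with Brent's method on sign changes of
a 1440-point scan; up to four intersections exist, and a branch hint
selects the nearest. Probabilities within 5e−4 (`atol`) of a packet peak
collapse the corresponding ellipse to its center point. Existence requires
μ ≤ δ_eff·D for both packets and overlapping ellipses; failures raise with
the item name.

Phase targets use the unit-overlap convention for *all* items (including
the rank-1 item, whose Hilbert-model phase differs slightly through c_m):
this is the convention under which the solved field's constant coefficient
reproduces the published value at the origin. Target signs default to the
greedy ε_k; cos is even, so node densities are sign-invariant, but the
interpolated field between nodes depends on this convention — the
published coefficients' sign convention is not recoverable from the
printed solution, so only the constant coefficient is checked against it.

The field θ(x, y) interpolates the 24 signed targets over the fixed
monomial basis {1, x, y, x², xy, y², …, y⁵, x⁶, x⁵y, x⁴y²} by a square
linear solve. The design matrix at the published coordinates has condition
~1e9; with interpolation residuals below 1e−8 degrees this is harmless,
and the interpolator raises only above a condition of 1e13 (reporting the
estimate). Coefficients are in degrees.

Default rendering grid: x ∈ [−12, 16], y ∈ [−4, 12] at 600×400 samples,
covering all published coordinates with margin.

## Negation statistic

I = 1 − μ(A and B) − μ(A and B′) − μ(A′ and B) − μ(A′ and B′) is zero for
any quadruple drawn from one classical joint distribution (a de Morgan /
total-probability identity). Measured concept data fluctuate around
I ≈ −0.81, between the classical 0 and the pure-quantum −1; the package
documents the −1 (the two-sector model realizing it is out of scope) and
exposes the quantum-informed total 1.81 as a parameter defaulting to the
published value. Out-of-range fourth-weight predictions are flagged, never
clamped — the overflow is itself diagnostic. Reproducing the −0.81
empirical average is out of scope (those datasets belong to companion
studies); only the prediction rules are implemented.

## Synthetic generators

The quantum regime draws both component columns from a symmetric
Dirichlet (concentration 5 at n = 24 — a moderate spread with roughly a
tenfold max/min ratio, comparable to the reference study's columns), phase
magnitudes uniform on [30°, 150°] with random signs (keeping cos φ away
from ±1, where arccos recovery is ill-conditioned), and builds the
disjunction through the interference formula at unit overlap. By AM–GM the
result is always a probability; the disjunction column is left exact by
default (its sum reported) because rescaling would destroy the identity
that parameter-recovery tests rely on. The classical regime draws one flat
Dirichlet 2×2 joint per item, so every diagnostic must come back classical
and I vanishes identically. The Likert sampler draws shifted ratings
binomial(6, w_i) per participant × item — the simplest categorical
mechanism whose shift-and-normalize conversion is unbiased for the target
weights.

What the generators emulate — and what they do not: they reproduce the
*structure* of membership studies (normalized columns, interference-built
or classically-built combinations, rating noise), not participant-level
responses, item correlations, response styles, or the empirical phase
distribution of real data. Passing recovery tests therefore shows the
pipeline inverts its own generative model to numerical precision, not that
real data satisfy the model.

## Problem sizes and determinism

All reference computations are desk-scale (24 items; a 24×24 solve).
Synthetic tests use n = 20–24 items; the Likert convergence check uses
10⁵ participants (≈2.4M binomial draws). All randomness flows through
`numpy.random.default_rng(seed)`; hypothesis property tests run
derandomized.

## Known limitations

- Two-concept disjunctions only; no general n-concept combinations and no
  conjunction Fock-space model.
- The sign convention of the interpolated phase field between nodes is a
  choice; published mid-field fringes are reproduced qualitatively, not
  coefficient-by-coefficient.
- The wave-field Gaussian widths are treated as given constants (the
  published solution is explicitly non-unique); no refit is attempted.
- Classicality diagnostics on collapse-probability columns are a
  convention (see above), and tables with zero component probabilities
  cannot enter the Hilbert construction.
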