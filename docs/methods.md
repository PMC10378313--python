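# Methods

## Model

`gearshift` implements a linear (proportional) non-equilibrium thermodynamic
model of catabolic free-energy transduction. A transducer converts the Gibbs
energy drop of catabolism, ΔGc > 0 (substrates minus products), into Gibbs
energy stored in ATP, ΔGp > 0, against the dimensionless **force ratio**
X = ΔGp/ΔGc. Two complementary descriptions are provided and kept exactly
equivalent.

### Mosaic description

K parallel catabolic pathways share a total catalytic capacity L. Pathway i
carries a capacity fraction w_i (Σ w_i = 1) and is fully coupled to ATP
synthesis with stoichiometry n_i ≥ 0 (ATP per unit catabolic flux). Each
pathway obeys a proportional flux–force relation:

    Jc_i  = w_i · L · ΔGc · (1 − n_i X)        (catabolic flux)
    −Jp_i = n_i · Jc_i                          (ATP synthesis flux)

An optional uncoupled leak (proton leak, maintenance) hydrolyses ATP at rate
λ·L·ΔGc·X, with λ = Lpℓ/L the dimensionless specific-uncoupling
coefficient. Totals are affine in X:

    Jc  = L·ΔGc·(1 − ν X),             ν  = Σ w_i n_i
    −Jp = L·ΔGc·(ν − σ² X),            σ² = Σ w_i n_i² + λ

Derived quantities: the **flux-ratio stoichiometry** n(X) = −Jp/Jc (the
realized "gear setting", which falls as X rises even though every mechanism
parameter is fixed) and the **efficiency** η = n(X)·X. Two critical force
ratios follow in closed form: ATP synthesis stalls at X = ν/σ², and
catabolism reverses at X = 1/ν. Stalling strictly precedes catabolic
reversal whenever two distinct stoichiometries carry capacity or λ > 0.

### Phenomenological description

The classical black-box form uses a phenomenological stoichiometry Z and a
degree of coupling q ∈ [0, 1]:

    Jc  = L·ΔGc·(1 − qZX),    −Jp = L·ΔGc·(qZ − Z²X)

The mosaic model maps onto it exactly via

    Z = sqrt(Σ w_i n_i² + λ),    q = ν/Z,

so qZ = ν and Z² = σ². By the Cauchy–Schwarz inequality 0 ≤ q ≤ 1, with
q = 1 exactly when there is no leak and all capacity-carrying pathways share
one stoichiometry. Incomplete coupling thus arises either from specific
uncoupling (λ > 0) or from two gears operating at once — at high X the
high-stoichiometry pathway reverses into ATP hydrolysis, a futile cycle.

Z is computed as the *root* of the weighted second moment. The linear form
without the root fails two requirements that pin the mapping down: the
phenomenological totals must reproduce the mosaic totals at every X, and a
single fully coupled pathway of arbitrary stoichiometry n must have q = 1
(with Z = n). The mosaic⇔phenomenological equivalence property test (1e-12
relative tolerance over random systems) enforces this choice. Likewise the
flux ratio is evaluated as n(X) = Z(q − ZX)/(1 − qZX), the only form
algebraically equal to −Jp/Jc under the mapping.

## Gear optimisation

At fixed q and X the flux qZ − Z²X is a downward parabola in Z with vertex
Z* = q/(2X) and value q²/(4X) ("variomatic" continuous shifting). This is
the upper envelope of all fixed-Z lines.

With a discrete gear set (each gear a single fully coupled unit-capacity
pathway, normalized flux n(1 − nX)), consecutive gears n < m exchange
optimality at X = 1/(n+m). For this affine family every gear appears on the
upper envelope (the pairwise crossing points are ordered), so the optimal
schedule steps down through the gears as X grows; for gears {1,2,3,4} the
switch points are 1/7, 1/5, 1/3. **Ties break toward the lower gear**: the
higher gear reverses into hydrolysis sooner, so the lower gear is the safer
boundary convention. Schedules are capacity-invariant when all gears share
the same L.

For a dual-pathway mosaic family the total flux is affine in the capacity
split φ; the φ-coefficient vanishes at X* = 1/(n1+n2), where every split
gives flux n1·n2/(n1+n2). Above X* the flux ordering in φ inverts, so a
transducer free to retune capacities should jump from the high to the low
gear at X* in one step.

The parallel-vs-best-single crossover (sum of several fixed-Z fluxes versus
their pointwise maximum) is solved segment by segment on the exact
piecewise-affine upper envelope; grid sampling appears only as a test
oracle. A meeting point is accepted only where the best single pathway is
still synthesising: identical pathways meet the sum only at their common
stall point, which is reported as "no crossover" rather than a root.

## Numerical choices

- All roots use closed forms (the model is affine in X); bisection
  (scipy `brentq`) serves as an independent cross-check in tests, with
  1e-9 agreement required on X.
- n(X) and η at the singular point X = 1/ν are reported as an explicit
  undefined marker (`None` in the API, an empty cell in CSV), never ±inf,
  detected by |Jc| ≤ 1e-12·L·ΔGc.
- Force ratios X ≥ 0 are accepted beyond catabolic reversal; such rows are
  tagged with a `reverse_flag` (ATP hydrolysis driving reverse catabolism is
  rarely physiological but the algebra is well defined).
- Stoichiometries are real-valued; integer gears are a constraint imposed
  only by the discrete optimiser.
- Pathway weights must sum to 1 within 1e-12; the config validator reports
  the offending sum together with every other violation in one pass.

## Default parameterizations

The named presets fix the study conditions used throughout the examples and
tests: `fig1` — two gears, φ = 0.2, n = (1, 2), L = ΔGc = 1, λ = 0 (stall
at 0.75, catabolic reversal at 1/1.2 ≈ 0.83); `fig2` — three pathways at
equal coupling q = 0.9 with Z ∈ {0.5, 1, 2}, unit capacity each, their sum
and the variomatic envelope (parallel operation beats the best single
pathway below X = 9/17 ≈ 0.529); `fig3` — the dual-pathway family n = (1, 3)
at capacity splits φ ∈ {1, 0.375, 0.25, 0} (common intersection at
X = 0.25, flux 0.75); `fig4` — gears {1, 2, 3, 4} with the discrete
switching schedule. In `fig2` the summed curve adds three unit-capacity
systems, so its implied total capacity is 3 while each individual curve uses
capacity 1; the tables mirror that normalization deliberately. The default
sweep grid is X ∈ [0, 1] in steps of 0.01.

## Scope and limitations

The flux–force relations are linear and even proportional — an
approximation adequate for illustrating tendencies (how gear composition
shapes Z, q and the optimal switching structure), not for quantitative
prediction in any particular organism. Anabolic Gibbs energy (biomass
formation) is not modelled; the output is ATP synthesis flux. No estimation
of (Z, q) from measured flux data is provided (the forward map only), and
the dynamics of switching (regulation, expression kinetics) are outside the
model: schedules say which gear is optimal at each force ratio, not how a
cell gets there. Because the model is closed-form and deterministic, the
test suite exercises it over broad random parameter draws rather than
simulated noisy data; passing tests certify the algebra and its invariants,
not the linearity assumption itself.
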