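# Methods

## Model and sampling structure

Responses are normal with known standard deviation σ; arm means are
μ₀ (control) and μ₁, …, μ_K, with effects θᵢ = μᵢ − μ₀ and one-sided
hypotheses H₀,ᵢ: θᵢ ≤ 0.  Stage 1 assigns m₁ patients per arm
(including control); the stage-1 effect estimates are differences of
independent arm means, so their covariance is

    V = (σ²/m₁) (I + J),   V⁻¹ = (m₁/σ²) (I − J/(K+1)),

with J the all-ones matrix (variance 2σ²/m₁, correlation 1/2 through
the shared control).  The closed-form inverse is verified against a
generic numerical inverse for K = 2…8 in the test suite.  The simulator
draws the K + 1 arm means directly and differences them, which induces
V exactly rather than approximately.  Selection is the argmax of the
stage-1 estimates (ties, a probability-zero event, break to the lowest
index); the futility gate continues iff θ̂ᵢ\*⁽¹⁾ ≥ ℓ, with equality
counting as "continue".  Stage 2 contributes an independent estimate
with variance 2σ²/m₂ for the selected arm only.

Sample sizes m₁, m₂ are represented as positive reals: the
known-variance normal model makes fractional group sizes well defined,
and the efficiency (ρ) and matched-size (m̃₂) searches need continuity.
The allocation search restricts m₁ to integers and lets
m₂ = (N − (K+1)m₁)/2 stay real.

μ₀ is fixed at 0 without loss of generality: every statistic is a
function of mean *differences*, so a common shift of all arms cancels
identically in the simulator.  Scale invariance (multiplying σ and all
responses by a constant changes no decision) is covered by a test.

## Decision rules

All rules share the upstream selection and futility behaviour, so power
differences isolate the data-combination step.  Statistics map stopped
trials to −∞ (action A₀).

**Conventional.**  Z₂,ᵢ\* against the analytic critical
Φ⁻¹(1 − α/p_cont), where p_cont is the null continuation probability —
K/(K+1) when ℓ = 0 (the trial stops iff the control mean is the largest
of K + 1 iid means), and otherwise the one-dimensional integral
1 − ∫φ(u)Φ(u + ℓ√m₁/σ)^K du.

**TSE.**  w₁Z₁,ᵢ\* + w₂Z₂,ᵢ\* with wⱼ = √(mⱼ/(m₁+m₂)); equivalently a
positive multiple of the information-weighted pooled estimate
m₁θ̂ᵢ\*⁽¹⁾ + m₂θ̂ᵢ\*⁽²⁾.

**Closed testing with combination tests.**  H₀,ᵢ\* is rejected iff every
intersection hypothesis H₀,I with i\* ∈ I is rejected by a combination
test of the stage-wise p-values P₁,I and P₂,I.  Stage-2 p-values use
only Z₂,ᵢ\* (the only arm with stage-2 data), P₂,I = 1 − Φ(Z₂,ᵢ\*);
intersections not containing i\* cannot block the rejection of H₀,ᵢ\*
and are skipped.  Stage-1 intersection p-values are either Simes
(min over j of n·p₍ⱼ₎/j) or Dunnett for the equicorrelation-1/2
many-to-one structure, 1 − ∫φ(u)Φ(u + √2·t)ⁿ du with t the largest
statistic in I.  Two reductions make the 2^(K−1) intersections cheap:

* both combination functions decrease in the stage-1 p-value, so the
  closed test compares the combination at the *largest* intersection
  p-value with the critical value;
* the selected arm carries the maximal stage-1 statistic, so every
  Dunnett intersection containing i\* has the same t and the p-value
  grows with |I| — the full index set is always binding.  For Simes the
  2^(K−1) supersets are enumerated (sorted once per replicate).

Both reductions are validated against a brute-force oracle that
evaluates every intersection from scratch.  The inverse-χ² statistic is
exposed on the −ln(p₁p₂) scale — its unadjusted α-level reference is
half the upper-α χ²₄ quantile (5.5717 at α = 0.025) — and the inverse
normal on the z scale; "larger = more evidence" in both conventions.  A
zero p-value saturates the statistic at +∞.  Dunnett integrals use
140-node Gauss–Hermite quadrature (absolute error well below 1e-8,
checked against adaptive quadrature), chunked over replicates to bound
memory.

**Bayes-optimal rules.**  For a family of effect vectors (permutations
of (γ₁, …, γ_{K−1}, 1)·δ), a prior putting mass 1/(K+1) on θ = 0 and
1/(K+1) on each best-arm block, a reward c₂ for a correct rejection and
cost c₁ for a false one yields a Bayes rule that rejects when a
likelihood-ratio statistic exceeds a constant c.  Only the ratio c₁/c₂
matters, so rules are parameterized by c directly and c is calibrated
to null rejection rate α; the resulting rule maximizes the
block-averaged power among all rules with null error rate ≤ α.  Each
prior atom φ contributes the linear form λ(φ)ᵀθ̂⁽¹⁾ with
λ(φ) = V⁻¹φ = (m₁/σ²)(φ − 1·Σφⱼ/(K+1)), plus the stage-2 exponent
(m₂δ/(4σ²))(2θ̂ᵢ\*⁽²⁾ − δ) from the N(θ, 2σ²/m₂) likelihood ratio.

* *Single shape* (all off-best effects γδ): the block has one atom, the
  statistic is a single linear form, and dividing by δ makes it
  δ-free — one calibration serves every effect scale.  The off-selected
  coefficients are proportional to (2γ − 1)/(K + 1): negative below
  γ = 1/2, zero at γ = 1/2 (where the statistic reduces to the TSE
  pooled estimate — verified by an exact decision-equality test), and
  positive above.
* *Permutation*: the statistic is log Σ over the (K−1)! atoms with the
  peak at i\*, computed with a max-subtracted log-sum-exp (the exponents
  scale with m₁δ/σ² and overflow otherwise); c depends on δ, so each δ
  is calibrated separately (no uniformly most powerful rule exists).
  Families are enumerated explicitly for K ≤ 8.
* *Ordered* (dose–response prior): the top-dose block collapses to the
  single increasing vector θ_ord carrying the whole block mass, which
  enters the log-sum-exp as a log((K−1)!) offset; other blocks are
  unchanged.

The statistics are validated to 1e-10 against an oracle that evaluates
the multivariate-normal density ratios directly from V.  Strong FWER
control from null calibration requires every component of every λ(φ) to
be nonnegative; the minimum coefficient is proportional to
min_j φⱼ − Σφ/(K+1), positive for equally spaced γ's exactly when
γ₁ > K/(K+2).  Rules failing the check are labelled *pseudo-optimal*:
they bound attainable power but do not guarantee strong control.

## Calibration

Critical values are set so the FWER at θ = 0 equals α, futility gate
included.  The default method simulates one fixed null ensemble,
computes each replicate's threshold statistic once (for closed tests,
the minimum over intersections — so a single ensemble yields the whole
FWER-versus-critical curve), and places the critical midway between the
order statistics bracketing the α-quantile.  The procedure is
deterministic given the seed, and the in-sample rejection fraction is
⌊αR⌋/R by construction; tests revalidate on independent ensembles.  A
Robbins–Monro mode (cₙ₊₁ = cₙ + a/(n₀+n)·(I{reject} − α), warm-started
at a subsample quantile, gain scaled to the statistic's upper-tail
spread, n₀ = 1000 damping the early steps) is provided as an
alternative; its step schedule is a choice, and the quantile method is
the reproducibility-grade default.  Spot checks at effect vectors with
one, two and four positive components confirm the FWER stays at or
below α (with some conservatism) for the calibrated rules.

## Evaluation

**Power** is pr{select the truly best arm and reject its hypothesis};
vectors without a unique maximum are rejected.  Permutation scenarios
re-randomize the arrangement each replicate and judge success against
that replicate's own best arm (power averaged over the K!
arrangements).  The decomposition pr{select} × pr{reject | select} is
exact on a shared ensemble.

**Relative efficiency** of a rule against a benchmark is 100/ρ, where ρ
solves power(ρm₁, ρm₂) = benchmark power, with the rule recalibrated at
every scaled design.  The root search is Brent's method on a bracketed
interval; all evaluations reuse one standard-normal reservoir (common
random numbers), making the power curve effectively monotone and smooth
in ρ at desk-scale replication counts.

**Allocation.**  Under a fixed total N = (K+1)m₁ + 2m₂, a direct search
over integer m₁ recalibrates the rule and estimates power per grid
point with common random numbers.  The reported optimum is the argmax
of a moving-average smoothed curve: the true curve has a wide flat
maximum, so the smoothing window (21 grid points on a unit-step grid,
matched to the flat region's width) suppresses Monte-Carlo jitter in
the argmax without materially moving it.

**Phase-II value.**  With (m₁, m₂) maximizing the combined rule's power
under the budget, r\* answers "what are the stage-1 observations on the
selected arm and control worth, in stage-2 currency?"  The matched size
m̃₂ makes a conventional analysis (selection on m₁ stage-1 observations,
final test on stage-2 data alone) reach the combined rule's power; both
the 2m₁ stage-1 observations and the additional 2(m̃₂ − m₂) stage-2
observations count patients on two arms, so

    r* = 100 · (m̃₂ − m₂) / m₁ .

Because the conventional side uses an *analytic* critical, calibration
error in the combined rule's critical feeds straight into m̃₂; the
implementation therefore calibrates on a larger null ensemble
(default ≥ 2×10⁶) than it uses for the power match, and couples the two
power estimates on one reservoir.

## Random numbers and reproducibility

Randomness flows from integer seeds through `numpy` `SeedSequence`
children: separate streams feed the stage-1 arm means, the control, the
stage-2 estimate and the per-replicate permutations, so a single
standard-normal reservoir can be re-realized under any design, effect
vector or scale — the coupling used for rule comparisons, ρ and m̃₂
root-finding and the m₁ grid search.  Identical seeds give identical
batches bitwise.  Ensembles are column-oriented arrays over replicates;
generation is chunked beyond ~2×10⁶ replicates to bound peak memory.

## What the simulations do and do not show

The generator realizes exactly the model the design assumes: normal
responses, known σ, a common response distribution across stages, and
selection purely on the stage-1 estimate.  Real seamless trials deviate
from all four (estimated variances, stage-to-stage drift in populations
or endpoints, safety-informed selection); passing tests certify the
operating characteristics *under the stated model*, not robustness to
those departures.  Unequal allocation, unknown σ, binary or survival
endpoints, and multi-look monitoring are out of scope.

## Default problem sizes

Calibration defaults to 2×10⁵ replicates (FWER SE ≈ 3.5×10⁻⁴) with
10⁶ used for reported critical-value tables; power and efficiency
evaluations default to 1.5–2×10⁵ coupled replicates.  The acceptance
script runs the critical-value calibrations at 10⁶, the allocation
searches at 1.5×10⁵ per grid point, and the phase-II value match at
2×10⁶ power replicates with an 8×10⁶-replicate calibration, sizes at
which each quantity's Monte-Carlo error is small against the precision
at which it is reported.
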