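# Methods

This note records the modelling choices behind `caremcda`: what the
framework assumes, which knobs matter, what the packaged datasets do and do
not represent, and where the design was genuinely open.

## The evaluation model

The framework is an additive MCDA over five criteria. Each criterion score
is produced by a fixed rubric from structured evidence, scaled to [0, 2] so
criteria are commensurable, then combined as T = Σ w_c s_c with positive
weights normalised to mean 1. Benefit is set against net implementation
cost C through the ratio V = C / T (AUD per point); lower V is better value.
The additive form assumes criteria are preferentially independent — the
value of a capacity gain does not depend on the integration score — and the
common 0–2 scale assumes a point of workforce development is worth a point
of capacity improvement under equal weights. Both are simplifications the
weighting layer exists to probe.

### Rubrics

* **Capacity.** Only reductions in acute/emergency service use count; a
  statistically significant reduction (p < 0.05) scores 2, an observed but
  non-significant one scores 1. Evidence whose significance cannot be
  assessed is treated as non-significant (score 1 when a reduction is
  observed): the rubric credits the observation, not the missing test. A
  mixed shift — utilisation falling in one setting while rising in another
  without proof of net benefit — scores 0. A recorded p-value must be
  consistent with the significance flag; an inconsistent pair is a data
  error, rejected at validation.
* **Patient outcomes.** Satisfaction and quality of life contribute 0/1/2
  (none/observed/significant), access 0/1, and the 0–5 raw sum is rescaled
  by 2/5. Access is binary because perceived accessibility gains resist
  finer quantification.
* **Integration.** Two evaluators independently judge three domains
  (clinical, professional, organisational). A domain contributes 2 points
  only when both judge it fully integrated. Agreed partial integration, or
  one full and one partial judgement, contributes 1 — the scale must admit
  partial integration or observed intermediate states could not be
  represented. A full-versus-none disagreement is resolved conservatively
  to 0 and surfaced as a warning, since such a conflict signals an
  evidence problem rather than an intermediate state. Domain points are
  divided by 3 for the common scale, so scores are multiples of 1/3.
* **Workforce.** Upskilling and improved provider satisfaction each count
  1; gains achieved at the expense of increased workload or reduced
  satisfaction are not gains, so the worsened flag forces 0.
* **Risk.** Coded implementation facilitators F and barriers B classify the
  environment: supportive when F > 1.25 B, hostile when B > 1.25 F, else
  balanced (so (0, 0) is balanced). The "outweigh by more than 25 %" rule is
  read as a ratio test by default; a share-of-total variant
  ((F − B)/(F + B) > 0.25) is provided because the phrase admits both
  readings. Implementation success is high above 2/3 of objectives achieved,
  low below 1/3, with both boundaries falling to moderate (the thresholds
  are strict inequalities; fractions are compared exactly, not in floating
  point). A 3×3 matrix maps environment × success to a score; the default is
  additive, (environment level + success level)/2, which anchors
  (supportive, high) = 2 and (hostile, low) = 0 and keeps every other cell
  in {0.5, 1.0, 1.5}. Only the two corners are fixed by the scale's
  construction; the interior default is a reconstruction, and any matrix
  respecting the corners, the 0–2 range and the 0.5 step is accepted.

### Double-counting guard

One outcome measure may inform exactly one criterion per project (a
length-of-stay reduction is a capacity gain *or* a patient outcome, not
both; the most immediate effect wins). This is enforced structurally:
project records carry an optional map of named measures per criterion, and
a measure attached to two criteria fails validation at load time.

### Weights

Three sources: equal (all 1), direct numeric weights, or an ordinal
criteria ranking transformed to surrogate weights. The three standard
transforms are implemented — rank sum (n + 1 − r), rank reciprocal (1/r)
and rank-order centroid ((1/n) Σ_{j≥r} 1/j). Which transform the prior
decision-support framework this design descends from actually used is not
recoverable, so all three are available and rank-order centroid — the one
with a decision-theoretic optimality argument — is the default. Ties are
averaged into fractional ranks before the transform; the centroid formula
is extended to fractional ranks by linear interpolation on the integer
grid, which for a tie of adjacent ranks equals averaging the tied
positions' weights.

Weights are normalised to sum to the number of criteria (mean 1) rather
than to 1, so the equal scheme reproduces plain unweighted sums and totals
stay on the familiar 0–10 scale for five criteria. The four bundled
sensitivity lenses are: equal; a quantitative-evidence ordering (capacity,
outcomes, workforce, integration, risk); its reverse (the qualitative
lens); and a stakeholder-perception lens with capacity and outcomes joint
first (averaged rank 1.5), then risk, workforce, integration.

### League table, rounding, frontier

Net cost is budget spend − retained funds + in-kind value − non-capacity
savings; components are validated non-negative and held as integer cents so
league-table arithmetic carries no float drift. Negative net cost (a
cost-saving project) is legal, flagged, and eligible for the frontier.

Two totalling modes exist because integration scores are thirds: `exact`
(default) keeps full precision; `1dp` rounds each criterion score to one
decimal before summing, matching tables whose printed fractions were
rounded first. The two differ by at most 0.05 per criterion. Cost-per-point
under `1dp` therefore divides by the rounded-score sum — this is what a
reader recomputing a printed table obtains, and recomputation across the
packaged 17-row table confirms that mode reproduces its printed
cost-per-point column to the dollar, while `exact` does not.

Ranking is by ascending cost-per-point with competition ranking on ties
("1224") and stable secondary order by project id. The frontier uses weak
pairwise dominance only — no convex-hull/extended dominance — implemented
as an O(n log n) sort-and-sweep and cross-checked in the tests against an
independent O(n²) oracle; duplicate (T, C) points do not dominate each
other. A project with T = 0 has no defined cost-per-point and is excluded
from the table with a warning rather than ranked.

Rank-range sensitivity re-totals and re-ranks the portfolio under each
scheme and reports each project's (min, max) rank. The range machinery also
accepts externally supplied per-scheme rank vectors, since published rank
columns may come from weighting variants this package does not reproduce.

## Packaged datasets

`load_league_fixture()` is a 17-project portfolio league table (scores as
printed at one decimal, equal-weight totals, net costs in AUD).
`load_evidence_fixture()` is a synthetic evidence-level reconstruction of
the same portfolio: per-criterion evidence chosen so that the rubrics
reproduce the league table's score columns exactly and the portfolio
aggregates match the evaluation's reported counts (six capacity-significant
projects; 9/14+3/8+1 full/partial integration tallies across the three
domains, 66 domain points in total; eleven projects with workforce
development; four projects at risk score 2 and one at 0). Within those
constraints the per-project composition — which instrument drove an outcome
score, the exact facilitator/barrier tallies — is one consistent assignment
among many, not original study data. Both files are frozen
(checksum-verified, fixture version 1.0) so golden tests are stable.

## The synthetic generator

`simulate_projects` draws one evidence record per criterion per project,
independently across criteria and projects, so every output is rubric-valid
by construction; all randomness flows through the config seed. Defaults are
set so portfolio summaries loosely resemble a small state-funded
integration portfolio: P(capacity significant) = 0.55 × 0.6 = 0.33,
P(workforce ≥ 1) ≈ 0.68, facilitators Poisson(8) vs barriers Poisson(6),
6–12 implementation objectives achieved with probability 0.6, and net cost
log-normal(μ = 13.5, σ = 0.8) — median ≈ $0.73 m, central mass roughly
$0.15 m–$3.5 m.

What the generator does **not** emulate: correlation between criteria
(effective projects likely both integrate and develop workforce),
evaluator disagreement (both evaluators report the same judgement),
measurement error in the tallies, and any cost–benefit correlation. Tests
passing on generated portfolios therefore demonstrate the pipeline's
structural correctness (closure, determinism, invariants), not calibration
to real portfolio structure. One boundary consequence of the rubric design:
a portfolio generated with every effect probability at zero scores 0 on
four criteria but 0.5 on risk, because empty tallies classify as a balanced
environment and zero achievement as low success, and the additive matrix
assigns that cell 0.5 — an all-zero score vector would require a hostile
environment, which absence of evidence does not imply.

## Numerical choices

* Success-fraction thresholds compared with exact rational arithmetic;
  environment thresholds with exact float arithmetic (1.25 B is exact for
  integer B).
* Currency as integer cents internally; display rounding to the dollar
  happens only at presentation.
* Score-support validation tolerates 1e-9 absolute error for thirds.
* Competition ranks from `scipy.stats.rankdata(method="min")`; tie
  averaging from `rankdata(method="average")`.
* Seeds: a single `numpy.random.default_rng(seed)` per generated portfolio;
  identical configs give identical portfolios byte-for-byte through JSON
  round-trips.

## Known limitations

The discrete rubrics do not distinguish small from large validated effects,
the number of patients reached, or equity of impact; a 3-week
length-of-stay reduction and an 8 % presentation-rate reduction can earn
the same score. Significance-based scoring inherits every pathology of
p-value dichotomisation. Integration and risk scores rest on qualitative
judgement and may not transfer across evaluator teams. Cost-per-point is
undefined for zero-benefit projects rather than infinite, a deliberate
refusal to rank them. The frontier uses simple dominance, so it is not the
convex-hull frontier of incremental cost-effectiveness analysis; ICERs
between adjacent frontier points are out of scope.
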