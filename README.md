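# caremcda

Multi-criteria decision analysis (MCDA) for portfolios of integrated-care
projects.

Health services that fund many heterogeneous care-integration projects — a
telehealth triage model here, a hepatitis C outreach service there — need a
way to compare them on one scale when a conventional cost-effectiveness
analysis is too narrow and long-term outcomes are not yet observable.
`caremcda` implements a mixed-methods MCDA that does this for a portfolio
evaluated over a short horizon: each project is scored on five criteria with
fixed evidence-to-score rubrics, the scores are weighted and summed into a
single benefit score, and net implementation cost per benefit point produces
a value-for-money league table, a cost-effectiveness frontier, and a
weight-sensitivity analysis.

## The model

For project *i* with criterion scores *s<sub>ic</sub>* ∈ [0, 2] and criteria
weights *w<sub>c</sub>* > 0 (normalised to mean 1):

- **Total benefit** T<sub>i</sub> = Σ<sub>c</sub> w<sub>c</sub> s<sub>ic</sub>
- **Cost per point** V<sub>i</sub> = C<sub>i</sub> / T<sub>i</sub>, where
  C<sub>i</sub> is net implementation cost (budget spend − retained funds +
  in-kind contributions at market rate − non-capacity cost savings), in AUD.
  Projects are ranked by ascending V<sub>i</sub>.
- **Frontier**: project *i* is dominated if some *j* has
  T<sub>j</sub> ≥ T<sub>i</sub> and C<sub>j</sub> ≤ C<sub>i</sub> with at
  least one strict inequality; the non-dominated set is the
  cost-effectiveness frontier on the (T, C) plane, with usual care at the
  origin.

The five criteria and their rubrics (each scaled to 0–2):

| criterion | evidence consumed | rubric |
|---|---|---|
| capacity | direction + significance of acute service-use change | significant reduction 2; non-significant (or unreported-significance) reduction 1; none/mixed 0 |
| patient outcomes | satisfaction, quality of life (none/observed/significant), access (binary) | raw 0–5 points × 2/5 |
| integration | two evaluators judge clinical, professional, organisational domains | 2 per agreed-full domain, 1 per partial, ÷ 3 |
| workforce | upskilling, provider satisfaction, workload flags | both 2, one 1, none or worsened 0 |
| risk | facilitator/barrier tallies, objectives achieved | 3×3 environment × success matrix, 0–2 in 0.5 steps |

Weights come from equal weighting, direct specification, or an ordinal
criteria ranking via surrogate-weight transforms (rank sum, rank
reciprocal, rank-order centroid; ties averaged), supporting sensitivity
analysis across stakeholder "lenses".

## Worked example

The package ships a 17-project portfolio as both a published-style league
table and an evidence-level reconstruction. Scoring the evidence and ranking
under equal weights with printed-precision (1 dp) totalling:

```bash
python -c "
import caremcda as cm
cm.write_projects(cm.load_evidence_fixture(), 'projects.json')
open('run.yaml', 'w').write('rounding: \"1dp\"\n')"
caremcda rank -i projects.json -c run.yaml -o out
```

```text
project_id  total   net_cost cost_per_point  rank  on_frontier
         4    3.7   $210,950        $57,014     1         True
         5    2.7   $238,476        $88,324     2        False
        15    8.7   $784,865        $90,214     3         True
        14    4.8   $471,029        $98,131     4         True
        11    7.2   $913,336       $126,852     5        False
        17    6.0   $821,383       $136,897     6        False
...
```

Project 4 delivers a benefit point for $57,014 — the best value in the
portfolio — while the most expensive point costs $1.4 m. The frontier
command reports the projects no rival beats on both score and cost:

```bash
caremcda frontier -i projects.json -c run.yaml -o out
# frontier projects: 10, 4, 14, 15
```

and `caremcda sensitivity` re-ranks the portfolio under the four bundled
weighting lenses (equal, quantitative, qualitative, stakeholder perception),
reporting each project's min–max rank range:

```text
            equal  quantitative  qualitative  stakeholder_perception  rank_min  rank_max
project_id
1              17            17           17                      17        17        17
10              9            14            7                      16         7        16
11              5             5            5                       5         5         5
...
```

Projects strong (or weak) on every criterion hold their rank under any
weighting (projects 1 and 11); projects concentrated in one criterion swing
widely (project 10). `caremcda score` writes the per-criterion scores and
`caremcda simulate` generates seeded, rubric-valid synthetic portfolios for
testing at any scale. The same operations are available as library functions
(`score_projects`, `build_league_table`, `sensitivity_ranks`, ...).

## Layout

- `src/caremcda/rubric.py` — evidence records and the five scoring rubrics
- `src/caremcda/weighting.py` — equal/direct/rank-based weight schemes
- `src/caremcda/league.py` — net costs, totals, league table, frontier, sensitivity
- `src/caremcda/projects.py` — project records, JSON/CSV I/O, run config
- `src/caremcda/simulate.py` — seeded synthetic portfolio generator
- `src/caremcda/datasets.py` — packaged worked-example fixtures
- `src/caremcda/cli.py` — the `caremcda` command-line interface
- `docs/methods.md` — modelling assumptions, parameters and limitations
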