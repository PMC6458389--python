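# Methods

## Model

A city is `M` well-mixed neighbourhoods ("cells") with no spatial
structure: every cell is one hop from every other. The initial population
is `n_residents` residents, `p = n_residents/M` per cell (construction
fails if not divisible). Residents are permanent; migrants enter over time
and remain migrants. Agents carry a single tolerance: a resident accepts a
cell while its migrant fraction is at most `τ_res`, a migrant while the
resident fraction is at most `τ_mig`. Equality is tolerated — the
tolerance is the *maximum* acceptable fraction — so a breach is strict
exceedance. Fractions are computed over all agents in the cell including
the evaluating agent; for a prospective move the agent counts itself in
the destination. An empty cell has both fractions defined as 0 and is
therefore always acceptable.

Each iteration runs sequentially, with every state change visible to the
next action:

1. **Entry phase.** `Mig(t) = g·P(t−1)`, rounded half-up, migrants attempt
   entry; zero attempts once `P(t−1) ≥ max_pop_factor·P(0)`. Each attempt
   independently draws a target cell uniformly, succeeds with probability
   `exp(−β_in · resident fraction)`, and is discarded on failure (no retry
   or queue). Admissions are immediate, so later attempts see the updated
   composition.
2. **Movement phase.** `P(t)` draws of agents uniformly at random *with
   replacement* — every agent has one opportunity per iteration on
   average. A satisfied agent does nothing. A breached agent draws one
   candidate cell uniformly among the other `M−1` and moves iff satisfied
   there; otherwise it stays. A breached resident is stamped with the
   current iteration as its first-breach time (once, monotone).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `M` | 20 | neighbourhoods |
| `n_residents` | 1000 | initial population (50 per cell) |
| `tau_res` | 0.25 | resident tolerance for migrant fraction |
| `tau_mig` | 0.75 | migrant tolerance for resident fraction |
| `g` | 0.005–0.05 | entry attempts per iteration as a fraction of `P(t−1)` |
| `beta_in` | 1.0 | entry friction in `exp(−β_in·f_res)` |
| `max_pop_factor` | 1.5 | population cap as a multiple of `P(0)` |
| `n_iterations` | 200 | run length |

With these values `τ_res` and `τ_mig` are complementary: a cell whose
migrant fraction exceeds 0.25 simultaneously breaches its residents and
becomes attractive to migrants, which is what turns the first crossing
into a cascade (residents flee, migrants pile in, the cell tips).

## Observables

- `B_c(t)`: residents currently breached / all residents, censused at
  iteration end.
- `B_f(t)`: residents ever flagged / all residents; monotone by
  construction.
- `T_τ`: mean first-breach iteration over flagged residents at run end;
  undefined (an error, not 0) when nobody was breached.
- `CSI`: mean over non-empty cells of `|f_r − f_m|/(f_r + f_m)` where
  `f_r` (`f_m`) is the cell's share of the city-wide resident (migrant)
  total. Before any migrant exists `f_m := 0` for every cell, so CSI is 1
  from `t = 0`; it dips as entry mixes the city and rises back toward 1 as
  breached residents re-sort.
- Curve helpers: per-iteration growth rates with a pre-cap window mean
  (the window ends at the last iteration with nonzero admissions), the
  first iteration at which the ensemble-mean `B_f` reaches each whole
  percent, and the population increase at each such crossing. Percent
  curves are computed on ensemble means (single smooth curve per `g`);
  per-run curves are available by passing a single trajectory.
- The *ensemble first-breach time* is the first iteration at which the
  ensemble-mean `B_f(t)` lifts off zero — equivalently the earliest breach
  across the ensemble's runs, which is what one reads off a mean-curve
  plot. The per-run average first-breach time is a different, much larger
  number (~84 vs ~58 iterations at `g = 0.005`) and is exposed separately.

## Design choices where the design was open

- **Breach detection is agent-centric by default.** A resident's first
  breach is recorded when the resident is drawn in the movement phase and
  evaluates its cell. The alternative — an end-of-iteration census that
  stamps every resident of a breached cell at once — is available as
  `breach_census=True`. Census stamping dates a whole ~50-resident cell at
  its tipping iteration, which systematically advances `T_τ` and the
  `B_f` percent-crossings by roughly the mean sampling lag; agent-centric
  detection matches the reference statistics better and follows the
  model's own movement rule (an agent discovers a breach when it acts).
  Under the default, `B_c(t) ≤ B_f(t)` can be transiently violated because
  current-breach censuses see a tipped cell before all its residents have
  been drawn; `breach_census=True` restores the inequality.
- **Movement draws are with replacement** (`P(t)` of them), the literal
  reading of "on average, every agent has the opportunity to move". A
  permutation variant (`move_without_replacement=True`) is provided; it
  clears breached cells slightly faster.
- **Candidate cells exclude the current cell**, uniform over the other
  `M−1`.
- **`Mig(t)` rounds half-up**, keeping `g·P(0)` exact for the reference
  values.
- **Seeding.** One `random.Random(seed)` stream per run; ensembles use
  seeds `base_seed + k`. Same params ⇒ bit-identical trajectories.

## Analytical companion model

Deterministic continuum approximation: cells are *sequenced* `C_1..C_M`,
each receives exactly `x` migrant mass per iteration (no entry
probability), and migrants never move. Residents of a cell are breached
when its migrant mass reaches `τ_r` times its resident mass (equality
triggers, unlike the stochastic model's strict exceedance — a documented
asymmetry); the cell's residents are then redistributed equally over the
cells after it in sequence. With `j = τ_r N/M`:

- `I_1 = j`; `I_u = Mj/((M−u+1)(M−u+2))` for `u ≥ 2`. The general formula
  does not reduce to `j` at `u = 1`, so the first step is special-cased.
- cumulative migrants per cell at breach `u`: `jM/(M−u+1)` (telescoping sum
  of the `I_q`, exact),
- `T_u = jM/((M−u+1)·x)`, `B_u = u/M`, `⟨T⟩ = (Σ T_s)/S` paired with
  `B = S/M`.

All quantities stay real-valued (the reference `τ_r = 0.33`, `N = 5000`,
`M = 20` make `j = 82.5` non-integer by construction). The cascade stops
at `u = M−1`: the last cell has no destination cells, so `B` caps at
`(M−1)/M`. The per-cell population increase at breach `u`,
`M·cumulative/N`, is independent of `x` — the analytical model lacks the
entry friction that makes the stochastic relationship `g`-dependent, and
that absence is precisely why it misses the stochastic model's
nonlinearity. A discrete-event oracle (`discrete_oracle`) simulates the
rules step by step with integer time; its breach iterations sit within one
iteration above the continuous closed forms, and its trigger thresholds
reproduce the cumulative closed form even when `x` is large enough to
breach several cells in one sweep.

## What the simulations establish — and what they do not

There is no external data: every experiment is self-generated from the
parameter table above, and the reference statistics are 30-run ensemble
means. A green suite establishes that this implementation reproduces the
published ensemble statistics of the same stated model at desk scale, and
that the closed forms agree with their own discrete oracle. It does not
establish anything about real cities: the model has no geography, no agent
heterogeneity, no wealth, no migrant-to-resident conversion, and its
tolerance parameters are stylised survey-motivated constants.

Ensemble statistics carry sampling error: per-run final `B_f` at
`g = 0.005` is a small integer multiple of one cell (most runs tip exactly
one of 20 cells), so its ensemble mean moves in steps of ~0.17%. Minimum
statistics (the ensemble first-breach time) are noisier still; the
acceptance suite compares them within max(15% relative, 2 bootstrap
standard errors of the statistic). The mean time-to-breach at
intermediate rates sits ~8–12% below the published values across seeds —
the first-tip-time distribution evidently has a slightly lighter right
tail than the original implementation's; the discrepancy is reported, not
absorbed into tolerances.

## Numerical notes

- Tolerance comparisons use exact float arithmetic on counts
  (`mig > τ·total`); the reference tolerances 0.25 and 0.75 are exact
  binary fractions, so boundary cells (e.g. 17 migrants among 68 agents)
  are classified exactly.
- The movement phase short-circuits when no agent anywhere is breached
  (the draws would all be no-ops); this changes the consumed random
  stream, not the dynamics.
- Residents are stored as per-agent cell/first-breach arrays; migrants
  only as per-cell counts (they carry no individual state). A full 200
  iteration run of ≤1500 agents takes ~0.1 s; the 8-scenario × 30-run
  reference set runs in ~25 s on one CPU.
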