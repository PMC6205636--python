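# Methods

This note documents the model implemented by `copcost`, the conventions
chosen where the published methodology leaves the design open, and what
the synthetic-data tests do and do not demonstrate about real ledgers.

## Model and assumptions

The estimator works by elimination on planned-funding ledgers. For each
cost cell (partner *i*, agency *j*, year *t*) it removes, in order:
sub-awarded funding (estimated via retention rates), then costs on which
indirect rates cannot be charged (capital, vehicles, a lab-equipment share
of HLAB funding, ARV procurement under HTXD). What remains — the
non-excludable cost, NEC — is the sum of the MTDC base and the indirect
costs charged on it, so a rate `r` fixes the split:
`Ind = NEC·r/(1+r)`.

Key assumptions inherited from the method:

- Planned funding approximates disbursed funding at the cell level.
- Retention behavior estimated in the sub-award observation window is
  stable across the study period.
- The first $25,000 of each sub-award (rate-chargeable under MTDC rules)
  is *not* credited back; sub-award detail is too sparse to support it.
- Rental costs are not excluded anywhere (no data in COP-style ledgers).
- Negotiated cost bases narrower than full MTDC are assumed to yield
  roughly the same indirect totals via correspondingly higher rates.
- Overhead and G&A are treated as one combined indirect rate; fringe
  benefit rates are direct costs and out of scope.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `lab_fraction` | 0.40 | fraction | HLAB share excluded as equipment |
| `lab_budget_code` | HLAB | — | laboratory-infrastructure code |
| `arv_budget_code` | HTXD | — | ARV procurement code (fully excluded) |
| capital categories | construction, renovation, construction/renovation | — | cross-cutting capital exclusions |
| vehicle categories | motor vehicles: purchased | — | cross-cutting equipment exclusion |
| `backfill_level` | partner | — | first pooling level for imputing EC in unobserved years |
| sub-award threshold | $100,000 | USD | below this within-agency total, a sub-partner counts as local |
| scenario rates | A/B/C, 20/15/10% | fraction | university basis and IO rate rule per scenario |

Observed-year windows for capital and vehicle cross-cutting data default
to "whatever years the input table contains", matching the source-data
reality (capital from 2010, vehicles from 2013 in the real ledgers) without
hard-coding it; they can be pinned explicitly in the run config.

## Numerical conventions

- **Integer cents and exact rationals.** All money is integer cents; all
  rates (`fractions.Fraction`) are exact. Each product rate × amount is
  rounded half-even at the cent, and the second leg of every identity is
  derived by subtraction (`Sub = Total − Ret`, `MTDC = NEC − Ind`), so
  `Total = Sub + Ret`, `Ret = EC + NEC` and `NEC = MTDC + Ind` hold to the
  cent on every cell and aggregate, while `Ind = r·MTDC` holds to within
  the single cent-rounding. This is why the round-trip test can demand
  exact equality rather than a float tolerance.
- **Proportional splits** (NA allocation, over-exclusion squeeze) use the
  largest-remainder method, which conserves totals exactly and is
  deterministic for a fixed row order.
- **NA allocation stratum** is (country, year, budget code), escalating to
  (country, year), then (year); a pool no level can absorb stays NA and is
  reported. Splitting pro-rata over classified *rows* makes the allocated
  funding inherit class, agency and partner mix simultaneously, which
  downstream retention lookup requires.
- **Retention estimation uses pre-allocation funding**: sub-award
  observations describe actual mechanisms, so imputed NA amounts are kept
  out of the rate denominators; the estimated rates are then applied to
  post-allocation cells.
- **Fallback averages are funding-weighted.** With window-funding weights,
  the weighted mean of partner ratios equals the pooled ratio
  (Σ retained / Σ funding), which is how both the agency and global
  averages are computed. The IO-proportion adjustment is an agency-level
  quantity and is applied to partner-level rates too (a partner's own
  sub-award destination mix is not observable in this design).
- **University rate lookup** uses the NICRA period covering the year;
  otherwise the nearest period applies retrospectively/prospectively, ties
  toward the more recent period. The IO average over universities is
  unweighted by default (a funding-weighted variant exists); it may drift
  slightly year to year as rate periods roll over.
- **Degenerate inputs**: sub-awards exceeding funding clamp retention to
  zero; an exclusion component exceeding retained funding is clamped; if
  combined exclusions still exceed retained funding, the components are
  scaled down proportionally so the identities stay exact with NEC = 0.
  All three events are reported as data-quality signals, never silent.
- **Presentation rounding** is half-even to thousands of USD; shares are
  percent to two decimals. Internal aggregation is never rounded.

## Open design choices made here

- The exact stratum used for NA allocation and the weighting of the
  published agency averages are not recoverable from the published
  aggregates; the conventions above are declared choices, configurable
  where reasonable (`backfill_level`, explicit observed-year windows,
  weighted IO average).
- Partner-name canonicalization (case-fold, whitespace collapse, legal
  suffix stripping, `NA` sentinel for empty/unavailable) is a stated
  convention; the original cross-year reconciliation of hundreds of
  partner spellings is not reconstructable.
- Non-US universities without public rates can be rated as IOs via
  `io_override`, reflecting that their NICRAs are as opaque as IO rates.

## The synthetic generator

The generator emulates the *accounting structure* of COP-style ledgers:
partners with classes and agencies, budget-code mixes, sub-award flows
with agency-specific retention and IO-direction, capital/vehicle
cross-cutting records, NA funding by stratum, and the observation gaps of
the real data (sub-awards in the first three years only, capital
cross-cutting from year four, vehicles from year seven, about a third of
partner-agency pairs reporting sub-awards). Default magnitudes mirror the
published aggregate shape: exclusion fractions of 0.85% (capital), 0.53%
(vehicles), 4% HLAB / 14% HTXD budget shares, a 14% NA share, agency
retention parameters taken from the published agency table, and roughly
60% of funding in scope.

Cell totals are drawn in whole millions of dollars and all generating
rates are four-decimal fractions, so every forward quantity is an exact
integer and the *realized* rates (ratios of cents actually written) equal
the generating rates. Ground truth is completed with the same exact
arithmetic the estimator uses; per scenario it stores `r`, `MTDC` and
`Ind` per cell, plus a nominal-truth column using the configured true IO
rate. Non-reporting partners keep their own drawn retention rate in the
ground truth — the estimator can only impute the agency average for them,
which is precisely the bounded error the recovery report measures.

What passing tests show: the estimator inverts the generating process
exactly when fully observed (`SyntheticConfig.fully_observed()`: no masks,
full reporting, no NA funding), degrades gracefully and monotonically as
sub-award coverage narrows, and conserves every identity on arbitrary
inputs. What they do not show: robustness to real-world features the
generator omits — partner-name noise beyond the normalization rules,
retention drift over time, correlated budget-code/agency structure,
planned-vs-disbursed gaps, or the actual magnitudes of the real ledgers,
which require the external dataset.

## Problem sizes

Test and demonstration ledgers use 15–30 partners over 4–10 years
(roughly 200 cost cells, a few thousand ledger rows) — large enough to
exercise every fallback path and stratum level while keeping the whole
suite under a few seconds. The estimator itself is linear in ledger rows
and has been run comfortably at hundreds of thousands of rows.

## Known limitations

- Indirect costs incurred by sub-awardees of *local* primes are not
  modeled; neither are USG management costs.
- The expenditure-analysis comparison published alongside the original
  model is a manual validation exercise, not a pipeline stage here.
- Cost-sharing offsets and negotiated non-MTDC bases are not modeled.
- The published aggregate totals cannot be reproduced without the
  external COP dataset; the acceptance surface is the set of worked
  examples computable from published tables plus the synthetic
  round-trip and conservation suites.
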