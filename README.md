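# copcost

Indirect-cost recovery estimation for PEPFAR-style planned-funding ledgers.

Donor programs such as PEPFAR publish planned funding per implementing
partner, funding agency and year, but never split it into direct and
indirect costs. Organizations recover indirect costs (facilities,
administration) through a negotiated rate — a NICRA — charged on a
regulatory cost base, the *modified total direct cost* (MTDC), which
excludes sub-awards, capital expenditures, equipment and, for HIV programs,
ARV drug procurement. `copcost` estimates, by process of elimination, how
much of each award plausibly went to indirect costs, for international
organizations (IOs) and universities.

## The model

For partner *i*, funding agency *j*, year *t*:

```
Total_ijt = Sub_ijt + Ret_ijt          sub-awarded vs retained funding
Ret_ijt   = EC_ijt  + NEC_ijt          excluded vs non-excludable costs
NEC_ijt   = MTDC_ijt + Ind_ijt         the rate base plus indirect costs
Ind_ijt   = r_ijt × MTDC_ijt           the indirect-cost rate
          ⇒ Ind_ijt = NEC_ijt · r_ijt / (1 + r_ijt)
```

The pipeline stages:

1. **Classification** — partners are classed IO / university / local / USG
   from a classification table; unclassified ("NA") funding is allocated
   pro-rata within its (country, year, budget code) stratum; local and USG
   funding is then out of scope.
2. **Retention** — sub-award data exist only for an early window, so
   per-(partner, agency) retention rates `R = (funding − sub-awards) /
   funding` are estimated there and applied everywhere, adjusted to an
   *applied retention rate* `R + (1 − R)·p` for the agency-level share `p`
   of sub-award dollars flowing to other IOs or universities (who charge
   their own indirect rates). Funding-weighted agency and global averages
   back-fill partners without data.
3. **Exclusions** — construction/renovation cross-cutting amounts, purchased
   vehicles, 40% of laboratory-infrastructure (HLAB) funding and all ARV
   (HTXD) funding are excluded; years without cross-cutting data are
   back-filled with pooled proportional rates (partner-level, falling back
   to agency, then global).
4. **Scenarios** — the remaining NEC is inverted into indirect costs under
   six rate scenarios: universities keep their published on- or off-campus
   OSA rates; IOs get the average university rate (scenarios A, B, C) or a
   fixed assumed rate of 20/15/10% (10% being the *de minimis* rate).
5. **Reporting** — annual and cumulative tables in thousands of USD,
   scenario ranges, and shares of total funding.

Money is carried as integer cents and every rate as an exact rational, so
all four identities hold to the cent on any input. A synthetic-ledger
generator with known ground truth makes each stage testable end to end:
on a fully observed synthetic ledger the pipeline recovers the generating
indirect costs *exactly*, per cell, in all six scenarios.

## Worked example

Generate a synthetic ten-year ledger and run the model:

```
copcost synth --out demo_data --seed 42
copcost run --funding demo_data/funding.csv --subawards demo_data/subawards.csv \
    --crosscutting demo_data/crosscutting.csv --classes demo_data/partner_classes.csv \
    --rates demo_data/nicra_rates.csv --out demo_out
```

which prints the annual report (thousands of USD; excerpt):

```
measure_thousands_usd    2007    2008   ...    2016    Total
total_funding          423256  443023  ...  468605  4466279
sub_awards              45672   43789  ...   44770   436492
ec_arv                  59256   62023  ...   65605   625279
total_nec              306532  324864  ...  345171  3280042
ind_A                   80362   84918  ...   90637   861548
ind_ASSUMED_10          40809   41130  ...   44905   426444
```

Reading the output: of $4.47B in-scope IO/university funding, $0.44B is
estimated sub-awarded; after excluding capital, vehicles, lab equipment and
ARV drugs, $3.28B (73.4%) remains as NEC; inverting NEC through the
scenario rates brackets cumulative indirect costs between $426M (assumed
10% for IOs) and $862M (on-campus university averages) — a range of
$435M, or 9.7% of in-scope funding (`report_range.csv`). The bundle also
contains `report_shares.csv`, the estimated `retention_table.csv` with a
provenance flag per rate (partner-observed, agency average, or global
average) and an `audit_log.txt` of allocation and clamping events.

The same run is available as a library:

```python
from copcost import SyntheticConfig, generate, run_pipeline

ledger = generate(SyntheticConfig(seed=42))
result = run_pipeline(ledger.funding, ledger.subawards, ledger.crosscutting,
                      ledger.classes, ledger.rates)
print(result.report.to_thousands())
```

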