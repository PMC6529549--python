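# cultev

Risk-versus-reward decision analysis for microbial cultivation campaigns.

Dilution-to-extinction (DTE) culturomics dilutes a natural community into
microtiter plates at ~1 cell per well, hoping some wells grow into axenic
cultures. Whether such a campaign is "worth it" is usually argued
qualitatively. `cultev` makes the argument quantitative, for cultivation
labs and the people who fund them:

* **Cultivation probability (cP).** For each taxon, compare how often it was
  actually isolated with how often it should have occurred in the wells given
  its relative abundance: `cP = n_isolates / expected_occurrences`. Expected
  occurrences come from an occupancy model — nominal
  (`wells × abundance × cells_per_well`) or Poisson
  (`wells × (1 − e^(−λ·abundance))`). Wilson score intervals quantify the
  uncertainty.
* **Expected value.** A cultivation attempt at an isolate valued `i` with
  probability `cP` and experiment cost `e` has expectation
  `EV = i·cP − e·(1 − cP)`. A project recovering `x` isolates amortizes its
  cost: each isolate is charged `e/x`, and
  `EV_project = Σ i·cP − (e/x)·Σ(1 − cP)`. Break-even solvers invert these
  for the cost (`e* = i·cP/(1−cP)`, or `x·Σi·cP/Σ(1−cP)` project-wide) or the
  isolate value at which the expectation crosses zero.
* **Planning.** Expected isolate yield of a design, the well count needed to
  hit a target yield, the number of repeat experiments for a desired chance
  of at least one success (Poisson model), and per-isolate cost amortization.
* **Portfolio scenarios.** Enumerate isolate-count combinations across a grid
  of (value, cP) categories at fixed project cost and classify each
  combination's expectation sign against total isolates and the low:high
  value ratio.
* **Simulation.** A seeded stochastic simulator of DTE campaigns (exact-one
  or Poisson well loading, growth as Bernoulli trials per taxon, optional
  axenic-purity requirement) that validates the cP estimator by parameter
  recovery.

## Worked example

A SAR11 subclade IIIa strain valued at $500,000 was isolated 6 times out of
an estimated 410 occurrences in culture wells; a HIMB11-type *Roseobacter*
24 times out of 84:

```sh
$ cultev estimate-cp records.tsv
taxon_id    n_isolates  expected_occurrences  cp         cp_low      cp_high    clamped
SAR11_IIIa  6           410                   0.0146341  0.00672376  0.0315553  false
HIMB11      24          84                    0.285714   0.20015     0.39002    false
```

With cP = 1.46%, an experiment devoted to the IIIa strain alone should not
cost more than about $7,400 if the expectation is to stay positive:

```sh
$ cultev breakeven --value 500000 --cp 0.0146
quantity         value
breakeven_cost   7408.16
rounded_to_100   7400
```

But if the same experiment also brings in a HIMB11 isolate (valued at
$50,000 with its much higher cP of 28.2%), amortizing the cost over both
isolates keeps the expectation positive up to a $25,000 project:

```sh
$ cultev ev scenario.tsv --cost 25000
label       ev       kind
SAR11_IIIa  -5017.5  category
HIMB11      5125     category
TOTAL       107.5    positive

$ cultev breakeven --scenario scenario.tsv
quantity                   value
breakeven_project_cost     25126.2
largest_positive_thousand  25000
```

The per-category rows show the high-probability isolate subsidizing the
long-shot one: the IIIa isolate alone carries a negative expectation at this
cost, but the portfolio total is +$107.50.

The same arithmetic runs in reverse for feasibility: 500 wells inoculated at
1 cell per well from a community with the target at 20% abundance give 100
expected occupied wells, and at cP = 1.46% about 1.46 — effectively one —
expected isolate (`cultev plan`).

## Library layout

| Module                | Contents |
| --------------------- | -------- |
| `cultev.evmodel`      | EV arithmetic, break-even solvers, scenario types |
| `cultev.cpestimate`   | cP estimation, occupancy models, Wilson intervals |
| `cultev.planner`      | yield/scale planning, per-isolate cost, feasibility |
| `cultev.scenario_sim` | portfolio scenario enumeration and summaries |
| `cultev.dte_sim`      | stochastic campaign simulator, synthetic fixtures |
| `cultev.io` / `cli`   | TSV readers/writers, umbrella `cultev` command |

See `docs/methods.md` for model assumptions, parameter defaults, and known
limitations.
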