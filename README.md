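# treeconsensus

Consensus analysis of categorical clinical decision trees.

Participants (centers, experts, guideline panels) each contribute a
treatment algorithm expressed as a decision tree over shared categorical
criteria. `treeconsensus` validates and harmonizes those trees, expands
each one over **every scenario** (every combination of criteria levels),
tallies the recommendations per scenario across the ensemble — mode set,
congruency rate, strict (>50 %) majority — induces a compact consensus
tree from the per-scenario modes, and profiles which criteria actually
drive each participant's decisions and which treatments each participant
offers.

## Package layout

| module               | contents |
| -------------------- | -------- |
| `tree_model`         | `Criterion`, `CriteriaSet`, `Scenario`, `RecommendationSet`, `DecisionTree`, `DecisionTable`; `evaluate`, `scenario_space`, `depends_on` |
| `io_formats`         | versioned YAML tree/criteria/rule documents, CSV decision tables, DOT export; canonical, reject-don't-repair parsers |
| `validation`         | exhaustive structural reports: gaps, conflicts, overlaps, unknown levels, unreachable branches |
| `harmonization`      | cut-off / synonym rules onto shared criteria, criterion census, inclusion threshold with a mandatory exclusion log |
| `consensus_engine`   | `expand`, `vote_of` (any-/main-recommended policies), `consensus` (exact `Fraction` tallies), `induce_tree`, consensus CSV |
| `profiles`           | criteria-usage and treatment-portfolio boolean matrices |
| `synthetic`          | seeded ensemble generator around a known truth tree; packaged fixtures (six-center performance-status cut-offs; defective draft pancreatic-cancer tree) |
| `cli`                | the `treeconsensus` command |

Key semantics:

* **Mode ties are never broken** and exactly-half support is **no**
  majority (majority is strictly more than 50 % of the participants voting
  at that scenario).
* Multi-recommendation cells vote fractionally (1/|members| each) under
  the `any-recommended` policy so every participant weighs exactly 1; a
  full-vote-per-member weighting is available via `fractional=False` /
  `--full-votes`. The policy is always an explicit argument, never a
  silent default.
* Scenarios a participant marks not-applicable abstain and shrink that
  cell's congruency denominator.
* "Uses criterion c" in the usage profile means the expanded table
  actually changes with c, so vacuous splits do not count.
* Harmonization and marginalization pool recommendations by union —
  a preference never stated is never invented.

## CLI

```bash
# structural validation (exit code 1 if any tree is defective)
treeconsensus validate centre1.yaml centre2.yaml --csv issues.csv

# apply harmonization rules, drop criteria used by < k participants
treeconsensus harmonize tables/*.csv --rules rules.yaml -k 3 --out harmonized/

# per-scenario tallies + induced mode consensus tree (YAML + DOT)
treeconsensus consensus harmonized/*.csv --criteria criteria.yaml \
    --policy any-recommended --out consensus/

# criteria-usage and treatment-portfolio matrices
treeconsensus profiles harmonized/*.csv --out profiles/

# synthetic ensemble with known truth
treeconsensus simulate --spec spec.yaml --seed 7 --out sim/
```

Every output directory gets a `manifest.json` echoing the configuration,
inputs and participant finalisation dates.

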