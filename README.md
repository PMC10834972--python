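# crowdrank

Multimodal (ordinal + numerical) crowd-estimate aggregation for ordering
tasks. The package implements:

- **core_model** — domain types for tied rankings, numerical estimate
  ballots, participant records and crowd datasets; numerical→ordinal rank
  conversion (competition ties) and ranking projection.
- **distances** — the halved sign-sum discordance distance and the
  pairwise-intensity distance on complete inputs, their normalized
  projected extensions to incomplete inputs, the discordant-pair count,
  and the [0, 1] normalized ground-truth accuracy metric d*.
- **voting** — plurality, Borda and Copeland on incomplete tied ballots,
  plus multimodal aggregation (each participant contributes their ordering
  and the ranking induced from their counts) and mixed-group aggregation
  (ordinal ballots from one group, converted numerical ballots from a
  disjoint group).
- **coa** — the cardinal-and-ordinal consensus optimization: an exact
  enumeration oracle for small universes (permutations + inner linear
  program) and an anytime mixed-integer formulation (HiGHS via
  `scipy.optimize.milp`) with time limit and optimality-gap reporting.
- **synthetic_data** — seeded crowd simulator: 30-image universes with
  distinct dot counts, permutation-partition task allocation with balanced
  per-image view counts, log-normal perception noise, and joint vs
  independent elicitation conditions.
- **experiments** — per-participant self-consistency (Kendall tau-b,
  Spearman, Pearson), discordant-pair error histograms, group-size
  accuracy sweeps, coupled- vs separate-estimate-group comparison, and the
  1.5·IQR outlier filter.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (combinatorial
maxima, allocation bookkeeping, exact-oracle equivalence of the MIP solver
on 50 random instances, metric axioms, qualitative directional findings on
synthetic crowds, and seed determinism).

## CLI

```bash
crowdrank simulate --participants 300 --task-size 5 --condition independent --seed 7 --out data/
crowdrank aggregate --rule borda --modality both --in data/ --out consensus.csv
crowdrank coa --in data/ --time-limit 600 --mip --out solution.json
crowdrank dist --function npks --a x=1,y=2,z=3 --b x=3,y=2,z=1
crowdrank run --config config.json --seed 5 --out results/
```

Datasets are four UTF-8 CSVs: `ground_truth.csv` (image_id, task_size,
true_count), `ordinal.csv` (participant_id, image_id, rank_position),
`numerical.csv` (participant_id, image_id, estimate), `participants.csv`
(participant_id, interface_condition, task_size).

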