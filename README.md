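# mousebarn

Social-network and vocal-communication analysis for RFID-tracked house mouse
(*Mus musculus domesticus*) populations monitored with duty-cycled passive
acoustic recorders.

Free-living house mice in high-density habitats (barns, farms) use nest boxes
fitted with RFID antennas, so every entrance and exit of a tagged mouse is
logged. Placing autonomous recorders (AudioMoths, 55 s record / 5 s pause)
on those boxes adds a parallel stream of squeak and ultrasonic-vocalization
(USV) detections. `mousebarn` turns these two streams into the quantities a
behavioural ecologist asks of such data:

- **Box-use summaries** — per-mouse total box time, stay-duration
  distributions, favourite-box preference, diel activity profiles, weekly
  occupant turnover, seasonal assignment (spring = Mar–May, …, winter =
  Dec + Jan/Feb of the next year).
- **Seasonal social networks** — pairwise *meetings* (maximal co-occupancy
  intervals under half-open `[entry, exit)` semantics) aggregated into a
  **co-occupancy index**, a time-based Jaccard coefficient
  `COI(i,j) = T_ij / (T_i + T_j − T_ij)` where `T_ij` is the pair's total
  meeting time and `T_i`, `T_j` each mouse's total in-box time for the
  season. Networks are partitioned by Louvain modularity maximization
  (best-of-20 restarts), tested against degree-preserving weight-permuted
  nulls, and summarised by the small-world coefficient
  `σ = (C/C_rand)/(L/L_rand)`, per-node centrality, and the exponential
  decay `y = a·e^(−bx)` of box sharing with distance.
- **Vocal statistics** — AudioMoth→RFID clock correction (affine map
  through start/end chime anchors, assuming linear drift), per-"minute"
  (55 s segment) binning, permutation tests of squeak–USV co-production
  (exact hypergeometric permutation law), peri-event histograms of
  vocalizations around box entrances/exits with time-randomized nulls,
  negative-binomial GLM comparison of four hypotheses for vocal counts
  (season; +adults; +sex ratio; +pups) by AIC with the dispersion α
  profiled on a log grid, and per-pair Spearman correlations between
  meeting vocal counts and subsequent co-occupancy against shuffled
  controls.
- **A synthetic barn** — a generator with planted ground truth (social
  groups, diel rhythms, vocal-event kernels around box events, pup-driven
  rate increases, joint squeak+USV bouts, linear clock drift) so that every
  stage of the pipeline is testable by parameter recovery.

## Worked example

Simulate a small barn (30 mice, 9 boxes, four seasonal windows with one
recorder deployment each) and run the full pipeline:

```python
from mousebarn import pipeline

config = {
    "seed": 11,
    "simulate": {"config": {"n_mice": 30, "n_boxes": 9},
                 "days_per_season": 4, "recordings_per_season": 1,
                 "n_segments": 360, "boxes_per_deployment": 3},
    "analysis": {"n_rand_modularity": 20, "n_random_smallworld": 10,
                 "n_perm_cominute": 500, "n_shuffles": 20},
}
results = pipeline.run_pipeline(config, "demo", force=True)

import pandas as pd, json
net = pd.read_csv("demo/network_summary.csv")
print(net[["season", "n_nodes", "n_edges", "modularity",
           "modularity_z", "small_world_sigma"]].round(3).to_string(index=False))
with open("demo/glm_comparison.json") as fh:
    glm = json.load(fh)
print("best squeak model:", glm["squeak"]["best"])
print({k: round(v, 1) for k, v in glm["squeak"]["aic"].items()})
```

which prints

```
season  n_nodes  n_edges  modularity  modularity_z  small_world_sigma
spring       30      369       0.598        21.029              1.007
summer       30      352       0.564        15.764              1.003
autumn       30      369       0.560        26.386              1.003
winter       30      398       0.490        28.312              1.003
best squeak model: season+pups
{'season': 200.5, 'season+adults': 201.0, 'season+sexratio': 200.1, 'season+pups': 166.4}
```

Each seasonal network is far more modular than its degree-preserving nulls
(`modularity_z` ≈ 16–28 standard deviations above the null mean — the
planted social groups), sits slightly on the small-world side of matched
random graphs, and the negative-binomial model in which vocalization depends
on season *and* the number of pups in the recorded box wins the AIC
comparison by ~34 points, recovering the planted pup effect.

The same run is available from the shell:

```bash
mousebarn run-all --config config.yaml --out demo --seed 11
mousebarn report --out demo
```

`report` lists every results table and flags gaps in incomplete bundles.
Existing RFID/detection CSVs can be analysed with `mousebarn ingest`
(schemas: stays `mouse_id,sex,box_id,entry_iso8601,exit_iso8601`; detections
`recording_id,box_id,onset_s,offset_s,label`; anchors
`recording_id,clock,event,timestamp`).

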