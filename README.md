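# reeftrace

Analysis of passive acoustic telemetry for reef shark movement ecology:
detection pre-processing, residency and site-fidelity indices, linear
displacement, array-utilization and activity indices, and directed
movement-network analysis with permutation testing — plus an
agent-based detection simulator with known ground truth so every stage
can be validated without field data.

The package is built around the study design used for Caribbean reef
sharks (*Carcharhinus perezi*) in the Cayman Islands: a multi-year,
multi-island array of VR2W receivers (~300 m detection radius)
listening for surgically implanted coded tags (V9/V16, ~90 s random
transmission intervals), with receivers occasionally moved between
stations and offline for stretches of time. It is intended for
movement ecologists working with receiver-download CSV exports.

## The metrics

For each shark, a **detection day** is a local calendar day with at
least two detections anywhere on the array (single detections per day
are treated as likely false detections and removed).

- **Residency Index**: `RI = detection days / monitoring period`,
  where the monitoring period is the tag's expected battery life
  truncated at the study end. RI ∈ [0, 1], low to high residency.
- **Classification of Residency**: rule-based categories — *Passer-by*
  (never detected after the first 30-day block post tagging),
  *Transient* (re-detected after a > 30-day silence but < 3 detection
  months), *Pseudo-resident* (≥ 3 detection months, present < 30% of
  the detection period) and *Resident* (≥ 3 months, ≥ 30%).
- **Detection Index** per station:
  `DI = (station detections / total detections) × (station detection
  days / total detection days)`; the **Site-Fidelity Index** is
  `SFI = DI / ΣDI × 100`, and the rank-1 station is the shark's
  *primary site*.
- **Minimum linear displacement**: great-circle distance (haversine,
  R = 6371 km) between the two most distant detecting stations
  + 0.6 km (one 0.3 km detection radius per endpoint); single-station
  sharks use the distance from the tagging location + 0.3 km.
- **Utilization Index** per station:
  `UI = (sharks detected / total detected sharks) × (station days /
  total detection days)` with `station days = detection days / working
  days`; **Activity Index** per calendar month:
  `AI = (detection days / working days) × (sharks detected / total
  detected sharks)`. Both are ranking indices.
- **Movement networks**: successive detections of a shark at two
  distinct stations form a directed edge; edge weight counts
  transitions, node degree counts distinct in- plus out-neighbours.
  Subset networks (sex, maturity, summer/winter, day/night) are
  compared with a Mantel permutation test on the off-diagonal
  adjacency entries and a Mann-Whitney test on node-degree vectors.

The nonparametric toolkit (`reeftrace.stats`) wraps chi-squared
goodness of fit, tie-corrected Spearman, Mann-Whitney (rank-sum `W`
convention), Kruskal-Wallis, Dunn post-hoc comparisons and the Fisher
exact test (2×2 and 2×3 by full enumeration).

## Worked example

```python
import numpy as np
from reeftrace import load_cayman_summary, residency_index
from reeftrace.residency import DetectionMetrics

summary = load_cayman_summary()   # published per-shark study summary
metrics = [DetectionMetrics.from_summary_row(r) for _, r in summary.iterrows()]
ri = np.array([residency_index(m) for m in metrics])
print(f"mean RI = {ri.mean():.4f} (range {ri.min():.4f}-{ri.max():.4f})")
```

prints

```
mean RI = 0.0607 (range 0.0005-0.4810)
```

i.e. the 39 detected sharks were, on average, inside the array on about
6% of their monitored days; the most resident shark (tag 28955) was
detected on 595 of 1237 monitored days (RI 0.4810).

End-to-end on synthetic data:

```sh
reeftrace simulate --preset minimal --seed 7 --out scenario/
reeftrace report --detections scenario/detections.csv \
    --stations scenario/stations.csv --deployments scenario/deployments.csv \
    --sharks scenario/sharks.csv --config scenario/config.yml --out results/
```

The scripts in `examples/` walk through each capability (residency
metrics, site-fidelity ranking and displacement, seasonal networks,
the full pipeline) and print annotated output.

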