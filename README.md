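# granulefate

Quantitative analysis of pharmaceutical fate and microbial activity in
aerobic granular sludge (AGS) sequencing batch reactors (SBRs).

Wastewater engineers running paired control/test SBR exposure experiments
need three linked analyses: (1) how well the reactor removes dosed
pharmaceuticals and conventional analytes over time, (2) whether removal is
biodegradation (are transformation products appearing?) or just sorption,
and (3) which members of the microbial community are actually *active* while
this happens. `granulefate` implements all three as a tested, seeded
pipeline, together with a synthetic-data generator that emulates a
two-reactor, ~80-day exposure study (removal phase, desorption spike,
negligible-removal tail) with known ground truth — so every stage can be
validated without access to raw instrument or sequencing data.

## The core methods

**Quantification and mass balance.** Parent compounds are quantified from
peak areas via an OLS calibration curve, corrected for solid-phase-extraction
losses with spike recovery

```
recovery = (prespike − unspiked) / (postspike − unspiked)
corrected = measured / recovery
```

and expressed as percent removal by a per-timepoint mass balance,
`100 · (C_in − C_out) / C_in`. Negative removal is meaningful: an effluent
at twice the influent concentration (desorption of previously sorbed
compound) gives −100 %.

**Suspect screening.** Peaks are matched against a compound database (PCDL)
of parents and literature degradation products. A detection requires a mass
error strictly below 5 ppm against the theoretical [M+H]⁺ m/z (computed from
an embedded isotope-mass table) and S/N ≥ 10. Detections are tracked as
relative *corrected peak areas*:
`area · CF / area_std100` (aqueous, CF = concentration factor) and
`area / (area_std100 · dry_weight)` (solid, per g granules), where
`area_std100` is the parent's 100 μg/L standard in the same run.

**Active community.** For each sample, paired rRNA gene (DNA) and transcript
(cDNA) ZOTU libraries are rarefied without replacement over 100 trials; per
trial each ZOTU's ratio of rarefied cDNA to DNA relative abundance is
computed, with the *phantom rule*: transcripts present but gene reads absent
⇒ ratio set to 100. A ZOTU is **active** when its across-trial mean ratio
is ≥ 1. Active-community relative abundances, family aggregation, richness
and Shannon diversity use unrarefied DNA reads.

**Community response.** Changes between two timepoints are scored with the
bounded response ratio `rr = (b − a)/(b + a) ∈ [−1, 1]` (+1 appearance,
−1 disappearance, |rr| ≤ 0.5 neutral), restricted to active ZOTUs above
0.1 % relative abundance at either timepoint. Effluent concentrations are
related to community ordination coordinates by least-squares vector fitting
with a permutation p-value (the `envfit` construction; the ordination
itself is an input).

## Worked example

```python
import pandas as pd
from granulefate.pharma_quant import (SpikeRecoverySet, compute_recovery,
                                      correct_for_recovery, removal_percent)
from granulefate.synthetic_data import SimConfig, simulate_community
from granulefate.active_community import call_active, active_relative_abundance
from granulefate.community_response import response_table

rec = compute_recovery(SpikeRecoverySet(prespike_conc=140.0,
                                        unspiked_conc=45.0,
                                        postspike_conc=145.0))
print(f"recovery = {rec:.3f}")                      # recovery = 0.950
corr = correct_for_recovery(95.0, rec)
print(f"corrected effluent = {corr:.1f} ug/L")      # 100.0 ug/L
print(f"removal = {removal_percent(150.0, corr):.1f} %")   # 33.3 %

cfg = SimConfig(seed=1, n_zotus=30, depth_dna=5000, depth_cdna=5000,
                community_days=(5, 17))
sim = simulate_community(cfg)
calls = call_active(sim.dna["test"], sim.cdna["test"], n_trials=100, seed=1)
print(calls.groupby("sample_id")["active"].sum())
# test_d005    11
# test_d017    11
comp = active_relative_abundance(calls, sim.dna["test"])
resp = response_table(comp, "test_d005", "test_d017")
print(resp.head(3).to_string(index=False))
#  zotu_id  abundance_t1  abundance_t2  response_ratio category
# ZOTU0001      0.255212      0.113816       -0.383157  neutral
# ZOTU0002      0.060644      0.010347       -0.708501 negative
# ZOTU0003      0.073279      0.020085       -0.569743 negative
```

A measured effluent of 95 μg/L with 95 % recovery corresponds to a true
100 μg/L, i.e. one third of a 150 μg/L influent removed. In the simulated
test reactor, 11 of 30 ZOTUs are active at both days, and the dosed-reactor
drift built into the generator shows up as declining responders between
days 5 and 17.

The full pipeline runs from one YAML config:

```bash
granule-fate run --config config.yaml --seed 42 --outdir out/
```

writing removal time series, degradation-product time series, active-family
abundances, response classifications, and a `manifest.json` with SHA-256
hashes of every table (identical config ⇒ identical hashes).

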