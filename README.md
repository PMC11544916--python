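# netcover

Network-pharmacology selection of multi-target drug combinations for acute
myeloid leukemia (AML), built for computational biologists who want a tested,
reusable version of the repurposing workflow: from consensus differential
expression through protein–protein interaction (PPI) network reconstruction
and druggability partition to greedy minimal-drug / maximal-hub-coverage
selection, drug–drug interaction (DDI)-constrained combination enumeration,
and rule-of-five drug-likeness screening.

## The problem and the method

Single-target AML therapies fail in part because interaction networks rewire
around a perturbed node. The alternative is to hit many hubs of the disease
network at once with as few drugs as possible (few drugs = less polypharmacy
risk). Formally this is weighted maximum coverage: each drug *d* is a set
*T(d)* of network proteins, each protein *p* carries a score

    s(p) = α · deg(p)/deg_max + (1 − α),

and the selector greedily picks, at each step, the drug maximizing the summed
score of its not-yet-covered targets, stopping at zero marginal gain
(unlimited budget) or at a fixed budget *k*. Greedy maximum coverage carries
the classic (1 − 1/e) approximation guarantee at any fixed budget, which the
test suite checks against a brute-force oracle. Selected drugs are then
combined in pairs and triples; a combination is *safe* only if every member
pair is free of reportable DDIs (pairwise closure), and combinations are
ranked by hub coverage |∪ T(d)|.

Upstream, the disease network is built from genes called up-regulated by
*every* one of several differential-expression methods (strict intersection
at FDR *q*), restricted to protein-coding loci, joined against a
STRING-style confidence-scored PPI table at a 0.85 confidence threshold.
Downstream, a small cheminformatics module computes molecular weights from
formulas with an embedded atomic-weight table and applies Lipinski
rule-of-five and published toxicity cutoffs (maximum tolerated dose
0.477 log(mg/kg/day); fathead-minnow LC50 < 0.5 mM).

Because the original inputs (TCGA/GTEx expression, STRING, DrugBank) cannot
be bundled, `netcover.synthetic_data` generates statistically faithful
stand-ins (negative-binomial counts with planted fold changes, scale-free
PPI graphs, power-law drug–target maps, sparse symmetric DDI tables), and
packages the fully printed AML case study: 6 approved drugs, the 15 network
hubs they target, and the 7 interaction-free pairs.

## Worked example

Run the packaged AML case study end to end:

```bash
netcover run --fixture --outdir out/
```

or in Python:

```python
from netcover import pipeline as pl
report = pl.run(pl.PipelineConfig(mode="fixture", outdir="out"))
print(len(report.selected_drugs), report.covered_hubs,
      report.safe_pair_count, report.safe_triple_count)
# 6 15 7 2
```

The greedy selector picks all 6 drugs (procaine, amiodarone, vismodegib,
fostamatinib, artenimol, ponatinib) covering 15 hubs; 7 of the 15 drug
pairs are interaction-free, and pairwise closure admits exactly 2 safe
triples. The head of `out/combos_k2.tsv` ranks safe pairs by coverage:

```
combo                   safe  coverage  covered_set
artenimol+fostamatinib  1     7         FLNA,INSR,KIT,PLK1,PLK4,RPS8,WEE1
fostamatinib+procaine   1     7         DNMT1,DNMT3A,INSR,KIT,PLK1,PLK4,WEE1
fostamatinib+vismodegib 1     6         INSR,KIT,PLK1,PLK4,SMO,WEE1
amiodarone+artenimol    1     5         CACNB2,CACNB4,FLNA,PPARA,RPS8
```

so the best safe two-drug regimens each hit 7 of the 15 hubs. The
druggability report reproduces the partition arithmetic of the full AML
network (404 nodes, 102 druggable → 302 undruggable, 74.75%), and the
ligand screen gives the candidate molecule C15H15NO5 a weight of
289.29 g/mol with zero rule-of-five violations.

A full synthetic run (`netcover run --outdir out/ --seed 1`, or
`netcover simulate` for the raw tables) exercises every stage: three DE
stand-ins → consensus up-regulated genes → locus partition → 0.85-filtered
PPI network → druggability split → greedy selection → combination reports.

## Layout

| Module | Role |
| --- | --- |
| `synthetic_data` | input generators + the packaged AML case study |
| `deg_consensus` | DE stand-ins, strict consensus intersection, locus partition |
| `network_build` | confidence filtering, induction, degree/hub statistics |
| `druggability` | druggable/undruggable partition and report arithmetic |
| `greedy_selector` | greedy coverage selection + brute-force oracle |
| `combo_enumerator` | DDI-safe 2-/3-drug combination reports |
| `ligand_screen` | formula weights, rule of five, toxicity thresholds |
| `pipeline` / `cli` | orchestration, reporting, and the `netcover` command |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
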