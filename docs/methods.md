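# Methods

## The selection model

The core object is a bipartite drug–target structure over a disease PPI
network. Each drug *d* maps to a set *T(d)* of network proteins; each
protein *p* has a score `s(p) = α·h(p) + (1 − α)` where `h(p)` is degree
normalized by the maximum degree (so `h ∈ [0, 1]` and `s ∈ (0, 1]`). The
two extremes of α span the two natural readings of "cover the most highly
connected proteins with the fewest drugs": α = 1 weights proteins purely by
connectivity; α = 0 reduces to unweighted maximum coverage / greedy set
cover. The published description of the protein scoring is qualitative, so
this linear blend is our design choice — the simplest form containing both
regimes — with α = 1 as the library default and α = 0 used for the packaged
case study, whose hub set carries no degree information.

Greedy selection iterates: pick the drug with the largest summed score over
its not-yet-covered in-pool targets; stop at a budget, or when the best
marginal gain falls below `min_gain` (or to zero — the unlimited-budget
default, i.e., greedy weighted set cover). Ties break by (fewer total
targets, then lexicographic drug id), making the output independent of
input order. The hub pool defaults to all druggable nodes; the reported
"top-15 hubs" is treated as the *output* of the selection (the covered
set), not a pre-filter — a second interpretation (`hub_pool="top_q"`)
restricts credit to the top score quantile and is exposed but not the
default. A brute-force oracle enumerates all k-subsets (≤ 20 drugs) and
backs the (1 − 1/e) approximation-bound property test.

Combination safety uses pairwise closure: a 2- or 3-drug combination is
safe iff every unordered member pair has no reportable interaction. The
source material never states how 3-drug safety was judged; pairwise closure
reproduces both published safe triples exactly and is adopted as the rule.
One documented discrepancy: the prose gives artenimol + fostamatinib as
"4 hubs" in one sentence and 7 in the next, while the printed target sets
union to 7; the set-union arithmetic (7) is used throughout.

## Upstream stages

**Consensus differential expression.** A gene is a consensus DEG iff in
*every* method's table `p_adj ≤ q` and the signed log2 fold change matches
the requested direction with `|log2fc| ≥ lfc_min`. Defaults `q = 0.05`,
`lfc_min = 0` (the published analysis names the intersection rule but not
its thresholds). Three stand-in scorers make the stage testable without the
heavyweight DE packages: Welch's t on `log2(CPM + 0.5)`, Mann–Whitney with
normal approximation and continuity correction, and a two-sided permutation
test on the fold change. Fold change is `log2((mean tumor CPM + 0.5) /
(mean normal CPM + 0.5))`; the 0.5 pseudocount avoids log of zero and is
stated because it changes borderline signs. Multiple testing is
Benjamini–Hochberg per table.

**Network construction.** Edge confidences on the STRING 0–999 integer
scale are divided by 1000; the scale is auto-detected (any value > 1
implies the integer scale; fractional values mixed with values > 1 are an
error). The filter keeps edges with confidence ≥ threshold (keep at exactly
0.85 — the strictness is not stated in the source, ≥ is our choice). The
graph is induced on the upregulated protein-coding genes, isolated nodes
are dropped by default, and hub score is normalized degree. Node identity
is a case-sensitive string match; no alias resolution.

**Druggability.** A node is druggable iff some drug's target set contains
it. The undruggable percentage is rounded half-up to 2 decimals
(reproducing 302/404 = 74.75%); drugs whose targets all fall outside the
network do not count toward the unique-drug tally.

**Ligand screen.** Molecular weight is computed from a Hill-notation
formula against an embedded table of 2021 IUPAC conventional atomic weights
(≥ 4 significant figures per element) and rounded half-up to 2 decimals; no
parentheses, isotopes, or charges in this version. Rule-of-five verdicts
count violations over exactly four rules (MW ≤ 500, HBD ≤ 5, HBA ≤ 10,
LogP ≤ 5) and pass at ≤ 1 violation, Lipinski's original convention.
Toxicity interpretation is threshold arithmetic only: LC50 strictly below
0.5 mM is acutely toxic; a maximum tolerated dose ≤ 0.477 log(mg/kg/day)
flags low tolerance (0.477 is the documented toxic/tolerated boundary; the
comparison direction is our recorded reading of an ambiguous phrasing). The
underlying ADME/toxicity predictive models are deliberately not
reimplemented.

## What the synthetic generator emulates

Defaults mirror the study conditions: 151 tumor vs 456 normal samples,
20 000 genes with 7.5% planted up-regulated (≈ 1500 genes) at log2 fold
change 2, negative-binomial counts (`var = μ + 0.2 μ²`) with log-normal
baseline means (median ≈ 50 counts); a 1233-node preferential-attachment
PPI graph (m = 3, seeded from a path so the graph is connected and simple)
with Beta(8, 2) edge confidences, so a realistic minority of edges survives
the 0.85 filter; 607 drugs with truncated power-law target-set sizes
(exponent 2.5 — the per-node drug multiplicity is unpublished, so the
exponent is a free choice); DDI density 0.1 with uniform severity labels.
A single integer seed expands into fixed per-component substreams
(expression / graph / drugs / DDI / annotation), so components regenerate
independently and reruns are bit-identical.

Not emulated: library-size and GC biases, batch effects, correlated gene
expression, STRING's evidence channels, DrugBank record structure, and any
dose or pharmacokinetic aspect of interactions. Passing tests therefore
demonstrate the *pipeline logic* — intersection, filtering, coverage,
safety closure — under a faithful null model, not recovery of the original
genome-scale tallies (1506 consensus DEGs, the 404-node network, the
102/607 druggable mapping), which depend on the proprietary-scale inputs.

Tests and examples run at reduced sizes chosen to keep the suite fast while
preserving the planted structure: 1000 genes, 20 vs 20 samples, 500-node
graphs, 50 drugs, 200–300 permutations. The planted-ratio test bounds
[3.0, 5.3] around the expected 2² = 4 and the ≥ 0.8 recall floor on a
10-seed panel were fixed from seed-panel simulations under exactly these
conditions before being frozen into the suite (observed across panels:
ratio 3.65–4.42, recall ≥ 0.98).

## Numerical and degenerate-input choices

- Percent and weight rounding is decimal half-up, not banker's rounding.
- Duplicate PPI edges collapse to the maximum confidence; self-loops drop.
- An edgeless network gives every node hub score 0; component ids order by
  decreasing size with ties broken by smallest node id.
- Greedy and brute-force tie-breaks are identical, so the oracle and the
  heuristic are comparable instance by instance.
- Empty drug maps, empty combos, and absent DDI pairs are defined (warn +
  vacuous-safe) rather than fatal, since sparse real DDI tables are the norm.
- `report.json` excludes wall-clock timings (written separately to
  `timings.json`) so identical configs and seeds reproduce byte-identical
  reports.

## Limitations

- Degree is the only hub metric; no betweenness, modularity, or community
  detection, and no intra- vs inter-modular hub distinction.
- The DE stand-ins are not substitutes for edgeR/limma/DESeq2 on real
  RNA-seq; they exist to exercise the consensus logic.
- DDIs are taken as given, binary-per-pair; no interaction prediction,
  severity modeling, or dose dependence.
- The formula parser handles flat element-count formulas only; PSA, LogP
  and H-bond counts must be supplied, not computed from structure.
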