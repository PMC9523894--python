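# micropharm

Systems pharmacology of the gut microbiome: infer a **signed, directed
microbe–microbe interaction network** from metabolite
consumption/production profiles, propagate commensal/pathogenic labels
over it with a **Signed Random Walk with Restart (SRWR)**, survey the
**druggable space** of microbe proteomes from homology-search tables, and
**screen for drugs** that can hit pathogenic microbes while sparing
commensals — with hypergeometric overrepresentation of the resulting drug
categories.

## Who this is for

Computational microbiologists and drug-repurposing researchers who want a
tested, scriptable implementation of the metabolite-profile →
signed-network → label-propagation → selective-screen workflow, plus
synthetic-data generators that let every stage be exercised and validated
without access to external databases.

## The model

**Network.** For microbes *a*, *b* with consumption sets `C` and
production sets `P`, competition and cross-feeding extents are Jaccard
similarities

```
Negative_ab = |C_a ∩ C_b| / (|C_a| + |C_b| − |C_a ∩ C_b|)      (symmetric)
Positive_ab = |C_a ∩ P_b| / (|C_a| + |P_b| − |C_a ∩ P_b|)      (directional)
```

and the directed edge `u → v` (effect of *u* on *v*) carries the net
weight `Positive − Negative ∈ [−1, 1]`. Sign pairs of the two opposing
weights type each pair as competition (−,−), mutualism (+,+), commensalism
(+,0), parasitism (+,−) or amensalism (−,0).

**Label propagation.** A signed surfer starts at a seed node, restarts
with probability `c = 0.15`, and walks the semi-row-normalized network;
negative edges flip its sign, with balance attenuation `β = γ = 0.5`
governing enemy-of-enemy and friend-of-enemy behaviour. The stationary
positive/negative score vectors `(p, m)` are summed over known commensals
and pathogens to predict the seed's label; leave-one-out cross-validation
reports per-class precision/recall and macro F1. See
[docs/methods.md](docs/methods.md) for the update equations, conventions
and generator design.

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over the
library; all outputs land under `results/run/`):

```
python analysis/01_simulate.py          --seed 1
python analysis/02_build_network.py     --seed 1
python analysis/03_annotate_labels.py   --seed 1
python analysis/04_survey_druggability.py --seed 1
python analysis/05_screen_drugs.py      --seed 1
python analysis/06_enrichment.py        --seed 1
```

With seed 1 this prints, stage by stage:

```
network: 90 nodes, 7838 edges (3139 positive, 4697 negative)
largest strongly connected component: 90 nodes

annotated 66 unlabeled microbes: 32 predicted commensal, 34 predicted pathogenic
LOOCV on the observed labels: precision+/recall+ = 1.000/1.000,
  precision-/recall- = 1.000/1.000, macro F1 = 1.000
agreement with planted truth: 65/66 (98.5%) of unlabeled microbes

at the save threshold 1e-4, a mean 46.5% of each microbe's proteins have a
  homolog among known drug targets
at 1e-60 the mean druggable fraction is 18.8%

typed inh_not_inh recovered 30 drugs; planted answer has 30
untyped selective screen recovered 116 chemicals; planted answer has 116

40 categories tested; 1 significant at alpha 0.05
top category: CAT000 (k/K = 38/83, p_raw = 4.69e-33, Bonferroni = 1.88e-31)
planted category CAT000 tops the table
```

Reading it: the simulated 90-microbe community (6 guilds, 5% profile
noise, 30% of labels observed) yields a fully strongly-connected signed
network; the signed walk recovers the held-out curated labels perfectly
under LOOCV and agrees with the hidden planted truth for 65 of the 66
unannotated microbes; the typed inhibition screen returns exactly the 30
planted pathogen-selective drugs; and the planted drug category is the
single significant enrichment hit after any of the three corrections.

The same stages are available as a CLI (`micropharm simulate`,
`micropharm build-network`, …, `micropharm pipeline`) driven by a YAML
configuration; every stage writes a `manifest.json` with parameters and
input digests, and reruns under a fixed seed are bitwise identical.

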