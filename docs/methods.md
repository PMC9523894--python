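# Methods

## Interaction network from metabolite profiles

Each microbe *a* is reduced to two binary sets over a fixed metabolite
universe: its consumption profile `C_a` and its production profile `P_a`.
Two ecological mechanisms are scored per ordered pair:

* **Competition** (symmetric): `Negative_ab = |C_a ∩ C_b| / |C_a ∪ C_b|`,
  the Jaccard similarity of the consumption profiles. The more resources
  two microbes contest, the stronger their mutual negative effect.
* **Cross-feeding** (directional): the positive effect of *u* on *v* is
  `J(C_v, P_u)` — how much of what *v* eats is supplied by what *u* makes.

The directed edge `u → v` carries both extents and a single net weight.
The aggregation rule is the **difference** `positive − negative`, bounded
in [−1, 1]; the sign-interpretable difference is the simplest rule
consistent with treating the two mechanisms as opposing forces, and the
signed walk downstream needs exactly that semantics. An empty-vs-empty
Jaccard is defined as 0 (no shared resource, no interaction); self-edges
are excluded; pairs with both extents zero get no edge. Zero-weight edges
with nonzero extents (exactly cancelling forces) are kept in the graph but
carry no walk mass and count as "no effect" when typing relationships.

Relationship typing maps the unordered sign pair of the two opposing net
weights to competition (−,−), mutualism (+,+), commensalism (+,0),
parasitism (+,−), amensalism (−,0) or none (0,0). A configurable `epsilon`
(default 0) sets the magnitude at or below which a weight counts as zero;
the boundary value itself counts as zero, which only matters for
hand-picked epsilons.

## Signed Random Walk with Restart

Labels propagate by a signed surfer that starts positive at the seed with
unit score and restarts there with probability `c` per step. The signed
weight matrix is semi-row-normalized (each row divided by its absolute
sum); positive parts and negative magnitudes form the two transition
operators `T+`, `T−`. The sign dynamics follow balance theory with
attenuation: a positive surfer flips on a negative edge; a negative surfer
flips back on a negative edge with probability `beta` (enemy of my enemy)
and stays negative on a positive edge with probability `gamma` (friend of
my enemy). The stationary equations iterated to a fixed point are

```
p ← (1−c)·[T+ᵀp + β·T−ᵀm + (1−γ)·T+ᵀm] + c·q
m ← (1−c)·[T−ᵀp + γ·T+ᵀm + (1−β)·T−ᵀm]
```

with `q` the seed indicator. Mass arriving at a dangling node (zero
out-weight) restarts to the seed as positive mass, which preserves
`sum(p) + sum(m) = 1` at convergence — the conservation law the tests
assert. Walks run along edge direction (the direction of effect); a
`reverse` option transposes the matrix first.

Defaults: `beta = gamma = 0.5`; restart `c = 0.15` (the conventional
teleport value — any result should be read alongside it, since the method
itself does not pin it down); `tol = 1e−9` on the max-norm of the
concatenated `(p, m)` change; `max_iter = 1000`. With restart 0.15 the
iteration contracts at rate ≈ 0.85, so ~130 sweeps reach 1e−9;
non-convergence is reported via a flag, never an exception. Identical
inputs give bitwise-identical vectors (pure dense linear algebra, no
randomness).

Label prediction for a seed: `s_pos = Σ p` over known commensals plus
`Σ m` over known pathogens; `s_neg` is the mirror sum. The larger side
wins; exact ties fall to pathogenic by default (`tie_rule="to_negative"`),
the conservative choice for a screen that will target predicted pathogens.
Note one consequence of `beta = 0.5`: a pure two-negative-hop chain puts
exactly equal mass in both channels (half the returning negative mass
flips), so an isolated enemy-of-enemy with no other evidence is a tie, and
only `beta > 0.5` turns it into a positive call.

Leave-one-out cross-validation hides each labeled node in turn, seeds the
walk there, and votes against the remaining labels. Per-class precision,
recall and F1 feed an unweighted (macro) mean: the published-style figures
0.780/1.000 and 1.000/0.875 give per-class F1 0.8764 and 0.9333, mean
0.9049 ≈ 0.905, which is how the macro convention was fixed.

## Synthetic community generator

The generator plants exactly the structure the walk is meant to exploit,
so that recovery measures the method rather than the generator:

* Six guilds of 15 metabolically identical members; guilds 0–2 are
  commensal (+1), 3–5 pathogenic (−1).
* **Within a label class**, guilds form a directed trophic chain
  (0→1→2→0 and 3→4→5→3): each guild consumes the 12-metabolite waste
  block its feeder secretes and exports a waste block of its own, also
  re-secreting the imported block (partial recycling). This plants clean
  positive cross-feeding edges along the chain.
* **Across classes**, each commensal guild shares a 4-metabolite
  contested diet block with one pathogenic guild; contested metabolites
  are produced by nobody (diet-derived), which plants clean negative
  competition edges between opposite classes.
* Every membership bit of every member's consumption and production set
  flips independently with probability 0.05; per guild,
  `round(0.3 × 15) = 4` members keep an observed label (stratified
  masking, so both classes stay represented).

A structural caveat the pool sizes were chosen around: identical
within-guild consumption forces negative extent 1 inside a guild, while
the positive extent saturates at 1 only for a guild that exports nothing.
Any net exporter therefore carries moderate within-guild negative edges —
an artefact of the difference rule, not a planted signal. The chain
construction keeps that artefact (weight −(w+s)/(2w+s) with waste block
w = 12 and contested block s = 4) close in magnitude to the planted
cross-feed positives (+w/(2w+2s)), so first-order label votes are
dominated by the planted between-guild structure; the walk's second-order
balance dynamics (enemy-of-enemy mass returning as positive within a
guild) further absorb it. An isolated guild (no feeder) degenerates to a
closed self-recycling community with identical consumption and production
pools.

What the generator does **not** emulate: real metabolic network topology,
abundance or flux dynamics, environmental (pH) effects, predator–prey
interactions, strain-level label heterogeneity, and the long-tailed
degree distributions of curated metabolite data. Passing the planted
recovery test therefore shows the inference and propagation machinery is
correct under its own assumptions, not that real communities satisfy them.

The screening generator plants a set of drugs that inhibit only
pathogen-specific targets, plus decoys (mixed inhibitors, commensal-only
inhibitors, pathogen-only activators, non-drug chemicals); construction
guarantees the typed inhibition screen returns exactly the planted set and
the untyped selective screen returns the planted-plus-activator superset.
The annotation generator boosts one category's odds on study items
(default odds ratio 50 over a 5% base rate), recorded as ground truth.

## Druggability survey

Hits are standard BLAST tabular rows filtered at **strict** `e < t`
("lower than"); the save threshold is 1e−4 and the close-homolog threshold
1e−60. The sources that inspired these figures print them as "10e-4" and
"10e-60"; this package reads them as 1e−4 and 1e−60 (standard e-notation
intent — literally 10e−60 would be 1e−59). Counting is per **distinct
query protein**, never per hit, against an explicit per-microbe protein
inventory; the per-microbe mean fraction is the default statistic and an
all-proteins-pooled fraction is available, since summary percentages can
be read either way. The elbow of the fraction-vs-−log10(e-value) curve is
the interior point maximizing the discrete second difference, with
curvature ties (within 1e−12) resolved to the most permissive threshold;
it is advisory output and never gates a stage.

## Screens and enrichment

The untyped selective screen keeps drugs whose targets' microbe homolog
sets intersect the pathogenic set and miss the commensal set entirely
(strict exclusion: any commensal homolog disqualifies). The four typed
rules pair a required action on pathogens (activation or inhibition) with
a forbidden action on commensals; actions other than those two (e.g.
catalysis) never satisfy either side. Non-drug chemicals are dropped when
`drugs_only` is set; the filter commutes with screening. InChIKey
intersection normalizes to trimmed upper-case and validates the 14-10-1
block format; malformed or missing keys are dropped with logged counts.
Full-key matching is the default, first-block (connectivity) matching
being deliberately out of scope of the result sets reported here.

Overrepresentation uses the hypergeometric **upper tail** P[X ≥ k] (the
standard overrepresentation convention; the tail is computed through
`scipy.stats.hypergeom.sf(k−1, …)` and verified against exact rational
enumeration). ATC codes are expanded to all ancestor prefixes at lengths
1/3/4/5/7 so every hierarchy level is its own tested category, and the
correction family is the full set of tested categories in the run.
Bonferroni, Benjamini–Hochberg and Benjamini–Yekutieli adjustments come
from `statsmodels.stats.multitest`; items without annotations count in the
set sizes but in no category. The significance report keeps rows where
*any* adjusted p-value is below alpha, mirroring the usual
multi-correction reporting convention.

## Problem sizes and budgets

The default scenarios are deliberately desk-scale: 90 microbes over 84
metabolites (the curated datasets this emulates run to ~513 species and
233 metabolites), 200 chemicals, 1000 annotated items. These sizes keep
every stage dense-linear-algebra-friendly and the full test suite plus
acceptance run in well under a minute each, while preserving the
statistical structure (guild competition, trophic chains, planted
selectivity and enrichment) that the full-scale analyses rely on.

## Known limitations

* The difference aggregation rule is a declared choice; the underlying
  description of "summarizing" the two extents admits alternatives
  (ratio, clipped sum), which the `rule` hook accepts but none of which
  are tuned or tested here.
* Restart probability, tie handling and dangling-mass policy are
  conventions, documented above, not derivable from the method statement.
* The walk is dense (O(n²) memory); networks beyond ~10⁴ nodes would need
  a sparse reimplementation.
* LOOCV recomputes one walk per labeled node; the transition operators are
  shared but no further incremental speedup is attempted.
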