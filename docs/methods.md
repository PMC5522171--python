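# Methods notes

## Scope and model

herbnet implements a deterministic screening pipeline, not a fitted
statistical model: every stage is a filter, join or set computation over
six tabular resources, and the only probabilistic component is the
hypergeometric enrichment test. Results are therefore exactly reproducible
from the inputs; the package exposes per-stage functions rather than an
estimator object.

All joins run on one identifier namespace: trimmed, upper-cased gene
symbols. Conversion from other namespaces (Entrez, UniProt) is the
caller's responsibility. Compound identifiers are opaque join keys between
the chemical-link table and the herb ingredient table; the package never
interprets them chemically.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| hub degree threshold | 25 | minimum distinct PPI partners for a DEG product to count as a hub target (inclusive ≥); key proteins bypass it |
| chemical-link confidence | 0.9 | minimum STITCH-style score, unit scale, inclusive ≥ |
| SL disease confidence | 0.7 | disease-pair filter, **strict >** |
| enrichment alpha | 0.05 | BH-adjusted q-value cut for "involved" pathways |
| alternatives per prescription (k) | caller-set | number of greedy extension steps |
| category saturation cap | 3 | herbs per category before that category is deprioritized in decoction extension and alternative choice |

The deliberate asymmetry — inclusive ≥ for chemical links, strict > for
disease SL pairs — mirrors how the two cutoffs are conventionally quoted
for these resources. Off-target ("other SL") coverage applies **no**
confidence floor by default, treating any covered non-disease pair as
potential side-effect burden; a `min_conf` flag tightens this.

Duplicate-record policy (all inclusion-conservative at ≥ thresholds):
chemical links keep the maximum confidence per (compound, protein); SL
pairs keep the maximum confidence and the union of disease tags; the PPI
network collapses unordered duplicates and drops self-loops.

## Enrichment

One-sided upper-tail hypergeometric p-values (scipy), BH step-up
correction across all tested pathways (statsmodels). The background is
the set of genes appearing anywhere in the pathway database — the only
self-contained universe; query genes outside it are silently intersected
away, because herb target sets legitimately contain unannotated proteins.
A pathway with no background member is skipped. Rows sort by p ascending
with pathway-id tie-break, so output order is deterministic.

This replaces the DAVID web service used in the original analysis with a
plain, dependency-free test. Consequence: pathway counts obtained from
real data with DAVID (which uses a different background, statistic and
significance rule) are not expected to be reproduced; the test surface for
this module is fixture- and oracle-based.

## SL coverage semantics

A single ingredient hitting both genes of a pair counts as coverage — the
published evidence table forces this reading (adenosine triphosphate
witnesses both sides of several rows). Every covered pair carries one
canonical witness: the lexicographically smallest (ingredient_1,
ingredient_2) with targets aligned to the pair's sorted gene order;
`all_witnesses=True` returns the full witness list. For herb pairs the
default `require_cross=True` demands one ingredient from each member
(either orientation), because the pair — not either member alone — is what
is credited with inducing the joint perturbation; lifting the flag scores
the pooled ingredient set instead. Herb-pair enumeration is restricted by
default to pairs containing at least one hub CM, with a flag to lift the
restriction.

Ingredient→target links for SL analysis reuse the 0.9-filtered,
hub-restricted chemical link set. The alternative (all raw ingredient
annotations) is available by passing an unfiltered link list; the filtered
default keeps the SL stage consistent with the herb-scoring stage.

## Prescription assembly

The clinical heuristic behind "hub CM pair + alternatives" is qualitative;
this package operationalizes it as explicit, deterministic rules and flags
them as design choices:

- anchor pair: maximum safety ratio, ties by disease pairs covered, then
  lexicographic herb ids;
- alternatives: greedy over (category-preference tier, marginal gain in
  union DEG-target coverage, feature-tag match, Latin name) — tiers are
  tonic, hemorheologic, exterior-releasing, then everything else, with
  categories at the saturation cap demoted to a last-resort tier;
- decoction extension: a hub CM that pairs with a base herb, from an
  unsaturated category, ties by DEG-target count then Latin name;
- clinical-feature variants come from a rule table
  (feature tag → candidate herbs, order preserved), because no
  quantitative criterion exists for symptom-based selection; the rule
  table records, rather than resolves, that gap.

Given identical inputs the rendered prescription is byte-identical.

## Synthetic data

The generator emulates the statistical shape of the real resources: a
preferential-attachment PPI background (skewed degree distribution),
bipartite chemical links whose background scores (U(0.15, 0.89)) and
planted scores (U(0.90, 1.0)) straddle the 0.9 decision boundary,
multi-ingredient herbs with the eight-category label distribution
(21/123/98/64/28/21/45/18), and confidence/disease-tagged SL pairs.
Defaults reproduce the study composition: 596 DEGs (290 up / 306 down),
43 key proteins, 149 unmatched DEGs, 197 hub-degree DEG products (86 up /
111 down) covering 31 keys plus 12 sub-threshold keys, a flagship tonic
herb reaching exactly 83 DEG targets (37 up / 46 down), 2 high- and 3
low-confidence AML SL pairs, 5 covering herbs, and a pathway structure of
35 shared + 120 unique + 53 multi-group pathways (union 208, shared
proportion 16.8%). The PPI background is scaled to 1,200 partner proteins
and 210 background compounds — large enough for the degree and confidence
distributions to be non-trivial while the full pipeline runs in about a
second.

Planting is constructive where exact recovery is asserted: DEG–DEG edges
are never drawn, so each DEG's degree is exactly its planted partner
count; SL-pair genes receive high-confidence links only through dedicated
compounds held by designated herbs; pathway gene pools are private per
category and never touched by background noise. Within those reserved
structures recovery is exact by design — the corresponding tests assert
zero false negatives *and* zero false positives. What passing these tests
shows is that the pipeline logic is correct at its decision boundaries;
it does **not** show robustness to the ambiguities of real annotation data
(identifier drift, redundant compound names, overlapping pathway
memberships), which the generator deliberately does not emulate.

Published evidence tables are carried verbatim in `fixtures.py` and
guarded by frozen SHA-256 digests. Where the printed tables omit
machinery the pipeline needs (witness ingredients for two SL pairs, a
TP53-side witness for Angelica sinensis, the four blood-activating herbs
behind the decoction variants), the fixture supplies clearly documented
synthetic stand-ins.

## Known limitations

- Headline real-data counts from the original analysis (415 retained CMs,
  205 enriched pathways, 758 herb pairs, the 65/66/3/3 off-target counts)
  depend on specific releases of five external databases plus the DAVID
  service and are out of reach by construction; they are documented
  non-targets.
- The printed evidence table and the running text disagree on one SL
  confidence (ATM-TP53: 0.75 vs 0.56). Confidences are treated as data:
  the SL input fixture follows the text (required for the two-pair
  high-confidence filter result), the verbatim table encoding keeps its
  printed value.
- Degree is the only centrality implemented; no edge-confidence filtering
  is applied to the PPI (an optional column is accepted but off by
  default).
- The exclusion of unsafe/unconventional herbs is annotation-driven
  (flags in the herb table), not name-based: the original exclusion list
  is editorial and cannot be derived from data.
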