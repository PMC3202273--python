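# Methods

## The procedure

The engine joins two data layers per gene family and renders their product:

1. **Annotation cascade.** Input features arrive at one of five levels
   (probe set, gene, transcript, protein, mature microRNA) and are resolved
   to family members through per-organism mapping layers
   probe→transcript (many-to-many), transcript→protein (1:1 where present;
   non-protein-coding transcripts simply lack the protein hop) and
   transcript→gene (many-to-one). Mature microRNA identifiers are terminal
   members with no transcript hop. Ambiguity is *retained*: a probe mapping
   to k transcripts contributes its value to all k downstream members and is
   flagged, never dropped. Features that resolve to nothing are counted,
   never discarded silently.
2. **Family layer.** Families are either loaded verbatim from pre-clustered
   member→family tables (conserving the original identifiers) or derived
   from pairwise ortholog/paralog relation lists as connected components of
   the undirected relation graph, merging forward and reciprocal query
   directions. Families are disjoint by construction and validated as such;
   a member claimed by two families is a hard error.
3. **Expression layer.** Every dialect is re-calculated to log2-ratios.
   Redundant probes for one member are collapsed by the arithmetic mean of
   their log2-ratios; individual probe values are kept for the per-probe
   display column. Significance is a strict three-state call:
   up iff ratio > upper threshold, down iff ratio < lower threshold,
   otherwise not significant.
4. **Statistics.** Per family, per object, per direction, the one-sided
   upper-tail hypergeometric probability P(X ≥ k) with population N = all
   units at the chosen counting level (all genes by default, *including*
   units not assigned to any family), K = units called in that direction
   genome-wide, n = family units present in the data, k = the family's
   called units. Exactly four p-values per family. Values are collapsed per
   counting unit (e.g. all probes of a gene averaged) before counting.
5. **Output.** Matrices are assembled only from members that carry
   expression values; axes are sorted by gene, then member identifier.
   Cells carry the pairwise e-value, its colour bin, and the selection flag
   from the co-direction mode. Pages hold 50 families each; three
   tab-delimited tables export all pairs, significant pairs, or selected
   pairs; a loss report closes every run.

## Assumptions

* Input expression is already normalized and summarized to one value per
  feature and condition; the engine neither normalizes nor combines
  replicates, and it never validates data quality (e.g. absent calls).
* Identifiers arrive in one namespace per organism. Conversion between
  namespaces (e.g. UniProt→Ensembl) is a data-preparation step, supported by
  the standalone identifier map that drops and counts conflicting
  translations rather than guessing.
* Sequence similarity (BLAST e-values) is consumed, not computed; families
  cannot be re-computed from sequences by this package.
* Transcripts and proteins correlate 1:1; a violation is treated as a
  corrupt annotation file.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ThresholdSpec.upper_ratio` / `lower_ratio` | 4/3, 3/4 | strict fold-change bounds for the three-state call (ratio scale; ≈ ±0.415 log2 units) |
| `CoDirectionSpec.mode` | `none` | pair pre-selection: `co_up`, `co_down`, `co_both`, `anti`, or no restriction |
| `FamilyFilterSpec.mode` | `none` | singleton exclusion granularity: `multi_gene` (≥2 distinct genes for ≥1 organism) or `multi_protein` (≥2 members, i.e. splicing isoforms count) |
| `RunConfig.ora_level` | `gene` | counting unit of the ORA background (probe set, gene, transcript, protein, mirna) |
| `RunConfig.batch_size` | 50 | families per HTML page |
| e-value colour bins | bounds 1e-100, 1e-30, 1e-10, 1e-5, 1e-2, ∞ | decade bins; the top (≤1e-100) bin is violet, marking the most similar pair; fully user-overridable |

The e-value bin bounds are a package default, not a published constant: the
original display's bounds are not recoverable, so a documented decade scale
stands in and can be replaced wholesale via `ColourScale`.

## Numerical choices

* **log2 quantization.** `to_log2` rounds to 9 decimal places. The four
  dialects of the same data agree only to floating-point rounding
  (~1e-15) after text parsing; quantizing to a 1e-9 grid makes all dialects
  produce identical downstream values and byte-identical tables, while
  1e-9 is far below any biologically meaningful expression difference.
* **Threshold guard band.** Calls compare on the log2 scale with a 1e-9
  buffer, so a ratio of exactly 4/3 or 3/4 is never significant regardless
  of rounding direction — the strict inequality is honoured.
* **Exact tails.** The hypergeometric tail is computed with exact integer
  combinatorics (`math.comb`), summed and divided once; no normal
  approximation. At desk scale (family draws of tens against populations of
  thousands) this is exact to the last bit and still instantaneous.
* **Determinism.** Derived family IDs are prefix + zero-padded sequence
  number, assigned in lexicographic order of each component's smallest
  member; matrix axes sort by (gene, member); tables and reports iterate in
  sorted order. Identical inputs in any row order give byte-identical
  outputs.
* **Round-trip.** Floats in tables are written with `repr`, so re-parsing
  recovers the exact doubles used in rendering; missing e-values are `NA`
  and render in a neutral colour.
* **Degenerate inputs.** Nonpositive values where a ratio is required are
  routed to the loss report, not raised. A family with no expressed member
  is skipped entirely; a member without expression loses its row/column. A
  family with no units in the data gets p = 1 in all four directions.

## Design choices where the design was open

* **Averaging scale.** Redundant probes are averaged as the mean of
  log2-ratios, not the log2 of mean ratios — values are re-calculated to
  log2 before any aggregation, and the symmetric scale avoids biasing the
  summary toward high ratios.
* **Singleton handling.** Paralog subsets retain size-1 families but flag
  them; the exclude-singletons switch controls visibility, so the loader
  never destroys information.
* **`none` co-direction mode** applies no restriction (every pair selected),
  mirroring an unfiltered display.
* **Population background** counts all units in the annotation universe plus
  any observed unit, whether or not a family claims it; enrichment is
  measured against the genome, not against the familied subset.
* **Conflicting relation directions** (forward vs reciprocal) are unioned;
  the direction tag records pairs seen in both.
* **Multiple testing.** Raw p-values are reported; Benjamini–Hochberg
  q-values are available behind `emit_qvalues`, off by default, since the
  four-way per-family p-values are screening aids rather than a single
  confirmatory test.
* **Probes hitting genes in two families** contribute to both family
  matrices (ambiguity is displayed, not resolved).

## The synthetic generator

`FixtureSpec`/`generate_fixture` emulate a two-organism study background:
per-organism gene sets (default 2,000 genes) with 1–3 isoforms per gene,
occasional non-coding transcripts and ambiguous probes, a disjoint family
partition (default 400 families, 1–4 genes per organism each) written both
as a pre-clustered table and as an equivalent pairwise relation list,
within-family e-values drawn log-uniformly over 20–80 decades with one
designated cross-organism best pair far below (110–150 decades), and
expression simulated as per-probe log2-ratios Gaussian around a gene-level
effect: 0 for null genes, ±2.0 for planted co-up/co-down/anti families
(noise SD 0.2 per probe). Planted effects are placed only in families with
at least two genes per organism, since a one-gene axis cannot express a
co-directed paralog pattern. The manifest records planted classes, family
sizes and planted loss records (uncovered genes, unresolvable features,
non-coding probe records), making every stage checkable.

What the generator does **not** emulate: real probe-design biases,
correlated noise between probes of one transcript, length/database-size
dependence of e-values, family-size distributions of real inference
pipelines, or any inter-gene correlation. Passing tests therefore
demonstrate the correctness of the mechanics (construction, accounting,
statistics, output), not calibration against biological data.

The analytic null expectation used in tests follows from the noise model:
a null unit is called in one direction with probability
q = Φ̄(log2(4/3)/σ), and a family with (n1, n2) units is selected under
`co_both` with probability 2·(1−(1−q)^n1)(1−(1−q)^n2) − b(n1)·b(n2) where
b(n) = 1 − 2(1−q)^n + (1−2q)^n, by inclusion–exclusion over the two
directions; axes are independent, directions within an axis are not.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale:
2,000 genes per organism and 400 families for end-to-end checks (seconds),
complete hypergeometric grids to N = 25 against an independent library and
N = 10 against draw-by-draw enumeration, and 1,000 random relation graphs
of up to 30 nodes against brute-force transitive closure. These sizes were
chosen so the full suite documents the behaviour in well under a minute;
the implementation itself has no built-in size limits.

## Known limitations

* The HTML view is a static rendering: selection flags are computed
  declaratively from the co-direction mode (plus explicit lists), not
  toggled interactively.
* `transcript` as ORA counting level is equivalent to `protein` through the
  1:1 correlation; non-coding transcripts never carry members.
* External resource links are emitted from URL templates only; nothing is
  fetched.
* Within one run all expression of an object must come in a single dialect.
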