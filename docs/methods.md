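# Methods

## Sign-consistency inference

The network model treats regulation as deterministic sign algebra: an edge
`u → v` with sign `s` is consistent with states `σ` when `σ(v) = s·σ(u)`.
This is the strongest reading of a curated interaction — it ignores dosage,
saturation and combinatorial logic — and is appropriate for the intended
use: triaging hand-curated literature networks for hypotheses worth
testing, not quantitative modelling.

State prediction is iterative weighted voting. Anchored nodes (observed
states) are immutable. Evidence weights are known = 2, predicted = 1,
calibrated so the packaged worked example reproduces its published score
arithmetic (downstream-only 2 v 2; with regulators 4 v 3). Only the
ordering known > predicted is substantive; the absolute values are a
design choice. qRT-confirmed and array-reported anchors share weight 2 —
the tier distinction is retained in the data model for display and future
re-weighting, not used in scoring. Direct and indirect edges score
identically; directness is provenance metadata.

Numerical/procedural choices:

* Round 1 scores against known neighbours only; later rounds re-score
  **synchronously** (all updates computed from the previous round), which
  makes the result independent of node order. Iteration stops at a fixed
  point or `max_rounds` (default 25; `max_rounds=1` gives a single
  known-evidence pass).
* Ties (`score_up == score_down`) leave a node undetermined, and
  undetermined nodes contribute weight 0 to neighbours. The algorithm
  therefore never amplifies a guess.
* Cycles can make the synchronous dynamics oscillate. Assignment snapshots
  are kept per round; when a snapshot repeats, every node whose state
  varies within the detected cycle is frozen as undetermined and iteration
  continues. Deterministic, conservative, and irrelevant for acyclic
  networks.
* Pruning removes an edge only when **both** endpoints are determined and
  the edge fails the consistency predicate; edges touching undetermined
  nodes survive. A post-condition check (tested) guarantees every
  remaining determined-determined edge is consistent.
* Parallel opposite-sign edges (literature conflicts) are retained and
  flagged, never merged silently.
* The greedy per-node decision can in principle differ from the global
  joint-consistency optimum on adversarial inputs; on planted-consistent
  networks the two coincide (tested by exhaustive enumeration on small
  networks) and divergences would surface in those tests rather than being
  hidden.

Hub summaries count **distinct downstream target genes** (not edges), the
natural reading when parallel edges exist; the default hub threshold is 7
downstream targets.

## Word-enrichment landscapes

Scoring is per-gene presence/absence of a heptamer in the 3′UTR — one
count regardless of site multiplicity — so the exact two-class urn
(hypergeometric) model applies with no approximation. This deliberately
omits the Markov-background composition corrections of word-counting
enrichment tools; with them, UTRs biased in base composition can shift
null levels. Passing tests on the i.i.d.-background generator therefore
says nothing about composition-bias robustness on real UTRs.

* Enrichment tail `P(X ≥ k)` and depletion tail `P(X ≤ k)` are both
  computed at each cutoff; the signed score is `−log10(p)` of whichever is
  smaller (positive = enriched among the leading, i.e. upregulated,
  genes). A word present in every gene scores exactly 0 everywhere.
* Default cutoff spacing is `n_genes // 50` (≈50 landscape points).
* Genes with UTRs shorter than 7 nt are retained as word-absent; dropping
  them would silently change the universe.
* p-values are floored at 1e-300 before taking logs.
* The full 4^7-heptamer scan evaluates the exact tails once per distinct
  (k, K, c) triple; across 16 384 words the triples repeat heavily, which
  makes the scan exact *and* fast (~0.4 s for 500 genes × 50 cutoffs).
* The seed match of a mature microRNA is the reverse complement (DNA) of
  nucleotides 2–8. The mutant-seed heptamer is never hard-coded; it is
  derived from a user-supplied mutant mature sequence.

## qPCR statistics

* Relative expression is 2^−ΔΔCt with a single reference gene; per pair
  the wildtype is 1 by construction, so group comparisons are mutant
  per-pair ratios against a unit wildtype group. No
  amplification-efficiency correction.
* The QC rule keeps a pair when the tissue-marker gene's relative
  expression lies within `|r − 1| ≤ 0.30` (wildtype as denominator, the
  same normalisation as everything else).
* `wilcoxon_exact` computes the full permutation distribution of the
  rank-sum with mid-ranks for ties, via dynamic programming over (subset
  size, doubled-rank sum) — exact for group sizes ≤ 12, asymptotic with
  tie and continuity correction above. Two-sided p is
  `min(1, 2·min(lower tail, upper tail))`. The exact branch is authored
  here because standard library routines fall back to the normal
  approximation whenever ties are present, and tied per-pair ratios are
  the norm in this design.
* BH adjustment is the standard step-up; the adjustment *family* is an
  explicit caller choice (the genes passed to one `analyze_qpcr` call).
  Published per-panel counts are reproduced with per-panel families.
* The signed fold-change convention is `r ≥ 1 → r`, `r < 1 → −1/r`;
  rounding is left to the caller.

## Gene-list compilation

Inclusion: any array record with adjusted P < 0.1 or any qRT-PCR record
with adjusted P < 0.05. The attached quantitative value prefers the
significant qRT-PCR fold change; otherwise the significant array value,
with the P4 (older-stage) array preferred over P0 when both qualify, since
the network quantities reference the P4 dataset. Sign conflicts between
significant sources are kept and flagged. Probe collapsing keeps the
lowest-raw-p probe per gene (ties → larger |fc|, logged). The
enrichment-tool input applies the ">10 % change" rule on the signed scale
(|fc| ≥ 1.1) **after** probe collapsing — the alternative order is not
distinguishable from the published description; this one is fixed here.

## Synthetic generators

The generators define the study conditions for every stochastic test.

* **Networks** (defaults: 200 nodes, per-ordered-pair edge density 0.02,
  repression fraction 0.3, anchor fraction 0.3, 40 % of anchors at the
  qRT tier, flip probability 0, acyclic): nodes are hidden behind a random
  order; in acyclic mode each unordered pair becomes a forward edge with
  probability 2·0.02 so the expected edge count matches the ordered-pair
  density in both modes. Truth states propagate from random root states:
  each node's first incoming edge draws its sign at the repression
  fraction and sets the node's truth; every other edge's sign is then
  forced by consistency. The repression fraction is therefore exact only
  on truth-setting edges — an unavoidable consequence of demanding a
  fully consistent planted signal. A designated root plays the microRNA:
  state down, all out-edges repressive, targets up (loss of repression).
  Anchors are a uniform node sample reporting truth, flipped independently
  with the flip probability.
* **UTR sets** (defaults: 500 genes, 500 nt, GC 0.5, planted word GTGCCAA
  in 80 % of a 100-gene leading block): background bases are i.i.d.; the
  planted word overwrites a uniform random position. Real UTRs are longer,
  composition-biased and share repeat families; none of that is emulated
  (see landscape caveat above).
* **Ct tables** (defaults: 5 littermate pairs, noise SD 0.15 cycles):
  Gaussian noise applies to target-gene Cts only; reference- and QC-gene
  Cts are generated noise-free so the number of QC-violating pairs is
  exactly `round(fraction · n_pairs)` by construction. Violating pairs get
  a QC ratio of 1.5. This is the simplest model that exercises the
  2^−ΔΔCt and QC contracts; it does not emulate efficiency differences or
  heteroscedastic cycle noise.

## PPI centrality

networkx supplies the graph algorithms; the conventions are pinned to
match the Cytoscape Network Analyser (betweenness normalised by
(n−1)(n−2)/2; Wasserman–Faust component-scaled closeness; isolated nodes
closeness 0) and verified against explicit shortest-path enumeration.
Reproducing any specific published centrality table requires the same
interaction-database snapshot and is out of scope; the packaged
high-degree table is a transcription used for the >75-degree filter only.

## Known limitations

* The consistency model is Boolean; it cannot express partial effects,
  thresholds or combinatorial regulation.
* Greedy per-node voting is not a global optimiser; see above.
* Presence/absence word scoring ignores site multiplicity and composition
  bias.
* Gene identifiers are matched exactly, case-preserved; alias resolution
  is out of scope to avoid silent mis-joins.
* The packaged worked-example neighbourhood is a partial reconstruction:
  two of its five genes are placeholders (the published figure names only
  three), so it fixes the score arithmetic, not the biology.
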