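# Methods

## The two-stage model

The package treats a PPI network as a simple undirected graph *G = (V, E)*
over opaque protein identifiers (edges stored canonically, smaller ID
first). The working assumption of stage 1 is that physically interacting
proteins tend to be co-expressed and to share biological function, so two
local similarity indices of an *unlinked* pair serve as its existence
likelihood:

- **Expression correlation.** The Pearson correlation of the two genes'
  expression profiles, computed with the sample (n−1) standard deviation.
  The blockwise all-pairs implementation standardizes each profile and
  takes inner products; it is contractually identical (≤ 1e-10) to the
  pairwise formula. Pairs where either gene is missing from the
  expression matrix, has zero variance, or contains a non-finite value
  score 0 — the same convention used for unannotated proteins in the GO
  index — so any positive threshold excludes them. A
  `pairwise_complete` flag switches to correlations over the samples
  finite in both profiles.
- **GO semantic similarity.** A Wang-style measure: each ancestor of an
  annotated term receives a multiplicatively decaying S-value (max over
  paths), with per-relation weights w(is_a) = 0.8 and w(part_of) = 0.6 —
  the customary constants of this measure family; both are configurable,
  and other relations (e.g. `regulates`) are ignored. At the protein
  level the term set T_u is by default the ancestor closure of the
  protein's annotations with S_u(t) the maximum S-value over its
  annotated anchors; a flag restricts T_u to the directly annotated terms
  (which reduces the measure to a Dice overlap). Either protein lacking
  annotation gives similarity 0. Annotations default to the BP
  sub-ontology; evidence codes are not filtered unless requested.

Both threshold comparisons are inclusive (≥): behaviour at exact equality
is otherwise undefined, and inclusive is deterministic. GO similarity is
only evaluated for pairs that already pass the PCC gate — the same
two-stage filter used to build the augmented networks, and the reason the
computation stays cheap.

Stage 2 ranks proteins by centrality on the original network and on the
two augmented networks and looks for gold-standard essential proteins that
(a) enter the top *K* under at least one of the chosen measures in *both*
augmented networks, (b) are absent from the top *K* under every measure on
the original network, and (c) — the "deep-ranked" subset that drives edge
selection — sit beyond rank *R* under *all* measures originally. The
"any" quantifier for (a) and the "all" quantifier for (c) are the defaults;
both are configurable, since the rule is stated loosely in this literature.
Predicted edges incident to a deep-ranked candidate form the selected
group; validation counts the edges present in a confidence-scored
reference set at confidence ≥ 0.7 (inclusive).

## Centrality measures

Six measures are registered (DC, BC, CC, EC, SC, NC); stage 2 defaults to
DC/NC/SC, the topology-local ones that respond most directly to added
edges. Implementation notes:

- **CC** uses component-restricted closeness with Wasserman–Faust scaling
  ((component size − 1)/(N − 1)), which stays finite on disconnected
  graphs.
- **EC** is the principal eigenvector by power iteration to 1e-10 with the
  all-nonnegative (Perron) sign convention.
- **SC**(i) = Σ_k (Aᵏ)_ii / k! is evaluated as the diagonal of exp(A) via
  symmetric eigendecomposition; the contract (tested) is agreement with
  the truncated power series.
- **NC**(u) = Σ_{v ∈ N(u)} ECC(u, v), where ECC(u, v) = z(u, v)/min(d_u−1,
  d_v−1) with z the number of triangles through the edge, and ECC = 0 when
  the denominator vanishes.

Rankings are descending by score with lexicographic tie-break (recorded in
the ranking object) so that runs are reproducible to the byte.

## Random-walk baselines

RWR solves p = (1−c)·W·p + c·e_x per seed (W column-normalized, restart
c = 0.8 — the walk's only free parameter), iterating all seeds at once to
an L1 tolerance of 1e-10; mass leaving an isolated node returns to the
seed so every stationary vector remains a probability vector. The pair
score is p_x[y] + p_y[x]. LRW uses the t-step simple-random-walk
transition (t = 3) weighted by q_x = d_x/2|E|; the exact-t variant is the
default, the superposed variant (summing steps 1..t) is behind a flag.
Top-proportion selection takes ⌊proportion·|E|⌋ unlinked pairs, ties
broken lexicographically. Further scorers can be registered against the
same similarity-matrix contract.

## The synthetic generator

The generator emulates the full input bundle from one seeded RNG: a truth
network (Barabási–Albert, attachment 3, 300 nodes by default, or
Erdős–Rényi), an observed network obtained by hiding 10% of edges, 36
expression samples, a complete ternary ontology tree of depth 6 (every
fifth link `part_of`), annotations, an essential set (top truth-degree
decile) and a confidence-scored reference set (truth edges at
Uniform(0.7, 1) with a 10% false-negative fraction below 0.7; decoy
non-edges, half as many as truth edges, at Uniform(0, 0.7)).

Design choices that matter for interpreting test results:

- **Hiding.** The default mode hides a random matching with every
  endpoint keeping degree ≥ 1 (falling back to arbitrary hidden
  components only when the matching is exhausted; genuinely infeasible
  configurations raise). The `hub` mode first hides 80% of the edges
  around five designated essential proteins — the situation stage 2 is
  designed to detect. Hub proteins are taken from the *low-degree end*
  of the essential set so that losing edges actually moves their rank.
- **Expression.** Each connected component of the hidden-edge graph
  shares one latent factor; members are √ρ·z + √(1−ρ)·ε with ρ = 0.99,
  so every hidden pair has population correlation ρ, while background
  proteins are independent noise (optional global background factor).
  With 36 samples, chance correlation of independent pairs at |r| ≥ 0.95
  is negligible, which is what makes the planted-recovery precision
  checks meaningful.
- **Annotations.** Each protein carries one random leaf term; each
  hidden-edge component additionally has two dedicated leaf terms given
  to members with probability 0.9. Shared terms are planted along
  *hidden* edges only: GO similarity is only ever evaluated on unlinked
  pairs, and the only unlinked truth pairs are the hidden ones, so
  planting along observed edges would merely dilute hub annotation
  profiles without affecting any scored pair. Functional coherence of a
  hidden component mirrors a complex whose interactions were missed
  together.

What passing tests on this generator do **not** show: real expression
compendia have correlated noise, batch structure and missing values; real
GO annotation is far sparser, deeper and biased toward well-studied
proteins; real reference confidences are not uniform. The generator
demonstrates that the machinery is correct and that the method's
qualitative behaviour (GO filter only removes, selected group enriched,
baselines weaker on co-expression-driven hidden edges) emerges under its
own assumptions — not that the operating thresholds transfer to any
particular real dataset.

## Scales and cutoffs

Pipeline defaults keep the canonical operating points (network 1:
PCC ≥ 0.98; network 2: PCC ≥ 0.95 and GO ≥ 0.5) and the conventional
K = 200, R = 1000, which presuppose networks of several thousand
proteins. Analyses of the 300-node synthetic scenario use K = 45 and
R = 60: after hiding, a hub sits near rank 150 of 300 and recovers to
roughly rank 10–45 once its edges are restored, so the cutoffs are chosen
from that structure (K ≈ 15% of nodes, R ≈ 20%). The pipeline clamps K to
the network size and enforces R ≥ K.

## Numerical and degenerate-input choices

- Duplicate scored reference lines keep the **maximum** confidence
  (evidence-union reading); self-interactions are dropped everywhere; a
  node seen only in a dropped self-loop remains a node.
- Validation of an empty edge group reports fraction 0 with a warning;
  an empty reference set makes all reported fractions an explicit
  undefined marker (`null` in the JSON report) rather than 0.
- Empty predictions give undefined precision (None) and recall 0.
- Only gold-standard essentials count as hits; proteins absent from the
  essential list — including genuinely unclassified ones — count as
  non-essential in every tally.
- Candidate selection treats a protein missing from a ranking as rank
  infinity (cannot occur when node sets match, but documented for
  generality).
- All file outputs are sorted canonically and floats formatted
  identically, so a fixed config + seed reproduces outputs byte for byte.

## Known limitations

- No identifier mapping: expression, annotation, essential and reference
  files must share the network's naming system.
- The supervised and resistance-based random-walk variants are not
  implemented; the scorer registry accepts external implementations.
- Stage-2 counts compare top-K sets only; no significance test is
  attached to the set differences.
- GO S-value caching is per-DAG and unbounded; very large ontologies with
  millions of distinct anchors would need an eviction policy.
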