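# Methods

## Problem setting

Clinical coding maps a free-text diagnosis line to a set of concept codes
from a terminology organised as an is-a polyhierarchy (a directed acyclic
graph of child→parent subsumption edges, as in SNOMED CT).  Different coders
— clinicians, coding software, or a consensus panel — produce different code
sets for the same line, and raw exact-match rates understate how close a
near-miss is: choosing a parent or sibling of the reference code is a far
smaller error than choosing an unrelated concept.  `ontocode` therefore
grades disagreement by distance in the hierarchy.

## Distance model

**Pairwise distance.** δ(a, b) is the shortest-path length between codes a
and b with is-a edges traversed *undirected*, so one hop to a parent or to a
child each costs 1.  Undirected traversal is the simplest reading that makes
a code and its grandparent exactly 2 apart, which is how the metric is used
in practice; it also makes δ a true metric within each connected component
(symmetry, identity, triangle inequality — all property-tested).  Codes in
different components get an explicit `UNREACHABLE` sentinel (`math.inf`),
never a substitute constant: any finite stand-in would silently distort
averages.  Downstream, unreachable results fall only in the >3 residual band.

**Set distance.** For code sets X and Y the value is the mean of the per-code
minima in both directions (each x against its closest y, each y against its
closest x), over |X| + |Y| terms.  Pairing each code with its *nearest*
counterpart avoids penalising an item for describing several distinct
findings.  Averaging both directions penalises over-coding (spurious extra
codes raise the y→x terms) and under-coding (omissions raise the x→y terms)
alike.  The worked tendinitis/clavicle example is symmetric, so it cannot
discriminate between the bidirectional and one-directional readings; both
reproduce its value of 1.  A `direction="x_to_y"` switch preserves the
one-directional alternative for sensitivity analyses.

**Exactness and bands.** An *exact match* is set identity, not value = 0 —
on the one-directional variant a strict subset also has value 0, and set
identity is robust to pathological graphs.  Non-integer averages are banded
unrounded; bands exact/≤1/≤2/≤3/>3 are reported as cumulative percentages,
so every table row is non-decreasing left to right (an invariant asserted on
every emitted table).

## Comparison design

Code sets are first intersected with the descendant closure of a designated
finding root (the root itself included — the root of a finding subhierarchy
is itself a finding), which removes qualifier/procedure codes.  Codes absent
from the loaded ontology are dropped with a warning rather than an error,
because real annotation files cite retired codes; a strict mode upgrades this
to an error.  For each coder pair, items where either filtered set is empty
are excluded and counted by reason.  Items are stratified as single-finding
when *both* compared sets are singletons, multi-finding otherwise — a
mixed-arity pair (one singleton, one multi-code set) is multi-finding by the
literal both-single definition.  The gold standard is just another coder id
(`GS`), so one comparison engine serves human-vs-human, human-vs-gold and
software-vs-gold designs.

**Micro-averaging.** The multi-coder summary pools per-item outcomes across
all (coder, item) comparisons before computing percentages.  Coders with more
usable items therefore weigh more, which is the intended semantics; a mean of
per-coder percentages (macro) is deliberately *not* offered, and a unit test
pins the distinction (4/6 ≈ 66.7% micro vs 62.5% macro on a hand-countable
example).

**Qualitative concordance.** Ratings (Good / Acceptable / Not acceptable)
are input data — expert judgement is never computed.  The concordance table
groups (coder, item) observations by rating level, pooling coders, and
tabulates the cumulative band percentages plus the mean finite distance per
level; a monotone association shows as higher exact percentages (and lower
mean distances) for better ratings.  The cross-coder table asks whether the
same items are easy or hard for two coders: a contingency of exact/not-exact
outcomes (or rating × rating) against a shared reference, with margins.

**Display rounding.** CSVs carry full precision; the markdown report rounds
percentages to integers with round-half-away-from-zero so rendered reports
are bit-stable across platforms.

## Synthetic data generator

The generator emulates the statistical structure of a diagnosis-coding study
so every stage is testable without licensed terminology content:

* **Ontology** — a single-rooted random DAG; concept i attaches to
  1..`max_parents` uniformly chosen earlier concepts.  Defaults: 500
  concepts, `max_parents` 2.  Real terminologies are orders of magnitude
  larger (a Clinical-Finding subhierarchy has ~10⁵ codes) with heavier-tailed
  branching; 500 concepts keeps the full pipeline interactive while giving a
  realistic spread of inter-code distances.
* **Gold standard** — default 708 items; each is multi-finding with
  probability `multi_fraction` = 0.125 (seven single-finding items per
  multi-finding one, the imbalance typical of outpatient diagnosis lists),
  drawing 2–3 codes without replacement from the finding subhierarchy.
* **Coder error model** — per gold code: reproduced with `p_exact`,
  otherwise replaced by the endpoint of a random walk of geometric length ≥ 1
  over undirected is-a edges (`drift_geom` continuation probability), so both
  generalisation (ancestor) and over-specification (descendant) errors occur.
  Drift endpoints are resampled to differ from the original code; otherwise
  even-length walks return home and the realised exact-match rate exceeds
  `p_exact`, which would break parameter-recovery guarantees.  Then omissions
  (`p_omit`, multi-code sets only, never emptying the set), spurious
  additions (`p_add`, uniform over the subhierarchy), and whole-item
  invalidity (`p_invalid`, empty set) apply.  The study-shaped preset uses
  single-code exact rates of 0.86 / 0.89 for the two human-like coders and
  0.77 for the software-like coder — illustrative values bracketing typical
  human and automated coding performance, not fitted to any dataset.
* **Rating model** — a cumulative-logit model: P(Good) = σ(c₁ − b·d) and
  P(Good ∪ Acceptable) = σ(c₂ − b·d) with c₂ > c₁ (defaults c₁ = 2.0,
  c₂ = 4.5, b = 1.2, unreachable distances treated as 10 edges), giving
  monotonically worse ratings at larger distances.  Degenerate (always one
  level) and step (Good iff exact) variants exist for construction tests.

All generators are bit-reproducible given (parameters, seed); one study seed
fans out to fixed substreams (ontology / gold / per-coder / ratings), so
adding a coder never perturbs the gold standard.

### What passing tests do and do not show

The simulation validates the *machinery*: that distances, exclusions,
stratification, pooling and concordance are computed correctly, that injected
parameters (error rates, multi-finding fraction) are recovered within
binomial tolerance, and that the distance-rating association has the expected
direction under a monotone rating model.  It does not model free-text
ambiguity, coder-specific biases, terminology revisions, or the correlated
errors of NLP systems (e.g. abbreviation confusion), so passing tests say
nothing about the agreement levels any real coders would achieve.

## Numerical and degenerate-input choices

* Empty code sets are a contract violation for the metric itself; ingestion
  keeps them (flagged invalid) so exclusion counts can be reported.
* A stratum with zero usable items reports n = 0 with NaN percentages, never
  a division error; NA renders as `NA` in markdown.
* Duplicate (item, coder) rows are an ingestion error; duplicate codes within
  one cell collapse (code sets are unordered, multiplicity-free).
* Shortest-path queries cache the full BFS frontier per source code; the
  graph is immutable after construction so the cache never invalidates.

## Fixture problem sizes

The test suite runs the oracle-equivalence check on 100 random DAGs of up to
50 nodes, parameter recovery on 5,000 singleton items over a 300-concept
ontology, the rating-direction check on 10,000 items, and three full
simulate→evaluate rounds at 250 items — sizes chosen so the whole suite
completes in seconds while keeping binomial standard errors small enough for
3-SE assertions to be meaningful.

## Known limitations

* Only the is-a hierarchy is used; attribute relationships, description-logic
  semantics and post-coordinated expressions are out of scope, as are
  information-content or depth-weighted similarities (Wu–Palmer, Lin,
  Resnik) — the metric is raw edge counts by design.
* Chance-corrected agreement (kappa) is not computed; tables report raw
  percentages.
* The RF2 reader handles the snapshot dialect only (one row per
  relationship), not full-history releases.
* The synthetic ontology's branching process is a convenience model, not a
  fit to any released terminology's degree distribution.
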