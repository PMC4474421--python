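# Methods

## Signed-network model

Entities carry one of three roles — compound, CYP regulator, CYP enzyme —
and interactions are directed signed edges: +1 activation, −1 inhibition,
0 unknown direction. The network is a simple digraph: at most one edge
per ordered pair, no self-loops (a layered regulatory graph gives
self-edges no meaning). When curated rows assign conflicting signs to
the same ordered pair, the table keeps both records; network
construction collapses them to a single sign-0 edge with a logged
warning. Conservatism over voting: a conflict means the direction is
not established, and pretending otherwise would propagate a wrong sign
through every downstream path product.

Effect keywords map case-insensitively (activation/activates/up → +1,
inhibition/inhibits/down → −1, unknown/unspecified → 0); anything else
is a hard parse error naming the line, never a silent 0. Exact
duplicate rows collapse with a multiplicity counter; all degree
computations count distinct edges, not multiplicity.

## Filtering

Two elimination rules, applied as two passes on a copy of the input:

1. remove every compound with fewer than `min_compound_edges` (default
   3) distinct incident edges (in + out);
2. remove every regulator left without a compound neighbour.

Removals cascade (dropping a regulator lowers compound degrees), so a
`iterate_to_fixpoint` flag repeats both passes until stable. The default
is a single pass — the most literal reading of the two rules stated
together — and the fixpoint variant is the self-consistent alternative;
neither ordering is claimed to be canonical, which is why both are
exposed. In fixpoint mode re-filtering is the identity (tested).

## Path tracing and prediction

A prediction is a *simple* directed path (no repeated node) from a
compound to a terminal leaf — any node with out-degree 0 — with at most
`max_depth` edges (default 10). The net sign is the product of edge
signs with 0 absorbing. A compound that is itself a leaf yields no
paths: a zero-length path carries no interaction. Simple-path
enumeration plus the depth cap makes tracing terminate on cyclic curated
data (regulator–regulator loops occur in practice). Output order is
lexicographic in the node sequence, for reproducibility.

`predict_interactions` keeps paths whose terminal is an enzyme and
aggregates per (compound, enzyme): a single common sign if all paths
agree, else 0, with every contributing path reported. Hub clusters are
per-regulator sets of compound in-neighbours, ranked by size descending
with lexicographic hub-id tie-break.

## Fold change

Two conventions, chosen explicitly because wet-lab reports often omit
the formula used:

* **ddct** (for Ct data): per replicate `2^-(Ct − mean vehicle Ct)`;
  the per-dose mean is computed on the Ct (log2) scale, i.e. the
  geometric mean of the replicate fold changes. This makes the vehicle
  mean exactly 1 (an arithmetic mean of `2^x` terms would not be) and
  matches the multiplicative error structure of qPCR.
* **ratio** (for already-relative data): value / vehicle mean,
  arithmetic per-dose mean, vehicle mean exactly 1.

No reference-gene normalization or amplification-efficiency correction
is attempted.

## ANOVA and Tukey HSD

The omnibus test is the standard one-way between-treatments ANOVA from
explicit between/within sums of squares; by default the pipeline runs it
on fold-change values (the quantity the dose-response question is posed
about), with raw values available. Zero within-group variance is an
error, not F = ∞: degenerate data must not masquerade as overwhelming
significance. Groups of fewer than two replicates are rejected.

P-values use the exact identity `P(F(d1,d2) > f) = I_x(d2/2, d1/2)`,
`x = d2/(d2 + d1 f)`, via the regularized incomplete beta function
(absolute accuracy ≲ 1e−12; the identity `sf + cdf = 1` holds to 1e−10,
tested).

Tukey HSD is implemented for balanced designs only — the validation
design is balanced, and a silent Tukey–Kramer fallback would change the
test without the user noticing; unbalanced input is an error naming the
group sizes. For each unordered pair, `q = |m_a − m_b| / sqrt(MS_w/n)`
and `p_adj = P(Q(k, ν) > q)`.

The studentized-range tail is evaluated in-package by tensor-product
Gauss–Legendre quadrature (400 nodes in z over [−9, 9], 300 nodes in the
chi scale variable up to the 1e−16 tail cut) of

    P(Q ≤ q) = ∫₀^∞ f_ν(s) · k ∫ φ(z) [Φ(z) − Φ(z − qs)]^{k−1} dz ds,

where `f_ν` is the density of `sqrt(χ²_ν/ν)`. A slow nested
adaptive-quadrature evaluation of the same integral is kept as an
independent cross-check; the two schemes agree to ~1e−12, and the fast
scheme agrees with an external implementation to ~5e−13 over a broad
(q, k, ν) grid. At k = 2 the tail reduces to the two-sided t tail at
`t = q/√2`, which is tested to 1e−9 and drives the Tukey/t equivalence
check.

## Synthetic data

**Interaction databases.** The generator emulates a two-layer curated
database. Compounds attach to regulators by weighted sampling with fixed
per-regulator weights (default Zipf-like `1/rank`), giving the skewed,
hub-dominated cluster-size ranking characteristic of curated
compound–regulator networks; fixed weights were chosen over preferential
attachment because they keep the ground truth trivially bookkeepable
while still producing heavy-tailed hubs. Per-compound degree is Poisson
with mean `mean_compound_degree` (default 2.9 ≈ a few curated edges per
compound); regulator→enzyme edges are uniform with Poisson mean 2.0.
Signs are iid from `sign_probs` (default 0.45/0.45/0.10 — a small
direction-less fraction, as in curated data). Defaults are 300
compounds, 15 regulators, 10 enzymes.

Explicit paths can be planted with chosen signs; random edges never
duplicate or contradict a planted edge (rejection sampling). Ground
truth is computed inside the generator by an exhaustive double loop over
the two edge layers (in the generated DAG every compound→enzyme path has
exactly two steps) — independent of the pipeline's own tracer, so
truth-recovery tests are a genuine dual-route check even when random
edges create additional paths between a planted compound and enzyme (the
truth is then the aggregate sign over all paths, which is what the
pipeline must report).

**qPCR.** Ct(dose, rep) = baseline − log2_effect(dose) + N(0, noise_sd):
Gaussian noise on the cycle (log2-expression) scale, the standard qPCR
error model. Defaults emulate the vehicle + 0.1/1/10/100/1000 nM
triplicate design: baseline 24 cycles, noise SD 0.25 cycles (a typical
inter-day technical spread), and a saturating effect profile
(0, 0.5, 1.0, 1.8, 2.0, 2.1 log2 units) — monotone, flattening at the
mid doses. The profile is fully user-settable; no published fold-change
magnitudes are baked in.

What the generators do *not* emulate: literature-mining noise (false or
direction-flipped curated edges beyond the sign-0 fraction),
regulator–regulator edges, day effects or other replicate correlation
(replicates are iid, matching the plain one-way ANOVA that analyses
them), amplification-efficiency variation, and reference-gene
normalization. Passing tests therefore demonstrate correctness of the
algorithms under these idealized conditions, not robustness of the
discovery strategy to curation error in real databases.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through numpy
Generators; identical config + seed gives byte-identical output files
(tested at the CLI level). The standing test and acceptance runs use:
oracle equivalence on 100 random graphs of ≤ 13 nodes (path tracing and
filtering), 2000 simulated 6×3 null experiments for type-I calibration,
50 two-group datasets for the Tukey/t identity, and 50 random synthetic
databases (2–40 compounds) for planted-truth recovery — sizes at which
the brute-force oracles are exact and the whole suite runs in a couple
of minutes on one core.

## Known limitations

* Tukey HSD has no unbalanced (Tukey–Kramer) mode.
* The degree filter's single-pass default and the fixpoint variant can
  disagree on cascading removals; callers choose.
* Sign conflicts always resolve to 0, never by majority or provenance
  weighting.
* The discovery CLI assumes a two-file layout (compound–regulator and
  regulator–enzyme edges); arbitrary role projections are available
  through the library API.
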