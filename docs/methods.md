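# Methods

This note documents the models, parameter choices, numerical details
and known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Heme-motif census

The multiheme-cytochrome (MHC) census is purely positional: a motif is
any five-residue window with cysteine at positions 1 and 4 and
histidine at position 5. The two X positions accept any residue symbol
present in the sequence, including ambiguity codes (X, B, Z), because
the signature is defined by the constrained positions alone; stop (`*`)
and gap (`-`) characters never match any position. Every start index
is scanned, so overlapping occurrences all count — motif occurrences
are the unit being tallied and no de-overlap rule is part of the
definition. A protein is an MHC when it carries at least `min_motifs`
motifs (default 2: at least two hemes), and the proteome total
`n_motifs_in_mhc` sums motifs over MHC-classified proteins only, since
the census reports motifs *carried by* the MHCs. The summary records
which input file was scanned; when alternative annotations of the same
genome exist (e.g. GenBank versus RefSeq assemblies), the counts refer
to whichever was supplied.

## Chronograms and ensembles

A chronogram is a rooted tree whose node ages (Ma) decrease strictly
from root to tips, tips at age 0. Validation computes node age as tree
height minus root-to-node distance and requires all tips equidistant
from the root within `tolerance` × height (default 1e-6), naming the
worst tip pair on failure; tip ages are then snapped to exactly 0 (all
taxa are treated as extant).

Posterior ensembles are Newick tree lists, one tree per line, no
translate tables (NEXUS is out of scope). Burn-in discards the first
⌊`burn_in` × n⌋ trees per file, thinning keeps every `thin`-th of the
remainder, and files (chains) are concatenated after burn-in. The
default burn-in is 0.25; 0.20 is also in circulation for the same kind
of analysis, so the value is a parameter and never hard-coded.

Clade ages: crown = age of the spanning MRCA of the clade's taxa, stem
= age of that node's parent (root age when the MRCA is the root). A
clade that is non-monophyletic in some sample resolves to the spanning
MRCA with a logged warning rather than an error, because posterior
samples may vary in topology. Credible intervals are equal-tailed
(2.5th–97.5th percentiles, linear interpolation between order
statistics), not HPD: "95% CI" without qualification is reproducible
this way without any density estimation. HPD support would be an
extension, off by default.

## Undated DTL reconciliation

The reconciliation model is the undated Duplication–Transfer–Loss
parsimony model: speciations are free; duplications cost δ; transfers
cost τ with the recipient constrained only to be neither ancestral nor
descendant to the donor (no dating inside the reconciliation — the
chronology is tested downstream, which mirrors the reconcile-first,
assess-later pipeline order); losses cost λ. Between consecutive gene
events a lineage may pass through species nodes, losing the unused side
each time (speciation-loss, λ per step), or jump to an incomparable
lineage while its source copy dies (transfer-loss, τ+λ per step).
Transfer-loss chain steps are required for exactness: descending k
nodes of a caterpillar costs kλ, while one jump costs τ+λ, so omitting
them breaks minimality already on 7-leaf trees under (1,1,1).

The dynamic program iterates gene nodes in postorder. For each gene
node it first prices the best *event* at every species node
(speciation, transfer, duplication, evaluated in that preference
order), then runs a shortest-path relaxation over the chain graph
(edges: parent→child at λ; node→incomparable node at τ+λ) to price
the best *entry* at every species node. Relaxation iterates to a fixed
point (at most |S|+1 rounds; all weights are nonnegative) recording
predecessor steps only on strict improvement, which keeps the witness
chains finite and deterministic. The gene root maps wherever its event
cost is least, with no charge above it. Ties break by the event
preference order and then by species-node postorder index; exactly one
most-parsimonious witness is returned — co-optimal enumeration and
amalgamation over gene-tree samples are out of scope, as is
probabilistic (ALE-style) reconciliation. Polytomies are rejected, not
resolved. Complexity is O(|G|·|S|²) per relaxation round; desk-scale
trees reconcile in milliseconds.

The optional **dead lineage** is a single atemporal unsampled lineage
parallel to the whole species tree. Chains enter it at τ+λ (the
sampled copy is lost), persist in it for free, and leave it at τ alone
— losses inside an unsampled lineage are unobservable, so no λ is
charged on exit. Binary transfer events may also use it as donor or
recipient at τ. Because it only adds options, enabling it can never
increase the minimum cost (property-tested). More elaborate
Pareto-front strategies over multiple dead lineages are out of scope.

`brute_force_cost` is deliberately a different algorithm: it
enumerates every assignment of internal gene nodes to species nodes
(the dead lineage included when enabled), prices the forced event and
cheapest loss chains for each assignment using an all-pairs chain-cost
matrix, and minimizes. It is the oracle in the equivalence tests and
is capped at 6 gene leaves. The exhaustive sweep covers all rooted
binary gene/species pairs on ≤5 leaves by crossing one canonical
species tree per topology shape with every labelled gene tree — costs
are invariant under simultaneous leaf relabelling, so this covers all
pairs up to isomorphism at a fraction of the runtime.

Transfers extracted from a witness become HGT constraints whose donor
and recipient clades are the leaf sets below the donor and recipient
species nodes (crown-crown comparison by default; transfers touching
the dead lineage are reported but flagged untestable). The
interval-overlap check is the weaker necessary condition: a transfer
needs contemporaneous donor and recipient edges, i.e. overlapping
[child age, parent age] spans (open intervals; touching endpoints do
not count; the root edge is open-ended above).

## Compatibility assessment

A chronogram satisfies a constraint when the donor node is *strictly*
older than the recipient node, with the node on each side chosen by the
constraint's mode (crown-crown, stem-crown or stem-stem). The mode is
explicit data on every constraint because "donor older than recipient"
underdetermines the node pair; exact ties count as incompatible since a
transfer requires strict precedence. Per-constraint fractions and the
joint (all-constraints) fraction are both always reported — headline
percentages in the literature are sometimes per-transfer, sometimes
joint. Model ranking sorts by joint fraction, ties broken
alphabetically by label. Filtering keeps exactly the samples
satisfying all constraints, in order, and errors (with advice) when
none remain; constrained age summaries are ordinary summaries of the
filtered ensemble.

## Synthetic generators

All generators draw from one seeded numpy `Generator`; seeds are
mandatory (no wall-clock seeding) and every output is bit-reproducible.

**Species trees** come from a forward birth–death simulation started
at one origin lineage and stopped the first time standing diversity
reaches `n_taxa`, with the present placed a uniform fraction into the
waiting interval after that moment so that no terminal branch has zero
length. Extinct lineages are pruned, unifurcations suppressed.
Conditioning (survival and the `root_age_max` cap) is by retry, capped
at 10,000 attempts — simplicity over efficiency at desk scale. The
defaults emulate a deep-time bacterial clade: 12 taxa, birth 0.003 and
death 0.001 per Ma (crown ages typically several hundred to ~2,000 Ma),
root capped at 3,900 Ma, matching the scale of the root calibration
used in deep molecular-clock studies (3.9 ± 0.23 Ga, 3.44–4.36 Ga).
Stopping at first passage to `n_taxa` is not the uniform-slice general
sampling approach; the test oracle (an independent re-simulation of the
same interarrival sums, cross-checked against dendropy's birth-death
simulator with the documented half-interval offset) targets the rule
actually implemented.

**Ensembles** emulate posterior chains at the chronogram level, not by
MCMC: each sample multiplies every internal node age by independent
lognormal noise with median 1 and coefficient of variation `jitter_cv`
(default 0.05, a typical relative posterior spread for well-constrained
nodes), then a postorder repair pass enforces parent age ≥ max(child
ages) + ε with ε = 1e-9 × root age. Multiplicative-lognormal-plus-
repair was chosen over jointly resampling node ages because it is
simple, seedable, and guarantees validity of every sample; samples
share the truth's topology object and differ only in their age maps.
What this does *not* emulate: topological posterior variation,
autocorrelation along a chain, cross-node correlation of age errors,
and any systematic (biased) misestimation. Tests passing on this
generator therefore show the statistics are computed correctly, not
that any real chain is well calibrated.

**Planted transfers** draw a time uniformly in (0, root age) and two
distinct edges alive at that time (redraw, bounded, if fewer than two
— with `internal_only`, both edges must subtend ≥2 leaves so crown
ages are informative). Two contemporaneous edges are never
ancestrally related, so the clades are disjoint. The emitted
constraint uses stem-crown mode, which is true on the generating tree
by construction (donor stem > transfer time > recipient crown).

**Gene trees** evolve one copy from the species root: per-copy Poisson
duplications, transfers (to a uniformly chosen contemporaneous other
edge; the donor copy continues) and losses at the `dtl_rates`
(defaults 0.0002, 0.0005, 0.0002 per Ma per copy: a handful of events
over a default tree, the scale at which a single gene family is
informative without drowning the species signal). Speciation splits
every copy into both daughters; surviving copies become leaves labelled
by species; dead subtrees are pruned and unifurcations suppressed.
Forced transfers at recorded times support planting exact ground truth.
No sequence evolution is simulated anywhere.

**Proteomes** plant exact motif counts: background residues are drawn
from an 18-letter alphabet containing neither C nor H, and planted
motifs are separated by ≥2 background residues, so no accidental or
straddling motif can occur; every record is verified against the
scanner before being returned. The default plan (30×0, 10×1, 15×2,
10×5 motifs) lands the census at 25 MHCs carrying 80 motifs in a
65-protein proteome — the per-genome scale reported for
ammonia-oxidizer proteomes, at reduced proteome size.

## The calibration experiment

The credible-interval calibration check (tests and acceptance script)
asks whether the equal-tailed 95% interval from a 1,000-sample
ensemble covers the true node age at its nominal rate, over 200
replicate runs at `jitter_cv` 0.05. Jittering an ensemble directly
around the truth would make the truth the exact median of every node's
sampled distribution, so the interval would cover it essentially
always — a vacuous check. Each replicate therefore centres its
ensemble on one noisy draw from around the truth (the same lognormal
noise), emulating how a finished chain is centred on an estimate that
is itself offset from the truth; with matched noise the nominal ~95%
coverage is the correct expectation, and the experiment genuinely fails
if intervals are too narrow, too wide, or biased.

## Numerical and formatting conventions

Costs and ages are floats; DP/brute-force agreement is asserted to
1e-9. Tables are TSV, one header row, `.` for missing values, floats
at 6 significant digits. Ground-truth sidecars are flat key/value
text. The CLI exits 0 on success, 1 on validation or processing
errors (naming the failing input), 2 on usage errors; every run writes
an effective-config YAML next to its outputs, and primary outputs are
byte-identical across reruns with the same inputs and seeds.

## Problem sizes used in the checks

The exhaustive DTL sweep covers 349 tree pairs × 2 cost vectors (698
reconciliations, brute force up to 9⁴ mappings each). Compatibility
recount uses 500-sample ensembles on 12-taxon trees with 4 planted
constraints. Planted-transfer recovery uses 100 replicates of
500-sample ensembles (plus 5 noiseless replicates). Calibration uses
200 replicates × 1,000 samples × 11 internal nodes. The motif oracle
uses 1,000 random sequences up to 120 residues over a 23-letter
alphabet including ambiguity, stop and gap symbols.

## Known limitations

- The reconciliation returns one witness among possibly many
  co-optimal histories; extracted transfer constraints depend on the
  (deterministic) tie-break.
- The undated DTL model can accept histories that a dated model would
  reject; chronological plausibility is only tested downstream.
- Crown-crown constraints are uninformative when either clade is a
  single tip (crown age 0); stem modes exist for exactly this reason.
- The jitter model's independence across nodes understates the
  correlated uncertainty of real posteriors; compatibility fractions
  on real chains will be smoother functions of the constraint set than
  on synthetic ensembles.
- Birth–death conditioning by retry can be slow or fail for parameter
  combinations that make `n_taxa` survivors unlikely or the root-age
  cap tight; the error says so after 10,000 attempts.
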