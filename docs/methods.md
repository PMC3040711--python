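# Methods

## The problem

Two sister species that still exchange genes — or that simply retain
polymorphism from their common ancestor — show overlapping multilocus
genotypes. Summary statistics computed at the population level cannot say
*which individuals* carry the intermediate genotypes, and model-based
clustering rests on Hardy–Weinberg and linkage assumptions that do not hold
inside a hybrid zone. `hybnet` implements an individual-centered
alternative: build networks whose nodes are individuals and whose links are
genetic distances, prune the links to the percolation threshold, and read
hybridization off the topology — which individuals bridge the two species
clusters, and where they were sampled. The discriminating signal is
geographic: present-day hybridization concentrates inter-species proximity
in sympatric regions, whereas ancestral shared polymorphism is spread over
the whole range.

## Distances

Individuals are diploid multilocus microsatellite genotypes
`A = (a_1, A_1)…(a_k, A_k)`, allele lengths in nucleotides.

**Rozenfeld distance (RD).** Per locus, the minimal pairing of the two
allele pairs,

    d_i(A, B) = min(|A_i − B_i| + |a_i − b_i|, |A_i − b_i| + |a_i − B_i|),

and `RD(A, B) = (1/k) Σ_i d_i`. Because microsatellites mutate by repeat
steps, length differences accumulate with divergence time: RD carries
phylogenetic signal and separates anciently diverged gene pools.

**Shared-allele distance (SAD).** `SAD = 1 − P_SA` with
`P_SA = (1/2n_u) Σ_u S_u`, where `S_u ∈ {0, 1, 2}` counts alleles shared
identical-in-state by min-count (multiset) matching — a homozygote and a
heterozygote carrying one common allele share 1, not 2 (the standard
Chakraborty–Jin convention). SAD sees only identity, not divergence: it is
the recent-gene-flow lens. For diploid data SAD equals the scaled L1
distance between per-locus allele-count vectors,
`(1/4n_u) Σ_u ‖c_A − c_B‖₁`, which the tests exploit as an independent
closed form.

Both distances are metrics (per-locus optimal matching is an optimal
transport distance; the L1 form is a norm); the test suite verifies the
axioms exhaustively on a small genotype alphabet.

**Missing data.** A locus missing in either individual of a pair is dropped
from numerator and denominator (pairwise deletion, per metric). A pair with
no jointly typed locus has no distance and is reported as an error, never
silently zeroed. Nothing is imputed anywhere in the package. Under
missingness-at-random, pairwise deletion leaves the expectation of both
ratios unchanged; under informative missingness it does not, and the caller
is expected to filter loci first.

**Numerics.** Both distances are ratios of small integers. IEEE division
rounds equal rationals to identical doubles, so thresholding and tie
grouping on the float values is exact; tests compare at 1e-12.

## Networks and percolation

A threshold graph keeps the link {i, j} iff `D(i, j) ≤ thr` (inclusive).
Removing links in decreasing distance order, the network remains one giant
component until a critical distance — the percolation distance Dp — below
which it collapses into clusters. Fragmentation is tracked by the mean
cluster size excluding the largest,

    ⟨S⟩* = (1/N) Σ_{s ≠ largest} s² n_s,

with `n_s` the number of clusters of size s and N the number of nodes
outside the largest cluster (⟨S⟩* := 0 for a connected graph, the standard
finite-size-percolation convention that the susceptibility vanishes when
all mass sits in the giant component). Distances tie heavily (they are
ratios of small integers), so equal-weight links are added and removed
atomically and thresholds run over distinct realized values only. When
several components tie for largest, exactly one is excluded; the result
depends only on the size multiset, so the choice is immaterial.

Two readings of Dp are computed and reported:

* `dp` — the threshold at the global maximum of ⟨S⟩* (ties broken toward
  the larger threshold), the standard peak-susceptibility locator;
* `dp_last_connected` — the smallest threshold at which the graph is still
  a single component, i.e. the collapse point ("just before the network
  collapses").

On continuous distance data the two nearly coincide. On SAD values
discretized to multiples of `1/(2k)` (19 levels for k = 9) the peak
locator is knife-edge — a single tie-step moves it across the entire
hybrid-bridge scale — so procedures that need a *screening* threshold
anchor on the collapse point instead (below).

## Topology statistics

Per node: degree `k_i`; clustering coefficient
`C_i = 2E_i / (k_i(k_i − 1))` with `C_i := 0` for `k_i < 2` (the formula's
denominator vanishes; zero is the standard convention); betweenness
`bc(i) = Σ_{s≠t≠i} σ_st(i)/σ_st` over unordered reachable pairs,
unnormalized (a normalized variant sits behind a flag). Global: the degree
distribution P(k) and `⟨CC⟩`, the plain mean of `C_i` over all nodes.
Computation is delegated to networkx; the acceptance suite checks it
against brute-force path enumeration on small random graphs.

## Rewiring null model

The species clusters are internally far more interconnected than chance
expects. The null keeps the degree sequence and randomizes everything
else: each replicate applies at least `10·|E|` successful double-edge swaps
((u,v),(x,y) → (u,x),(v,y); swaps creating self-loops or multi-edges are
rejected) and records `⟨CC⟩`; the observed value is expressed as a z-score
against the replicate distribution. 10,000 replicates are the default
experiment size. An Erdős–Rényi `G(n, m)` resampling null (degrees free) is
available as `method="gnm"`; degree-preserving rewiring is the default
because it is the conservative choice. Graphs with no legal swap (stars)
yield zero null variance; the result is flagged degenerate and the z-score
left undefined.

The replicate loop runs as a numba kernel over bitset adjacency rows
(triangle counts by popcounted row intersections), which keeps 10,000
replicates on near-clique percolation-threshold graphs to tens of seconds;
a pure-Python fallback with identical semantics is used when numba is
absent. All stochastic operations take a single integer seed and are
reproducible bit-for-bit.

## Intermediate individuals and hybrid screening

`find_intermediates` returns every node incident to at least one link
joining the two species labels, annotated with same/other-species neighbor
counts and betweenness, plus an articulation check (does removing the set
sever all species-to-species paths?). Note the check is informative only
when hybrid-labeled nodes provide label-free detours: any component
containing both natural species necessarily contains an inter-species edge,
so removing all flagged endpoints always separates pure two-species graphs.

`detect_putative_hybrids` is the canonical screening protocol: compute the
SAD percolation profile, take the collapse point, and screen at the largest
value of the standard SAD threshold ladder (0.5, 0.39, 0.33, 0.28) at or
below it. Rationale: above the collapse point the network is one piece and
every individual trivially connects to everything; at the largest ladder
rung under it, rare high-sharing links between pure individuals have
dropped out while hybrid bridges — an F1 shares at least half its alleles
with each parent, so SAD ≤ 0.5 — persist. The 0.5 rung is exactly the F1
half-genome level, which is what makes the ladder informative rather than
arbitrary; anchoring is non-strict so that a collapse point landing
exactly on a rung still screens at that rung.

## Hybrid and backcross simulation

An F1 draws, at every locus, one allele uniformly from a *F. spiralis*
parent's pair and one from a *F. vesiculosus* parent's pair. A backcross
replaces one natural parent by an F1. By default one parent pair is fixed
per hybrid (a true cross); `parent_mode="per-locus"` redraws parents at
every locus, the other defensible reading of a random-fusion scheme. Allele
draws from a pair are uniform (1/2 each). A missing parent locus produces a
missing hybrid locus. Every drawn allele is logged with its source parent,
and `verify_parent_provenance` replays the log against the parents' actual
genotypes. Parents are drawn from sympatric locations, excluding the
natural putative hybrids themselves (to avoid compounding backcrossing into
the simulated cross).

Scenario assembly mirrors the four-dataset design: remove the n natural
putative hybrids, insert n simulated hybrids of one class (F1, BC_spi,
BC_ves, or the mixed 9 + 8 split), keep everything else untouched, so the
total sample size is preserved.

## The synthetic panel

The empirical dataset the method was developed on is not deposited, so the
generator produces panels with the same statistical structure:

| parameter | default | meaning |
|---|---|---|
| `n_per_species` | 286 | 572 individuals total, two species |
| `n_loci` | 9 | microsatellite panel size |
| `repeat_unit` | 2 bp | dinucleotide repeats |
| `divergence_steps` | 8 | repeat steps between each species mode and the ancestral mode |
| `shared_poly_fraction` | 0.1 | probability an allele is drawn from the shared ancestral pool |
| `step_p` | 0.65 | modal-allele mass of the per-pool step ladder |
| `max_steps` | 4 | ladder truncation (9 alleles per pool) |
| `region_shift_steps` | 3 | max regional displacement of a species mode, in repeat steps |
| regions | 6 | 4 sympatric (weight 1) + 2 allopatric (weight 2.5, one per species) |
| `missing_rate` | 0.0 | per-locus missing-genotype probability |

Each allele is drawn from a symmetric truncated-geometric ladder of repeat
steps around a pool mode (`P(step) ∝ r^|step|`, `r = (1−p)/(1+p)`, so the
modal allele has untruncated probability `step_p`); the pool is the shared
ancestral one with probability `shared_poly_fraction`, otherwise the
species pool displaced by ± `divergence_steps`, plus a fixed per-region
shift of up to ± `region_shift_steps`. The regional shifts create the
strong within-species phylogeographic structure (distinct northern/southern
clusters, large allopatric refugial samples — hence the allopatric region
weights) that real range-wide seaweed panels show. These values were fixed
by calibrating the generated distance geometry against the published
scales — within-region SAD well below between-region SAD, the SAD network
collapsing above the F1 half-genome level 0.5 and fragmenting regionally
rather than in one step, RD separating species cleanly — before any
recovery experiment was scored.

What the generator does *not* emulate: coalescent genealogies and linkage,
homoplasy constraints on allele size ranges, selection or hybrid fitness,
isolation-by-distance within regions, genotyping error. Passing recovery
tests therefore show the *method* behaves as designed on data with the
assumed structure; they are not an empirical error rate for field data.

## Experiment sizes

Heavy experiments are run at sizes chosen to keep the whole suite
single-CPU friendly: the species-separation check uses 100 individuals per
species; hybrid recovery uses the full 572-individual panel (17 injected
hybrids, as in the four-scenario design); the 10,000-replicate rewired null
runs on the 50-per-species two-cluster RD network at its percolation
distance (≈2,500 links), where the z-score is in the hundreds — the
contrast being scale-free, larger panels only inflate it.

## Known limitations

* The SAD scale has `2k + 1` levels; with few loci, thresholds and the
  ⟨S⟩*-peak Dp are coarse. Report both Dp readings and inspect the profile.
* `find_intermediates` flags *both* endpoints of every inter-species link,
  so each true hybrid typically drags one or two natural neighbors (its
  parents' lookalikes) into the putative set — precision is bounded by
  design, which matches the screening (not classifying) intent.
* Backcrosses are genuinely hard to see: BC individuals share ~3/4 of
  their genome with the recurrent species and attach inside its cluster at
  screening thresholds. Their near-zero network recall is a property of
  the method, reproduced deliberately.
* With heavy non-random missingness, pairwise deletion biases both
  distances; no correction is attempted.
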