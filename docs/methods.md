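# Methods

## The model

Highly homogeneous alpha-satellite HOR arrays are treated as single
chromosome lineages evolving under three forces, applied in a fixed
order within each generation of the forward simulator:

1. **Sporadic mutation.** Per copy, Poisson(μ·L) substitutions at
   uniform positions (L = unit length). Default μ = 2×10⁻⁵ /bp/copy/
   generation, chosen so that over the default 100 generations copies
   accumulate divergence in the 0.2–0.5% band observed between cloned
   repeats of a single homogeneous locus.
2. **Gene conversion.** Poisson(`conv_rate`) events per array; a
   uniformly chosen acceptor receives the homologous tract (geometric
   length, mean `conv_tract_mean` = 60 bp) of a donor within
   ±`xo_offset_max` copies. Copy-number neutral. Because the donor
   haplotype lands on a foreign background, conversion *diversifies*
   the acceptor's domain — a property verified by the tract-detection
   tests rather than assumed.
3. **Unequal crossover.** Poisson(`xo_rate`) attempts between copy i
   and copy i+d (d ≤ `xo_offset_max` = 4). The attempt succeeds only if
   full-unit identity(i, i+d) ≥ `xo_identity_min` (default 0.98):
   mitotic exchange requires misaligned pairing of near-identical
   repeats in close linear vicinity, and this gate is what lets diverged
   barriers freeze a boundary in place. On success one reciprocal
   product (expansion or contraction by exactly d, fair coin) replaces
   the array — the bookkeeping follows a single transmitted chromatid.
   Products that would leave `copy_bounds` are rejected and logged, so
   an accepted crossover always changes copy number by exactly ±d and
   the event log remains replayable; replay must reproduce the final
   array bit-exactly and is asserted over random parameterisations.

Indels are not simulated by default; observed shared variants in these
arrays are overwhelmingly substitutions plus rare deletions, and the
alignment layer handles deletions as `-` states in consensus
coordinates.

## Inference pipeline: numerical choices

**Monomer consensus self-derivation.** The monomer period is the lag in
[150, 200] maximising base-wise autocorrelation identity; the consensus
is the column majority over the implied frames. No external monomer
sequence is ever required.

**Monomer tiling.** Greedy left-to-right placement of the consensus at
the best-identity start within ±15 bp of the expected next start, ties
to the smaller start, acceptance floor 0.60 identity. Placement is
ungapped: on substitution-dominated arrays (the regime this package
targets, and the simulator's default) gapped placement changes nothing;
arrays with large interruptions would leave unassigned intervals, which
are reported and exactly complement the calls.

**HOR period.** k maximises mean monomer identity at lag k over lags
2..30. A flat profile (max − median < 0.02) is a hard error — a pure
monomeric array has no higher-order structure. Among lags within 0.005
of the maximum the smallest wins, so the fundamental period beats its
multiples.

**Phasing.** Restriction-site anchoring places unit starts at the
monomer containing the site's first base and errors out (suggesting
max-homogeneity anchoring) when fewer than half the candidate units
contain the site. Max-homogeneity anchoring maximises mean pairwise
unit identity. Note a structural fact: mean pairwise unit identity is
invariant to the cut phase on a periodic array (every phase compares
the same monomer pairs), so for exactly periodic inputs all offsets tie
and the deterministic tie-break (offset 0) applies; a genuine phase
preference exists only through a site anchor or edge effects. The tests
therefore check phase *consistency* (deterministic tie-break; exact
unit-boundary preservation under rotation for site anchoring).

**Alignment.** Each copy is globally aligned to the consensus
(match +1, mismatch −1, gap open −4, gap extend −1 — configuration
values, since the original figure alignments' program settings are not
recoverable) and projected onto consensus columns; copy bases opposite
consensus gaps are kept as insertion records so the coordinate system
never shifts. The consensus is re-estimated once from the projected
matrix and copies realigned if it changed. Equal-length copies at ≥90%
ungapped identity skip the dynamic program: under the default scoring
an affine-gap alignment of equal-length sequences cannot beat the
ungapped one at that identity, and the shortcut keeps the
100-replicate validation suites fast. Copies containing `N` are flagged
and excluded from variant calling, never silently dropped.

**DVN classification.** A variant is a (copy, column) state differing
from the column consensus (majority, ties A<C<G<T<`-`). Variants
sharing column *and* state across ≥ 2 copies form a DVN group; the
headline statistic is `dvn_columns`, the number of distinct positions
bearing at least one DVN, since two alternate states can share one
position. The sporadic rate divides singleton variants by all aligned
cells; per-copy rates are also emitted because the average hides
heterogeneity.

**Segmentation.** Copies are reduced to binary carrier vectors over DVN
groups; all-zero copies (real in young arrays) have Jaccard similarity
0 to everything and end up unassigned rather than forced into a domain.
Adjacency-constrained agglomerative merging (merge the adjacent segment
pair with the highest mean inter-segment Jaccard; stop below
τ = 0.2) yields domains (≥ 2 copies; defining DVNs = groups carried by
≥ half the members). Barrier detection then examines inter-domain runs
(unassigned copies and domains of ≤ 5 copies): a run with mean Jaccard
< β = 0.05 to both flanking major domains is a barrier. One polarity
caveat shapes both the method and the generator: a variant carried by
more than half the copies *becomes* the column consensus, so a domain
covering most of the array is visible only through its subdomain
structure; the generator therefore caps planted carrier counts below
half the core, which is also the realistic regime (observed DVN counts
per domain far exceed what full-penetrance carriage could produce).

**Conversion tracts.** For a copy in domain D, maximal runs of ≥ k_min
= 3 consecutive donor-domain defining DVN positions (in column order)
where the copy carries the donor state and not D's state. Planted
5-DVN tracts are recovered with sensitivity ≥ 0.98 and zero false
discoveries at defaults.

**Duplicate pairs.** Adjacent copies at ≥ 99.5% column identity,
annotated with DVNs private to exactly that pair. The threshold sits
between the background adjacent-copy identity at realistic divergence
(~99%) and the near-perfect identity of a freshly duplicated pair.

**Intermingling index.** Raw statistic: fraction of repeats whose
nearest non-self neighbour in haplotype Hamming distance belongs to the
other set, co-minimal neighbours contributing fractionally (a
deterministic tie rule). Normalised by the random-label expectation
(|B|/(N−1) for a member of A); one-sided p-value by label permutation
with a fixed seed. Calibration is verified: random bipartitions of a
pooled set average 1.0 (a single 40-copy draw has sd ≈ 0.16, so the
calibration check averages 30 draws), fully separated clusters give
raw 0, and two copies of the same set give an index well above 1
(every repeat's nearest neighbour is its twin in the other set).

## The synthetic data and what passing tests show

The generator emulates: tandem k-monomer HOR arrays (171-bp monomers);
domains defined by DVNs planted as contiguous carrier runs (penetrance
0.3–0.9 of the domain, half the runs terminating at a domain edge —
homogenisation runs cannot cross the barrier); a diverged barrier block
with its own DVNs; a bit-identical adjacent duplicate pair planted as
the youngest event; sporadic noise at 0.2–0.5%; divergent flanking
units and partial edge units; a restriction site once per unit
(scrubbed elsewhere, including across unit junctions); intact CENP-B
boxes in alternating monomers; and PCR-clone sampling of a sub-window
with duplicate clones and no positional labels.

The archetypal array uses 30 + 5 + 20 copies of an 11-monomer unit
(1881 bp; real D1Z5 units are 1866 bp because genuine monomers average
slightly under 171 bp — the 171-bp idealisation is deliberate and only
shifts absolute lengths by <1%). It does **not** emulate: indels and
retrotransposon interruptions, strand mixtures, sequencing error
profiles, or CENP-A chromatin placement. Passing tests therefore show
the inference machinery is correct and calibrated on
substitution-dominated, uninterrupted homogeneous cores — the regime
the method targets — not that it is robust to assembly artefacts or
heavily rearranged pericentromere.

Problem sizes in the validation suites (55-copy archetype; 40-copy
two-domain arrays over 100 replicates; 50 replicates per mutation-rate
point; 20 replicate simulations for the crossover/conversion regime
checks; 10 separation time points) are the package's chosen study
conditions: large enough that every recovery statistic is stable to the
third seed we tried, small enough to re-run the whole suite in seconds.

## Known limitations

- Monomer calls are fixed-length; arrays whose monomers vary by more
  than the ±15 bp jitter between neighbours would fragment the tiling.
- Segmentation assigns no confidence to domain boundaries; the barrier
  test is a threshold rule, not a significance test.
- The intermingling index formalises a qualitative clustering
  observation; its normalisation assumes exchangeability within sets.
- Unordered clone sets cannot be segmented into domains (positions are
  unknown by construction); only clustering-based comparison applies,
  mirroring the experimental limitation of PCR-cloned repeats.
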