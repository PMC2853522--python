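# alphadom

Analysis and forward-time simulation of highly homogeneous human
alpha-satellite higher-order repeat (HOR) arrays.

Human centromeric alpha satellite is organised as tandem arrays of
~171-bp monomers grouped into k-monomer HOR units that repeat at >97%
identity. These arrays evolve concertedly: unequal crossovers between
near-identical, linearly close copies homogenise and expand the array
into *domains*; gene conversion stamps foreign haplotype tracts onto
copies (introducing divergence, not homogeneity); and sporadic point
mutations accumulate at a few tenths of a percent per copy. `alphadom`
reconstructs this structure from sequence alone and ships a simulator of
the underlying evolutionary model so every inference stage can be
validated against planted ground truth.

## What it computes

Given a raw array sequence (FASTA or GenBank) or a set of cloned repeat
sequences:

1. **HOR decomposition** — self-derives the monomer consensus from the
   array's own ~171-bp periodicity, tiles the array with monomer calls,
   infers the HOR period *k* from the monomer lag of maximum identity,
   phases units (anchored on a restriction site such as HindIII
   `AAGCTT`, or on maximum unit homogeneity), and extracts the
   homogeneous core. An in-silico digest cross-checks the unit length.
2. **Consensus-anchored alignment and variant calling** — each copy is
   aligned to the copy-set consensus and projected onto its columns.
   A **Diagnostic Variant Nucleotide (DVN)** is an alternate state
   (including deletions) shared identically by ≥ 2 copies; singletons
   are **sporadic mutations**, reported as a percentage of aligned
   cells. A CENP-B box scan scores each monomer at the motif's 9
   essential positions.
3. **Structure inference** — copies are reduced to binary DVN
   haplotypes; adjacency-constrained agglomerative merging on Jaccard
   similarity segments the copy order into homogenisation domains;
   short runs alien to both flanking domains are labelled barriers;
   adjacent near-identical copies are reported as fresh
   unequal-crossover duplicate pairs; runs of foreign-domain DVNs on a
   copy become conversion tracts with their donor domain.
4. **Set comparison** — two repeat sets (homologues, or CENP-A
   chromatin-associated vs bulk repeats) are pooled into one consensus
   frame; DVNs are classified shared vs private, co-clustered
   (average-linkage on haplotype Hamming distance, newick output), and
   scored with a permutation-calibrated nearest-neighbour
   **intermingling index** (1.0 = as mixed as random labels, 0 = fully
   separated).
5. **Simulation** (`alphadom.sim`) — forward-time evolution under
   sporadic mutation, gene conversion, and similarity-gated unequal
   crossover, with a bit-exact replayable event log; plus
   planted-structure builders (two-domain arrays, conversion tracts,
   an archetypal 55-copy array with a 30/5/20 domain/barrier split) and
   PCR-clone sampling with duplicate clones.

## Worked example

Analyse a simulated archetypal array end to end:

```python
from alphadom import archetype_array, evaluation

result = evaluation.archetype_analysis(seed=0)
print(result["n_core_units"], result["k"], result["hor_length"])
# 55 11 1881
print(result["dvn_columns"], result["domains"], result["barriers"])
# 201 [(0, 29), (35, 54)] [(30, 34)]
print(result["duplicate_pairs"], round(result["sporadic_rate_percent"], 2))
# [(31, 32)] 0.42
```

Reading: the array's homogeneous core contains 55 complete HOR units of
11 monomers (1881 bp); 201 consensus positions carry DVNs; the copy
order splits into two homogenisation domains (copies 0–29 and 35–54)
separated by a 5-copy barrier whose adjacent copies 31 and 32 are an
unequal-crossover duplicate pair; sporadic mutations run at ~0.4% of
aligned cells. Every one of these numbers matches the structure the
generator planted.

The same analysis is available from the shell:

```bash
alphadom simulate --seed 5 --n0 12 --unit-len 300 --generations 50 --out sim_out
alphadom variants sim_out/array.fasta --out var_out
alphadom run --config run.toml        # full decompose→variants→segment→events
```

To analyse the deposited D1Z5 BAC record (BX248407), download its
GenBank flat file to `data/BX248407.gb` (e.g. via NCBI EFetch); the
test-suite then additionally verifies the published properties of that
record (141,084 bp of alphoid DNA, 55-copy core, k = 11, 1.9-kb HindIII
fragments, 281 DVN positions). No network access is needed otherwise.

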