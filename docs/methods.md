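# Methods

## The system being modelled

An ordered gRNA array is a chain of *k* expression units cloned into one
plasmid. Each unit is produced by polymerase cycling assembly (PCA): a
double-stranded U6 promoter fragment and a double-stranded
scaffold/terminator fragment are bridged by a single-stranded spacer
oligo carrying homology arms to both, and the joined molecule is
amplified by a position-specific primer pair. The primers add Type IIS
(BsaI) tails; in the Golden Gate pot BsaI cuts outside its recognition
site and exposes a 4-nt 5' overhang at each unit end. Because each
junction's overhang is unique within the set, ligation can only produce
the designed unit order, closing the chain onto a lacZ-dropout
destination vector.

## Sequence geometry and defaults

One amplified unit, top strand:

```
TT GGTCTC A <left-oh>  U6(250)  spacer(20)  scaffold(137)  <right-oh>' T GAGACC AA
\------- 13-nt tail -------/                              \------- 13-nt tail -------/
```

BsaI geometry as modelled: recognition `GGTCTC`, top-strand cut 1 nt
downstream, bottom-strand cut 5 nt downstream, i.e. a 4-nt 5' overhang.
The tail is a 2-nt pad (efficient digestion near ends), the recognition
site, one spacer base, and the junction overhang: 13 nt per side.

Defaults (all configurable on `ReferenceSet`):

| parameter | default | why |
|---|---|---|
| U6 length | 250 nt | realistic human U6 promoter scale |
| scaffold length | 137 nt | scaffold + terminator scale |
| up/down homology arms | 20 / 19 nt | a 20-nt spacer gives a 59-nt oligo |
| fwd/rev primer annealing | 20 / 20 nt | ordinary PCR primer footprint |
| unit amplicon | 13+250+20+137+13 = **433 bp** | the gel-verifiable unit size |
| ligated unit period | 4+250+20+137 = **411 nt** | what read binning divides by |

The bundled reference sequences are deterministic synthetic stand-ins
(rejection-sampled free of BsaI and BsmBI sites on both strands; the
real promoter/scaffold/vector sequences are lab-specific and can be
supplied as FASTA). Spacer validation additionally rejects any spacer
whose *assembled oligo context* (arms included) contains a BsaI or BsmBI
site, since a junction-spanning site would corrupt the Golden Gate
reaction or the BsmBI screening digest.

Coordinates are 0-based half-open throughout; plasmids are linear
strings with a declared origin and are compared under lexicographically
minimal rotation. Input sequences are case-insensitive and U→T
normalized.

## Junction overhang sets

A usable set has pairwise-distinct, non-palindromic 4-mers with no
reverse-complement pair (any of these would let a junction ligate in the
wrong place or to itself). Given a ligation-fidelity matrix *m* (entry
(i,j): propensity of overhang i ligating to the reverse complement of
overhang j), the expected correct-assembly fraction of a set is the
product over junctions of `m(i,i) / Σ_j m(i,j)` with j restricted to the
competing set. `select_overhangs` greedily adds the candidate that
maximizes this running fidelity (lexicographic tie-break, so output is
reproducible); greedy selection carries no optimality guarantee, and for
small label lists the test suite compares it against the exhaustive
optimum. k = 0 is rejected rather than defined. The bundled default set
(21 junctions → arrays of up to 20 units) is generated from a synthetic
matrix — diagonal 1000, off-diagonal decaying as 10^(3−Hamming) — which
merely encodes "near-identical overhangs cross-react more", the property
the selection needs; real NEB fidelity CSVs drop in via
`FidelityMatrix.from_csv`.

Junction assignment is k-independent at the vector: slot *p* uses
junction *p−1* on its left, and the set's **last** element is always the
terminal (unit_k → vector) junction, so the destination vector's two
overhangs never depend on array size.

## Assembly simulation

Digestion finds all BsaI sites on both strands (circular sequences may
wrap the origin), derives the overhang spans from the cut geometry, and
errors when cut windows sit closer than 10 nt (ambiguous doubly-cut
overhang). Fragments record each sticky end as the top-strand 4-mer of
the junction; base count is conserved when each junction is counted
once. Perfect ligation requires the overhang multiset to form a unique
chain from the vector backbone back to itself and is invariant to
fragment input order.

Stochastic ligation is a chain-extension model: from the backbone's free
right end, each step recruits one of the remaining fragments (or closes
the circle onto the backbone's left end) with probability proportional
to the fidelity-matrix entry for that junction. No re-cutting or
kinetics are modelled; the model is meant to reproduce *order errors and
truncations*, which is what read-length binning observes downstream.
Truncated, non-circularized chains count as products at their unit
count. One explicit integer seed drives the RNG; no global state.

Library diversity is the exact integer product of per-position pool
sizes (ordered arrays: position identity matters).

## Read QC

- **Insert extraction**: both the read and its reverse complement are
  searched for the two backbone flanks with edlib infix alignment
  (default edit budget 20% of flank length, flanks ≥ 15 nt). Since
  whole-plasmid nanopore reads start at an arbitrary origin, the doubled
  read is searched by default and the first best occurrence kept.
- **Binning**: nearest multiple of the ligated unit period (411 nt by
  default, derived from the design — the primer tails are absent from
  the ligated insert), with half-unit tolerance, 1 ≤ bin ≤ k.
- **Segmentation**: global alignment of the insert to the designed
  insert for its bin; designed unit boundaries are projected through the
  alignment cigar. Identity < 60% flags a segmentation failure.
- **Identification**: the observed spacer (projected spacer interval) is
  scored against every pool member with normalized edit similarity
  `100·(1 − d/max(len))`; best id wins if it clears the threshold
  (default 80) and beats the runner-up, exact ties are reported
  `ambiguous` rather than first-come, sub-threshold is `unassigned`.
  The threshold and scale are this package's decisions; a pure-python
  Levenshtein oracle in the tests pins the scoring.
- **Mutation classification**: per-base substitutions and per-run
  indels from a global alignment against the expected unit, labelled by
  the expected-coordinate region; insertions at a region boundary attach
  to the left region. Edits in the primer footprints (tails plus
  annealing stretches) are recorded but non-consequential; only
  U6/spacer/scaffold edits count toward the per-unit mutation rate,
  whose complement is the screening model's p(G).
- **Per-clone consensus**: raw long-read noise (percent-scale) swamps
  per-unit mutation rates of a few percent if mutations are called on
  single reads, so clone-level mutation profiling follows the practice
  of sequencing clones individually: reads of one clone are projected
  onto expected coordinates and majority-voted per column (ties resolve
  to the expected base). At ~12 reads/clone and 5% per-base error the
  consensus residual is far below the rates being measured. FASTQ
  quality strings are read but unused (edit-distance model only).

## Synthetic data

`simreads` generates what the QC stack must survive: clone populations
with a stated full-length fraction (truncations uniform over 1..k−1 by
default), one consequential edit per unit with stated probability
(uniform over the U6+spacer+scaffold span, uniformly a substitution,
insertion or deletion), optional per-position guide pools, and reads
that are random rotations of the circular plasmid on either strand with
i.i.d. per-base substitution/insertion/deletion noise. Defaults mirror
the characterized system: k = 10, 81% full length, 7.5% per-unit
consequential rate. Everything is byte-deterministic under a fixed seed.

What the generator does **not** emulate: homopolymer-biased ONT error
profiles, chimeric reads, quality-score structure, non-prefix
truncations, or correlated (oligo-batch) mutation clustering. Passing
tests therefore show the pipeline's logic is correct under controlled
conditions, not that real-run accuracy will match these numbers.

## Problem sizes used in the checks

The end-to-end recovery checks use 10-unit designs, populations of
1,000 clones with one read each (matching the working assumption that
each bulk read stems from an individual clone) at 5% total per-base read
error for full-length-fraction and identification accuracy, and 84
clones × 12 reads for consensus mutation-rate recovery; recovery is
judged against 95% binomial intervals at the realized denominator. The
round-trip identity check covers every k from 1 to 20 plus extra random
draws with shuffled fragment order.

## Known limitations

- Exact-match PCA model: homology arms must match perfectly; no
  mispriming or arm-internal annealing is modelled.
- No thermodynamic/kinetic ligation modelling, enzyme star activity, or
  transformation-efficiency effects; the stochastic ligation model's
  fidelity matrix is an input, not a prediction.
- Greedy overhang selection can be suboptimal; supply a curated set for
  production designs if one exists.
- Truncated assemblies are modelled as prefix chains closed onto the
  vector; real truncations can be internal deletions.
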