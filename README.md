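# guidearray

Design, in-silico assembly and nanopore QC of **ordered CRISPR gRNA
arrays** built by polymerase cycling assembly (PCA) and Type IIS (Golden
Gate) cloning.

Multiplexed CRISPR experiments often need many guides delivered from one
plasmid. A cheap, one-day route is to build each gRNA expression unit
(U6 promoter + 20-nt spacer + scaffold/terminator) by PCA from a single
59-nt spacer oligo, amplify it with a *position-specific* primer pair
that adds BsaI tails, and assemble all units plus a lacZ-dropout
destination vector in one Golden Gate pot. The 4-nt overhang exposed by
BsaI at each junction is unique to that junction, so ligation can only
chain the units in the designed order. `guidearray` is a toolkit for
labs running this workflow:

- **designer** — turns a spacer list into the full oligo order sheet
  (one 59-nt bridging oligo per guide, one BsaI-tailed primer pair per
  array slot) and predicts every downstream sequence (433-bp unit
  amplicons, ligated insert, final plasmid).
- **overhangs** — validates junction-overhang sets (no palindromes, no
  reverse-complement pairs) and greedily selects high-fidelity sets from
  a ligation-fidelity matrix (e.g. an NEB fidelity CSV). The bundled
  synthetic default supports arrays of up to 20 units.
- **assembly** — simulates PCA, BsaI digestion (4-nt 5' overhangs) and
  overhang-directed ligation, both deterministic and stochastic
  (fidelity-weighted chain extension), plus exact combinatorial library
  diversity (10 positions x 10-guide pools = 10^10 distinct arrays).
- **readqc** — analyzes whole-plasmid nanopore reads: extracts the array
  insert between backbone flanks (either strand, origin-wrapping reads
  handled), bins insert length into a unit count, segments units,
  identifies each position's gRNA by normalized edit-distance similarity,
  and classifies mutations by region (primer-footprint edits are
  non-consequential; U6/spacer/scaffold edits count).
- **clonestats** — the clone-screening model: with per-unit no-mutation
  probability *p(G)*, full-length probability *p(F)* and *k* units,
  *p(A) = p(G)^k*, *p(C) = p(A)·p(F)*, and screening *n* colonies
  succeeds with *p(U) = 1 − (1 − p(C))^n*; plus the inverse planner.
- **simreads** — synthetic clone populations (controlled full-length
  fraction and per-unit mutation rate) and noisy long reads, so the
  whole stack is testable without any sequencing data.

## Worked example

```bash
guidearray design --spacers spacers.csv --out design/
# designed 10-unit array: 30 oligos -> design
head -4 design/order_sheet.csv
# name,sequence,length,position,role
# g1_oligo,GTGTGATCTTTATGCTTGAGAATCGGGACACTGAGATTTGAAAATCAACCCTTGTCACA,59,1,spacer_oligo
# g2_oligo,GTGTGATCTTTATGCTTGAGTCAGCGTCTACTAGCGTTTGAAAATCAACCCTTGTCACA,59,2,spacer_oligo
# g3_oligo,GTGTGATCTTTATGCTTGAGTCGCAATTCCAATGAAGTTAAAAATCAACCCTTGTCACA,59,3,spacer_oligo
```

Each spacer needs only one 59-nt oligo (20-nt U6 arm + 20-nt spacer +
19-nt scaffold arm); the sheet also lists the 20 position primers. The
simulator then digests and ligates the predicted amplicons and confirms
the one-pot reaction can only produce the designed plasmid:

```bash
guidearray simulate --design design/ --out sim/ --events 200 --seed 1
# assembly: 6314 bp, parts vector-unit1-unit2-unit3-unit4-...-unit10
```

Finally, the screening model at the characterized operating point —
92.5% of units mutation-free, 81% of assemblies full length:

```bash
guidearray screen --p-unit-ok 0.925 --p-full 0.81 --k 10 --n 4
# p_array_ok   0.4586
# p_clone_ok   0.3715
# p_usable     0.8439
```

i.e. picking 4 white colonies gives an 84% chance of at least one
full-length, mutation-free array. `guidearray simreads` and
`guidearray qc` close the loop: simulate noisy whole-plasmid reads from
a clone population, then recover the full-length fraction, per-position
guide identities and mutation rates from them.

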