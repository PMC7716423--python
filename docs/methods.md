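# Methods

This note documents the models, rules and numerical choices behind
`sebarcode`, and what the bundled simulator does and does not emulate.

## Amplicon model

Each well of a plate holds PCR product of the form

    tag(5) + fwd_primer(25) + insert(~600–720) + rc(rev_primer)(26) + rc(tag)(5)

with a well-specific 5 bp tag on both ends and the Folmer COI primer
pair (LCO1490 / HCO2198) as defaults. Single-end 400 bp sequencing reads
each amplicon from both ends; the 3′-end read runs antisense to the
barcode. For a 658 bp insert the two reads share

    2·400 − 658 − (5+25) − (5+26) = 81 bp

of double-covered middle, which is the basis of overlap assembly.
Inserts longer than ~660 bp cannot reach the 80 bp minimum overlap and
inserts of ≤ 650 bp fail the length gate — the pipeline is intentionally
specific to full-length COI-sized markers.

## Filtering

Expected error `E* = Σ 10^(−Qᵢ/10)` is the expected number of wrong
base calls in a read. The removal rule is `E* > 10`, read literally:
a read at exactly 10.0 is kept. Reads containing 'N' are removed first,
so a read failing both checks is counted once, under "ambiguous".
Qualities are Phred-33; scores above 60 are clamped with a warning.

## Assignment

The first 5 bases are compared against every tag and the next 25–26
against each primer, with independent mismatch budgets (default 1 + 1).
IUPAC degeneracy in primers matches any base it denotes; 'N' in a read
matches nothing. A read is assigned only when exactly one (tag, primer)
combination fits; ties are discarded as ambiguous rather than broken,
because with tags at pairwise distance 2 a single sequencing error can
make two tags equally plausible.

Artifact scans run on every read:

* **Chimera** — any occurrence of either primer or its reverse
  complement starting strictly after the tag region (all start positions
  scanned, same mismatch budget as anchored matching). A chimera verdict
  overrides assignment.
* **NuMT** — on an otherwise-assignable read, an occurrence of the
  reverse complement of the *opposite* primer whose position implies an
  insert shorter than 300 bp (the typical size bound for nuclear
  mitochondrial pseudogene co-amplicons). These reads are counted
  separately and excluded from clustering; an opposite-primer hit
  implying an insert ≥ 300 bp is treated as chimeric instead.

## Clustering and consensus

Within each (sample, end) group, reads are dereplicated (count-sorted,
lexicographic tie-break) and clustered abundance-greedily: each sequence
joins the first centroid with identity ≥ 0.98, else founds a cluster.
Identity is positional for equal lengths (reads are primer-anchored and
fixed-length) and semi-global edit-distance based (edlib) otherwise.

A single greedy pass centres clusters on individual observed reads. At
the read depths this pipeline targets per well (tens, not thousands), an
error-rich centroid fragments what is really one sequence family —
typical reads carry 2–3 errors over a 370 bp insert, so member-centroid
distances sit near the 98 % boundary. A deterministic refinement pass
therefore rebuilds each cluster around its majority consensus and
re-assigns every dereplicated sequence to the best-matching consensus
('N' treated as wildcard); fragments re-absorb while genuinely diverged
families (a symbiont at 70 % identity) remain separate. This is a
single-iteration centroid refinement, not an open-ended EM loop, so
determinism is preserved.

Consensus calling is per-column plurality over the cluster's members in
centroid coordinates: the base whose count strictly exceeds all others;
exact ties (and uncovered columns) give 'N'. Cluster retention: the top
cluster needs ≥ 5 reads; the second cluster is additionally kept — as
the symbiont/co-amplicon candidate — when its abundance strictly
exceeds one tenth of the top cluster's and also reaches 5 reads.

## Assembly

The 3′ consensus is reverse-complemented (column counts flipped
accordingly) and every candidate overlap length k from the maximum down
to 80 is scored by ungapped identity with 'N' as wildcard; the
best-scoring k wins, ties toward longer overlap (maximising the
double-covered region). Gapped overlaps are deliberately not considered:
both consensuses derive from the same molecule, so an indel-level
disagreement indicates failure, not alignment slack. Disagreeing overlap
columns are resolved by summing the two ends' column counts and taking
the larger total (tie → 'N') — evidence-symmetric by construction.

Validation gates, in order, each recording the first failure:
both ends present → overlap found → overlap identity ≥ 0.95 →
translation → length > 650 → per-end read support ≥ 10. Translation
uses the invertebrate mitochondrial code (NCBI table 5, configurable),
forward frames only (orientation is fixed by the 5′ primer); codons
containing 'N' translate to 'X' and never count as stops; a stop in the
final complete codon is tolerated ("internal" stops fail). The 10-read
reporting floor exists because blank/control wells accumulate trace
reads through tag hopping and pipetting cross-talk; only assemblies
passing every gate are written to the final FASTA.

## Local taxonomy

Best-hit search ranks references by alignment identity (shorter sequence
aligned semi-globally inside the longer; identity = 1 − d/len(shorter)).
Databases of ≤ 200 entries are aligned exhaustively; larger ones are
prefiltered by shared 8-mers. Identity bands follow common barcoding
practice: ≥ 98 % species-level candidate, 91.4–98 % genus/family level.
E-value statistics are intentionally not computed — they depend on
database size and add nothing to a deterministic identity ranking on
curated references. The end-consistency check classifies the
non-overlapping 5′ and 3′ windows of one assembly separately and
compares lineages at family rank; a disagreement suggests an
inter-sample chimera. Secondary consensuses with ≥ 10 reads are labelled
WOLBACHIA / FUNGI / OTHER from the best hit's lineage when identity
≥ 0.8 over ≥ 100 aligned bases, else UNCLASSIFIED (the 0.8/100 gate is
this package's choice; random 658-mers align far below it).

## Tag design

Greedy code construction over candidates in lexicographic order:
accept a tag iff its Hamming distance to every accepted tag meets the
minimum. For 5 bp tags at distance ≥ 2 this recovers the 4-ary
single-parity code (capacity 256 words, minus full homopolymers), far
above the 96 a plate needs, and the result is independent of the seed
unless shuffled construction is requested. The default filter excludes
only full homopolymer tags and is disabled for 1–2 bp tags, where it
would gut the candidate space; an optional GC band (off by default)
can further constrain candidates.

## Simulator

The generator emulates the data-generating process the pipeline is
built for: per-well coding-frame-clean templates (rejection-sampled
codons, no frame-0 stops), tagged amplicons, 400 bp reads from both
ends, and base qualities decaying linearly Phred 38 → 15 across the
read with substitution errors drawn per base from the written quality
(error ~2.4×10⁻⁴ at the read start to ~3.2×10⁻² at the end, ~2.4
expected errors per read). Defaults describe a realistic plate: 96
wells, 50 reads per end, 5 % chimeric reads (spliced from two templates
with a fresh interior primer copy), 2 % NuMT reads (120–290 bp inserts,
20 % diverged truncated copies of the host template, padded past the
short amplicon with random adapter-like bases), symbionts in 8 % of
wells at 70 % identity and 20 % of target depth, and blank wells
receiving 6 reads per end of another well's template under the blank's
own tag. Everything derives from one seeded generator, so output is
byte-reproducible.

Deliberately not modelled: indels (the clustering/overlap stages are
ungapped by design; substitutions dominate the target platform),
platform-specific error motifs, PCR-cycle amplification dynamics, and
abundance skew between wells. Passing tests therefore demonstrate the
pipeline's logic and its behaviour under substitution noise and the
modelled artifact classes — not robustness to indel-rich or
heavily biased real-world runs.

## Problem sizes used in tests

The acceptance-style tests run a full 96-well plate at 50 reads per end
(~9,600 reads) for parameter recovery, 12-well plates for symbiont
retention, a 96-well shallow plate (3 reads/end) for group cardinality,
10,000 random quality vectors against the expected-error oracle, and
1,000 random instances against the exhaustive overlap oracle; these
sizes keep each property statistically meaningful at desk scale.

## Known limitations

* Uniform within-plate depth in the simulator understates the 1,000×
  read-count spread seen across real wells.
* The NuMT flag relies on the second primer being present on-read;
  NuMTs longer than one read are indistinguishable from targets at
  assignment time (they generally fail the translation gate instead).
* Dual-index (different tag per end) designs and index-hopping
  correction are out of scope; the tag is assumed identical on both
  ends of one amplicon.
* Consensus calling is count-based, not quality-weighted.
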