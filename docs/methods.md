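# Methods

## Problem

Primer-based amplification (e.g. Transplex Whole Transcriptome
Amplification, WTA) leaves artificial *tag sequences* at the ends of
sequencing reads: a fixed universal segment plus, for WTA primers, a
quasi-random tail that appears as trailing N positions.  Pyrosequencing
mis-calls homopolymer run lengths, so the observed tag copies carry
insertions and deletions, not just substitutions; blunt-end ligation
during library preparation additionally concatenates fragments, leaving a
3'-tag + 5'-tag junction inside a single read.  `tagtrim` removes these
artefacts: it matches tags approximately at read ends (and junctions
internally), predicts unknown tags from positional nucleotide frequencies,
splits concatenated reads, and applies post-trim filters.

## Approximate matching

Matching uses the semi-global unit-cost edit distance: the minimum number
of insertions, deletions and substitutions turning the tag into a
substring of the read, with gaps flanking the tag in the read free.  The
distance is computed with Myers' bit-vector formulation of the DP matrix:
column j is encoded as two difference bit-vectors updated in O(1) word
operations, and the running bottom-row score gives, for every read
position j, the distance of the whole tag to the best substring ending at
j.  Python's arbitrary-precision integers are the bit-vectors, so tag
length is unbounded; machine-word blocking would be a constant-factor
optimisation with identical semantics.  The implementation is verified
column-by-column against a naive O(nm) DP matrix and cross-checked against
edlib's infix mode on wildcard-free inputs.

IUPAC ambiguity codes in the tag are expanded into the per-letter match
masks during pattern pre-processing only (Y matches C or T at zero cost,
N matches anything); the per-read cost is unchanged.  Wildcards apply to
the tag side only: an N in a *read* is a low-quality signal, not a
pattern, and matches only a tag N.

### End search

A tag of length m is searched in a window of max{10, 3m/2} bases from its
end (integer floor; 46 bp for the 31-base example tag).  The 3' end is
searched on the reversed window with the reversed tag and coordinates
mapped back.  The scan stops at the first exact (distance 0) match; for
positive distances the best candidate is the minimum distance, ties broken
toward the larger trimmed extent (residual tag bases are worse for
downstream analysis than one extra trimmed base).  Because distance-0 ties
resolve to the *first* zero hit, disabling the early exit provably never
changes the result (tested).  Match start positions are recovered by a
bounded backward pass from the chosen end position, taking the longest
consistent start on ties.  Continuous trimming repeats the end search on
the residue until no match remains; a read consisting only of tag copies
trims to an empty residue and is removed by the length filter (reported
with fate `tag_repeat`).

Mismatch limits may be percentages of the tag length, floored
(10% of 31 → 3).

## Automatic tag detection

Per-position base frequencies at a read end separate three regimes:
a fixed tag position has one base near frequency 1; background (sample)
sequence is near 0.25 each under the assumed uniform base composition
(no G/C-content adjustment is applied); a quasi-random tag position shows
a preferred but not fixed base.  With r the range (max − min) and m̃ the
median of the four frequencies at a position:

* r > 3·m̃  → specific (fixed) position;
* r < m̃ + v → background, with v = 0.05 interpreted as an absolute
  frequency (the allowed variation);
* otherwise → quasi-random.

The predicted tag is the maximal run of non-background positions starting
at the profiled end; specific positions emit their majority base,
quasi-random positions emit N.

Indel noise shifts part of the dataset by a few positions and blurs the
profile, so frequencies are first re-registered via terminal k-mers
(k = 5): k-mers carried by ≥ 10% of reads are ranked by count (ties
lexicographic) and agglomerated by gapless shift alignment with at most
2 shift operations, the shift sign taken relative to the top-ranked k-mer
(±l when both directions tie, e.g. ACACA vs CACAC).  Shifts are then
offset by a = |min l| (5' end) or a = −max l (3' end) so no read shifts
off the profile start, and each read contributes its bases at positions
displaced by its k-mer's adjusted shift; unassigned (and ±l) k-mers
contribute unshifted.  Profiles cover 60 positions by default; positions
supported by fewer than 50 reads are classified background (insufficient
evidence) — both values are package choices, exposed as parameters.
Reads with an N at a position are excluded from that position's
normalisation.

## Splitting

A fragment-to-fragment concatenation shows the junction pattern
tag3·tag5 (one single IUPAC pattern; the N tails stay wildcards) strictly
inside the read.  Junctions are located with the same matcher after end
trimming, greedily selecting non-overlapping candidates by lowest distance
then leftmost end; only the tag3·tag5 orientation is searched (the
ligation model; the reverse order would imply an inverted insert).  A
read with n junctions yields n+1 fragments with ids `parent.1 … parent.n+1`
(unsplit reads keep their id); junction bases are discarded, and fragments
re-enter the filters like ordinary reads.  Exact matching
(`split_max_mm = 0`) is available to suppress false splits.

## Filters and stage order

Per read: 5'-end trimming, 3'-end trimming of the residue, junction
splitting, then per-record filters — length (inclusive bounds), N content
(filtered when strictly above the threshold percentage), tag occurrence
(5'/3'/both/either/none/don't-remove, evaluated on the read's end-match
flags) — and finally dereplication (exact duplicates, first kept) over the
passing records.  Dereplication runs last because duplicates can differ in
their noisy tag copies and only become identical after trimming.  Records
failing a filter are emitted with their original, untrimmed sequence.
The pipeline conserves reads: passing + failing = input + (fragments −
split reads), and re-running it on its own passing output changes nothing.

## Synthetic data

The generator emulates the study conditions: reads are
`noisy(tag5) + insert [+ noisy(tag3)·noisy(tag5) + insert] + noisy(tag3)`,
truncated at a 500 bp read cap.  Defaults: 31/30 bp WTA-style tag pair,
uniform insert lengths of 100–1,000 bp (so many 3' tags are truncated
away, as observed on real pyrosequencing data), 5% per-copy single-indel
rate with 2/3 of indels adjacent to a repeated base (homopolymer
miscalls duplicate or delete a base of the run), 1% per-base substitution
rate in tag copies, 2% concatenation rate, 5% duplicate rate, 0.2%
ambiguous-base rate in inserts.  Inserts are i.i.d. uniform A/C/G/T.
Quasi-random tag positions draw from probabilities (0.45, 0.30, 0.15,
0.10) with the base order rotated per position: WTA primer tails have
preferred, not uniform, bases (mismatch-tolerant annealing), and a
perfectly uniform tail would — correctly — classify as background.
Every read carries a truth record (planted trim coordinates, per-end edit
operations, junction intervals, duplicate flag).

What the generator does *not* emulate: flowgram-level noise and quality
scores, reads truncated mid-tag at the 3' end (truncation lands in the
insert, so the 3'-shift-correction path is exercised by constructed
fixtures rather than by the generator), non-uniform genome composition,
and 16S/amplicon data (on which frequency-based detection is expected to
over-predict).  Passing tests therefore demonstrate the mechanisms, not
performance on any particular real library.

## Problem sizes and numerical choices

Tests use 300–2,000 simulated reads for pipeline properties, 10,000 reads
for the concatenation-rate check, and 20 seeded replicates of 2,000 reads
for tag-recovery reliability; `scripts/acceptance.py` searches dataset
sizes 1,000/2,000/4,000 for the smallest with ≥ 19/20 exact recoveries.
At 1,000 reads the per-position frequency noise (σ ≈ 0.014) sits close to
the background cut for quasi-random positions, so recovery occasionally
misses one tail position; 2,000 reads gives a comfortable margin.  All
randomness flows from explicit integer seeds (numpy `default_rng` /
`SeedSequence`); there are no hidden tolerances — distances, shifts and
classifications are exact integer/rational computations apart from the
frequency thresholds stated above.

## Known limitations

* Detection needs ≥ 1,000 reads to resolve quasi-random tag tails; smaller
  datasets get a warning and should be reviewed via the frequency report.
* Ends dominated by incomplete 3' tags (deep truncation) can defeat
  detection when no terminal k-mer reaches the 10% threshold; the end
  then reports "no conserved end signal".
* Quality-aware trimming is out of scope and recommended downstream
  (upstream quality trimming would truncate the tags themselves).
* The matcher is online (no index); for single-pass tag removal an index
  would not amortise.
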