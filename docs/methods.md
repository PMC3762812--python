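# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `repeatscape`. Coordinates are 0-based half-open
everywhere in memory; 1-based inclusive conventions appear only at format
boundaries (GFF3, Tandem Repeats Finder `.dat`, BLAST tabular).

## Sequence-set statistics

Lengths exclude unresolved residues (N): total length, mean (truncated
toward zero), median, N50 (the largest L such that sequences of length
≥ L contain at least half of the total), shortest/longest, and GC as
(G+C)/(A+C+G+T). Whether N50 should use N-included lengths is a genuine
convention choice; N-excluded lengths are used for consistency with the
other statistics. Every "% of sequence set" denominator in the package is
the non-N total length.

## Pairwise alignment

Local alignment (affine gaps, both strands) and global alignment are
delegated to `Bio.Align.PairwiseAligner`; exact per-column counts —
matches, gap residues on each side, gap openings — are recomputed from
the aligned blocks, because the *sim* metric needs them exactly. The
default nucleotide scoring emulates the Censor normal-mode BLASTN
parameters: match +3, mismatch −4, gap open −5, gap extend −2, where a
gap of length L costs open + L·extend; the minimum reported local score
is 50. Multiple hits per sequence pair come from recursing into the query
segments flanking each best local hit, which guarantees query-disjoint
hits per strand.

Large searches (set vs library, all-vs-all self-alignment, consensus
vs consensus) shell out to NCBI `blastn` with the same scoring (reward 3,
penalty −4, gap 5/2, word size 10, no low-complexity filtering, E ≤
2×10⁻⁵). Tabular hits are rescored in the internal scoring units from
their counts (3·matches − 4·mismatches − 5·openings − 2·gap residues) so
that the 50/100 score thresholds mean the same thing on either engine.
Tabular ingestion necessarily approximates the match count as
round(pident × length / 100); the built-in aligner carries exact counts.
Both engines emit the same `AlignmentHit` contract.

**Global identity** (used for clustering) is 1 − edits/columns on a
minimal-edit-distance global alignment (edlib), with end gaps counted as
columns. This differs in principle from matches/columns under the affine
scoring (the fallback path when edlib is unavailable), but at the
identities where the 0.80 clustering threshold discriminates the two
definitions agree closely, and the edit-distance form is orders of
magnitude faster, which is what makes the clustering stage practical.

## The sim metric and the 80-80-80 standard

The gap-adjusted identity of a hit is

```
sim = match_count / (alignment_length − query_gap_length
                     − subject_gap_length + gap_count)
```

For a gap-free alignment all gap terms vanish and sim reduces to fraction
identity (a property test asserts this). `gap_count` is interpreted as
the number of gap *openings* (BLAST's `gapopen` column), not gap columns;
the formula is ambiguous on this point and openings were chosen because
that is the count the tabular format provides on both ingestion paths.

A hit is a **full-length** element copy when all three clauses hold:

1. its span on the reference (library) element is strictly greater than
   80 bp — the span is measured on the reference, consistent with the
   coverage clause;
2. sim ≥ 0.80;
3. reference span / reference length ≥ 0.80.

Non-redundant annotation greedily accepts hits by descending score (ties:
longer query span, then subject name); a hit overlapping an accepted hit
by more than 50% of its own query span is discarded. The 50% threshold is
a package choice — the underlying rule only says the highest-scoring
annotation wins.

## Tandem repeat detection

Periods of 2–500 bp are considered; mononucleotide runs are excluded
(they are confounded with assembly collapse). The detector has two
phases:

1. **Candidate proposal.** For every lag p, the sequence is compared with
   itself shifted by p (one vectorized pass per lag); windows of 24
   positions where ≥ 75% of positions match propose a candidate array
   region for period p. Overlapping windows are merged, and a candidate
   is skipped when an accepted array with a divisor period already covers
   90% of it (suppressing harmonic re-detection).
2. **Verification.** The candidate window (with one-period margins) is
   aligned to its period consensus (majority base per phase class) by a
   wraparound local dynamic program under the Tandem Repeats Finder
   default convention: match +2, mismatch −7, indel −7 (linear), floor at
   zero. The best-scoring path determines the array boundaries (maximal
   extension is intrinsic to the local DP), the matched fraction, and the
   copy number as consensus columns consumed / period, reported to one
   decimal. Arrays need score ≥ 50 and ≥ 1.8 copies. A consensus that is
   itself periodic is reduced to its primitive period. Windows whose DP
   matrix would exceed ~12M cells are processed in overlapping chunks and
   merged.

This is deliberately not a reimplementation of Tandem Repeats Finder's
probabilistic model; the `.dat` reader provides exact interoperability
with real TRF output, and everything downstream of detection (overlap
filtering, binning, summaries) is the package's own logic.

Overlap filtering is greedy by descending alignment score (ties: longer
array, then leftmost); an array overlapping an accepted one by more than
10% of its own length is discarded. The 10% tolerance is a package
choice. Class bins are micro 2–8 bp (di…octa), mini 9–100 bp (9–30,
31–50, 51–70, 71–100) and satellite > 100 bp (101–200, 201–300, 301–400,
> 400); "variants" counts distinct canonical motifs per bin, where the
canonical motif is the lexicographically smallest string over all cyclic
rotations of the motif and of its reverse complement (so AT/TA collapse,
as do the six AT-rich trinucleotides). Copy-number columns are sums over
loci. AT-richness of an array is A%+T% strictly greater than 60% of its
genomic span.

## De novo family discovery

1. **Seeds.** All-vs-all self-alignment of the set (identity diagonal
   removed). Two tandem-array leak paths are filtered here: same-sequence
   hits whose query and subject spans are separated by less than their
   own span are shifted self-matches of a tandem array (a genuine
   terminal-repeat pair is separated by the element's interior and
   survives); and any seed consensus in which detected tandem arrays
   cover ≥ 60% is a satellite, not an interspersed element, and is
   dropped. Qualifying HSPs (score ≥ 100, span ≥ 80 bp) are
   single-linkage clustered by reciprocal query-interval overlap ≥ 80%;
   clusters with ≥ 3 supporting HSPs yield a majority star consensus
   (members aligned to the longest; per-column majority; ties to the
   reference residue; gap-majority columns dropped; insertions relative
   to the reference do not create columns). A structural pass runs the
   LTR-pair detector over every cluster span regardless of support and
   adds the LTR-bounded span as a seed, so low-copy LTR elements are
   seeded even where consensus support is lacking. The support threshold
   of 3 reflects that a majority consensus needs at least three voters.
2. **Instances.** The seeds are the library of a non-redundant homology
   search against the set; hits surviving the 80-80-80 standard (seed as
   reference) become full-length instances, extracted in seed
   orientation. A 50%-truncated copy fails the 0.8 reference-coverage
   clause by construction.
3. **Clusters.** Greedy centroid clustering at 0.80 global identity:
   instances sorted by length descending (ties by genomic position), each
   joining the first centroid it matches, else founding a new cluster.
   The fixed sort order makes the output deterministic; order
   independence is not promised (greedy centroid clustering never has
   it). An instance shorter than 0.8× the centroid length is skipped
   without alignment (it cannot reach the bound when end gaps count).
4. **Families.** All-vs-all local alignment of the cluster consensi; two
   clusters are linked when a hit satisfies the 80-80-80 standard with
   the *shorter* consensus as the reference (which sequence the coverage
   clause should reference is an open convention; the shorter consensus
   is the permissive, merging-friendly reading). Families are the
   connected components. Family coverage is the sum of base pairs of all
   full-length member sequences over all clusters in the family; the
   representative cluster has the most members (ties: longer consensus).
   Families whose representative consensus passes the nucleotide route
   against a classified library inherit the library name; novel families
   get stable generated names in coverage order.

Why clusters split and families re-merge: copies at ~0.95 identity to
their master are only ~0.90 identical to each other, and after strand
orientation and boundary noise a single family routinely yields 2–3
clusters; the consensus-level merge under the 80-80-80 rule restores the
family.

## Structural features and classification

- **LTR/TIR pair**: the first W and last W bp (W = min(2500, len/3)) are
  locally aligned in both orientations; a repeat ≥ 100 bp at ≥ 80%
  identity (matches/columns) is accepted, direct orientation meaning an
  LTR retrotransposon candidate and inverted a TIR (DNA transposon)
  candidate. Elements shorter than 400 bp are not examined.
- **PPT**: the longest window of ≥ 10 bp with ≥ 90% purines within 30 bp
  interior of the 3' LTR.
- **PBS**: a ≥ 11 bp stretch within 30 bp interior of either LTR matching
  the reverse complement of a tRNA 3' end with at most one mismatch. The
  shipped tRNA fixture is a single synthetic 18-mer with the canonical
  T-loop motif and CCA terminus (`classify.TRNA_3PRIME_18MER`); a real
  tRNA set can be supplied instead.
- **ORFs**: six-frame scan, standard code; an ORF is a maximal stop-free
  codon run of ≥ 100 aa and may begin at the frame start.

Classification precedence is total and never downgrades: (1) a
full-length nucleotide hit to a classified library inherits the full
classification including the family; (2) otherwise a protein-level local
alignment (BLOSUM62, open −11/extend −1) between extracted ORFs and
library-entry ORFs at ≥ 35% identity over ≥ 100 aa assigns the
superfamily (and its implied order/class) but never a family — the
0.35/100 aa thresholds sit safely below family-level homology while
bracketing the 38–59% translated similarities that are typical of
informative cross-superfamily matches; (3) otherwise structural features
assign the order only. Gypsy vs Copia discrimination by internal domain
order is out of scope; superfamily calls come from homology evidence
only.

## The synthetic-data generator

The simulator emulates the statistical structure the analysis assumes:
multi-copy element families diverged from a master, degraded terminal
repeats, optional 5' truncation and nesting, and tandem arrays, on an
i.i.d. background at a target GC (default 0.38, typical of conifer
genomic sequence).

- Masters: LTR elements carry identical terminal repeats, an 18 bp PBS
  adjacent to the 5' LTR interior and a 13 bp polypurine tract adjacent
  to the 3' LTR interior; TIR elements carry reverse-complement termini;
  LINE-like elements a 12 bp poly-A tail.
- Copies: independent per-site substitution to a uniformly chosen
  different base; indels open per site with a geometric length (mean 3),
  insertion or deletion with equal probability. The realized identity is
  computed from the edit script (matches over implied alignment columns),
  so truth rows carry the exact divergence of each copy. Orientation is
  random per copy.
- Placement replaces background windows, so drawn sequence lengths are
  exact and features never overlap; a nested insertion instead lengthens
  the sequence inside a host copy, whose truth interval widens and is
  flagged. Placement fails loudly ("exceeds capacity") when features
  would occupy more than ~70% of a sequence or rejection sampling runs
  out of retries.
- Defaults: family sub_rate 0.05 (per-copy identity ≈ 0.95, comfortably
  above the 0.85 working floor of the structural detectors and the 0.80
  clustering threshold) and 0.05–0.20 is the sensible exploration range
  straddling the 80% family threshold; tandem arrays substitute-only.

What the simulator does **not** emulate — and hence what passing
recovery tests do not show about real data: higher-order background
composition (isochores, gene space), solo-LTR formation, ancient
high-divergence copies (> 20%), segmental duplications, and assembly
artifacts. The benchmark conditions (3 × 200 kbp, K ≤ 5 families with 10
copies each, 20 tandem arrays) are desk-scale by design; the same
operations apply unchanged to arbitrarily large FASTA inputs, where the
blastn engine carries the search cost.

## Numerical and degenerate-input choices

- Ties everywhere are broken deterministically (score, then length, then
  position/name), so all outputs are reproducible for a fixed seed.
- The wraparound DP floors at zero (local semantics); its traceback
  treats a cell that matches no predecessor (possible across the wrap
  seam, where the in-row propagation is evaluated over two turns of the
  circle) as a path start, which can only shorten an array by a few
  columns in pathological cases.
- An all-N record has undefined GC and is an error; empty sets, empty
  libraries and empty FASTA files are errors; an empty hit or annotation
  list flows through every summary as zeros.
- Mean lengths are truncated toward zero, matching the integer-division
  convention of the summary tables the package mirrors.
- Copy numbers are reported to one decimal (fractional copies are
  meaningful for tandem arrays).

## Known limitations

- A truly single-copy LTR element (no self-alignment HSP anywhere) is
  not seeded: the structural pass scans HSP-cluster spans, not a
  genome-wide window. Low-copy (≥ 2) elements are covered.
- m8 ingestion cannot recover exact per-gap lengths; the rescoring
  charges each opening once and each gap residue the extension cost,
  which equals the true affine cost only when gap lengths are known —
  the discrepancy is bounded by the opening cost per extra fragment.
- The tandem detector's candidate proposal needs a locally clean match
  at the exact lag; arrays with dense indels (which the simulator does
  not plant and the `.dat` reader handles via real TRF) may fragment
  into chunks that the same-period merge only partially reunites.
- Star consensus ignores insertions relative to the reference, so a
  shared insertion absent from the centroid is lost from the consensus;
  with substitution-dominated divergence this is immaterial.
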