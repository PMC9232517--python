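# Methods

## Problem and model

Small-RNA libraries contain piRNAs whose sequences match the mitochondrial
genome. Because nuclear genomes carry NUMTs — fragments of mitochondrial DNA
inserted during evolution — a mitochondria-matching sequence may be encoded by
either genome. The package classifies every collapsed sequence by bounded-
mismatch placement against the two genomes independently (NU: nuclear only;
MT: mitochondrial only; NUMT: both; UNMAPPED: neither), identifies piRNAs and
miRNAs by reference-set membership, reconstructs 5′-anchored piRNA families
(a precursor and its 3′-trimmed matures), and reads a communication direction
off each family:

* **retrograde** — precursors exclusively MT, at least one mature NUMT: the
  precursor can only have been transcribed from mtDNA, yet the processed piRNA
  pairs with nuclear DNA;
* **anterograde** — precursors exclusively NU, at least one mature matching
  mtDNA (NUMT or MT);
* **self** — all precursor and mature classes confined to a single genome;
* **unresolved** — any other pattern, or an ineligible family.

Eligibility requires ≥ 3 members, ≥ 1 precursor, ≥ 1 mature, and ≥ 1 member of
class MT or NUMT. Direction proportions are reported over eligible resolved
families, counted once per cohort.

## Sequence mapping

Placement is substitution-only (Hamming distance; no indels), both strands,
with allowance k (default 1 for genomes and the piRNA set, 2 for the miRNA
set). Only the minimal-distance stratum is reported per genome — an exact
placement suppresses imperfect placements on the same genome, but not on the
other genome, so NUMT calling never loses the weaker of two genomes.
Candidates are generated by pigeonhole seeding (split the query into k+1
chunks; any ≤ k placement matches one chunk exactly) and verified by direct
comparison; the test suite proves the output identical to an exhaustive
all-offsets numpy scan on full-size genomes for k ∈ {0, 1, 2}.

The mitochondrial genome is circular: the search text is extended by the first
74 bases (one less than the 75 nt read maximum) so junction-spanning
placements are found, with starts reported modulo the length. Coordinates are
1-based inclusive everywhere except the BED writer (0-based half-open at the
boundary). A hit's `start` is the leftmost window coordinate on the forward
strand for both orientations; 5′-anchor coordinates (`start` on plus,
`start + len − 1` on minus, circular-wrapped) are derived from it where family
clustering needs them. The inclusive span between coordinates a and b is
|a−b|+1, with the wrap-around alternative L−|a−b|+1 also available for the
circular genome.

## Ingest and normalization

Reads are uppercased with U→T; reads containing ambiguity codes or outside
15–75 nt are discarded and tallied (the bounded-mismatch matcher is exact, so
N bases are dropped rather than wildcard-matched). CPM uses the per-sample
total of reads entering the collapse, which makes pre-filter CPM sum to 10⁶
per sample by construction. The retention rule keeps a sequence reaching the
threshold (default 10 CPM, boundary inclusive) in **at least one** sample,
recording per-sample flags so per-sample tallies count only samples where the
sequence passed; the cross-sample union keeps the count matrices rectangular.

## Annotation

Reference-set membership is equal-length Hamming matching (minimal stratum,
all ties kept; ≥ 2 matching piRNA ids sets a "multiple match" flag). Equal
length keeps the mature/precursor distinction sharp — precursor-prefix
relations are handled by the families module, not by the matcher. Categories:
piRNA, miRNA, dual (both sets), other. Dual sequences are counted in the
piRNA columns of the per-sample summary so the category×class cells partition
the mitochondrial totals.

Feature assignment is circular-aware interval intersection against the
annotation (tRNA/rRNA/CDS/D-loop/origin). Orientation is the read strand
relative to the feature's annotated strand; the D-loop is not a transcript, so
its baseline is the forward reference strand. Uncovered positions yield an
"intergenic" record, making per-hit overlap lengths sum to the read length.
Expression attribution divides a sequence's counts equally among its
minimal-stratum mitochondrial hits and, within a hit, proportionally to
overlap length — feature and strand matrices therefore conserve the
mitochondrial read/CPM totals exactly.

## Families

Families are connected components of the exact 5′-prefix relation over
sequences ≥ 20 nt (the lower edge of canonical mature piRNA length;
configurable), by default restricted to members sharing a genomic 5′ anchor
(same genome, contig, strand, 5′-end coordinate among minimal-stratum hits) so
coincidental prefix pairs from unrelated loci do not merge. Singleton
components are not families. The representative is the longest member
(lexicographically smallest on ties). Roles: mature iff the member matches the
piRNA reference set; precursor iff unmatched, longer than every mature member,
and mapped full-length to a genome; anything else is role "none" and excluded
from eligibility counts. Direction inference is a pure function of the
role-class pairs (member order never matters).

## Profiles

* Positional bias matrices cover positions 1–35 (canonical piRNA upper bound),
  sequence-weighted and read-weighted; each position is normalized over the
  sequences long enough to cover it.
* The per-sample summary reports sequences and reads in total, for the
  mitochondria-associated subset, and per category×class cell, plus cohort
  averages and derived percentages (mitochondrial share of total reads;
  category shares of mitochondrial reads).
* Per-kb enrichment is reads per feature type divided by annotated kilobases.
* Sample PCA: rows expressed in < 50% of samples are dropped first (a
  sporadic single-read row is a purely stochastic log-scale spike that can
  dominate the leading component), then log2(CPM+1), row-centering, and SVD of
  the sample×feature matrix. Component signs are fixed by making the
  largest-magnitude loading positive, so output is deterministic.

## Synthetic cohorts

The generator reproduces the study design it emulates: 12 single-end
libraries over {germ, somatic} × {female, male} × {11.5, 12.5, 13.5} days
post-coitum, reads ≤ 75 nt, a 16,299 nt circular mitochondrial genome with
the D-loop pinned at the high-coordinate end, and nuclear contigs carrying
NUMT insertions (the first sourced from inside the D-loop so D-loop families
can exist as NUMTs). Default mixture weights encode the emulated cohort
composition: 0.71% of reads mitochondria-associated; of those, 86.4% mature
piRNAs, 0.9% miRNAs, the rest precursors and background. Within the
non-mitochondrial mass, nuclear piRNA/miRNA singletons and background
fragments mirror a library dominated by nuclear piRNAs. Expression magnitudes
per pool entry are lognormal (σ = 0.6) — a stand-in choice, as no empirical
magnitude distribution is asserted — and per-sample counts are multinomial,
so each library totals exactly its configured depth.

Families are planted by locus construction so the direction label is true by
geometry: retrograde precursors sit in mtDNA extending past a NUMT source
interval (the mature head inside it); anterograde precursors straddle the
NUMT boundary in the nuclear genome; self families avoid NUMT intervals
entirely. Planted family 5′ ends are adenine (the mito-piRNA first-position
hallmark); nuclear piRNA singletons start with T (the canonical 1U bias).
Background reads carry a configurable first-position adenine bias (default
0.8), implemented by mass-splitting the background pool into A-start and
non-A-start subpools. Reads overlapping the D-loop are emitted antisense with
configurable probability (default 1.0, the regime in which every D-loop piRNA
is reverse-orientation); planted entries whose forward mitochondrial image
would fall inside the D-loop are rejected under that regime.

Two design rules keep the truth table exact for a 1-mismatch classifier:
(i) "absent from genome X" placement conditions are enforced up to one
substitution, because a window straddling a NUMT boundary by a single base is
Hamming distance 1 from the other genome; (ii) the truth table recomputes
every genome class with an exhaustive all-offsets scan at the same 1-mismatch
allowance — an oracle independent of the seeded mapper. Non-family pool
sequences are kept prefix-free of everything else in the pool, so planted
membership is the unique ground truth for the clustering stage. Decoy
reference entries and noise reads are verified unmappable (beyond one
substitution) by the same scans.

Determinism: one seed drives named substreams (mito genome, nuclear genome,
family planting, pool construction, read emission), so identical
configurations give byte-identical outputs and adding a consumer never shifts
another stage's draws.

What the generator does **not** emulate: sequencing errors and quality
variation (quality strings are constant), adapter contamination, ping-pong
signatures, isomiR length variants, and realistic NUMT age structure. Passing
tests therefore demonstrate correctness of the classification, clustering and
inference machinery under known truth — not robustness to platform noise.

## Problem sizes and numerical choices

Unit tests run on a compact cohort (4,000 reads/library, 2×20 kb contigs);
recovery tests and the acceptance script use the full design (12 × 100,000
reads, 10 families at 70/20/10 directions). At that depth every planted family
member is comfortably above the retention threshold, and recovery of classes,
membership, roles, directions and the planted proportions is exact. Matrix
round-trips are asserted at 1e-9; CPM normalization at 1e-6 relative; the
recovered background bias within three binomial standard deviations of its
planted value. Degenerate inputs: an all-identical expression matrix yields
zero PCA coordinates and zero explained variance; an empty eligible-family
set is flagged rather than divided by; empty read input is an empty result,
not an error.

## Known limitations

* Directions are constructions over mapping classes; they are hypotheses
  about information flow, not demonstrations of regulation.
* Equal-length reference matching will miss length-variant (isomiR-like)
  database entries by design.
* The NUMT divergence model is uniform per-base substitution; real NUMTs
  mutate heterogeneously and acquire indels, which the Hamming-only mapper
  would miss.
* Differential-expression testing between sample groups is out of scope; the
  profile stage provides PCA and descriptive matrices only.
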