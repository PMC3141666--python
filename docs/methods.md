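# Methods

`mirloop` implements a small-RNA miRNA discovery pipeline of the kind
used for plant stress-response studies: unique sequencing tags are
mapped exactly to a genome, candidate hairpin precursors are delimited
and folded around each mapped locus, and the mature/star duplex is
validated structurally before classification, isomiR summarisation,
target scoring and RT-qPCR quantification.

## The discovery model

A mature miRNA is a 19–24 nt RNA excised from a stem-loop precursor in
which it pairs, with at most a few mismatches, against the miRNA* (star)
strand on the opposite arm, leaving the canonical 2-nt 3' overhang on
both strands of the Dicer duplex.  The pipeline operationalises this as:

1. **Tag collapsing and filtering.** Reads are collapsed into unique
   tags with per-library counts.  Tags with a pooled total count ≤ 2 are
   discarded (`min_total_count = 3`), as are tags outside the 19–24 nt
   window.  Whether the count filter was meant per library or pooled is
   ambiguous in the protocol this follows; the pooled reading is the
   default and a per-library mode is provided
   (`PipelineConfig.per_library_counts`).
2. **Exact mapping.** Tags are matched without mismatches against both
   genome strands (seed-hash index, 19-mer seeds, verified extension).
   Tags mapping nowhere, or to more than `max_genome_hits = 5` loci
   counted over both strands combined, are dropped.
3. **Star location.** Around each hit, `flank_length = 200` nt of
   genomic flank is extracted on each side (truncated and flagged at
   chromosome ends).  The reverse complement of the tag (rc-tag) is
   aligned into the flanks — excluding the tag's own interval — with
   Smith–Waterman (match +1, mismatch −1, gap −2; G:U deliberately not
   rewarded at this step, wobble is handled by the duplex evaluation).
   Placements scoring below 60 % of the perfect rc-tag score
   (`star_min_score_frac`) are rejected; this floor is an artifact
   parameter, not part of the published protocol, and prevents spurious
   precursors in random flanks.  The candidate precursor is the window
   interval spanned by the tag and the rc-tag alignment.
4. **Folding.** The candidate is folded by weighted base-pair
   maximization (Nussinov-style dynamic program; G-C = 3, A-U = 2,
   G-U = 1; `min_loop = 3`; deterministic traceback pairing the 5'-most
   base with its smallest admissible partner).  The optimal score is a
   stem-stability proxy and is **not** comparable to thermodynamic free
   energies; only the pairing pattern of the duplex is consumed
   downstream.  Note that under *weighted* maximization only the optimal
   score — not the pair count of the optimal structure — is guaranteed
   monotone in `min_loop`; the tests assert score monotonicity.
5. **Duplex criteria.** A candidate is accepted when (i) mature and star
   lie entirely within opposite stem arms, outside the terminal loop and
   on opposite sides of its midpoint; (ii) at most
   `max_duplex_mismatches = 4` mature positions are neither Watson-Crick
   nor G:U paired to the star arm (so the 2-nt 3' overhang contributes
   two of the four allowed mismatches); (iii) the duplex contains at
   most `max_asym_bulges = 1` asymmetric bulge of at most
   `max_bulge_size = 2` nt.  The published criterion (iii) reads
   literally as "frequency less than one", which would reject canonical
   plant precursors; the relaxed reading above is the default and the
   strict one is available via `max_asym_bulges = 0`.  G:U counting as a
   pair in (ii) is configurable (`gu_pairs_in_duplex`).
6. **Locus merging.** Candidates at one locus (mature and star both
   sequenced, or end-variants of one arm) are merged into a single
   precursor record listing every observed mature; arm (5p/3p) is
   assigned by position relative to the terminal loop.

Coordinates are 0-based half-open internally and 1-based inclusive in
every report, so a precursor always satisfies
`length = end − start + 1`; BED output is half-open as usual.

## Classification, naming and isomiRs

Mature products are compared against a same-species catalog and a
catalog of other plant species (miRBase-style FASTA).  Priority order:
exact mature at a catalog locus (the candidate precursor matches a
catalog hairpin) → known; a mature from the opposite arm of a known
precursor → antisense-of-known; an identical or ≤ 2-substitution mature
at a new locus → new member of a known family; an exact match to a
non-soybean entry → conserved in other species; a same-precursor
end-shifted variant of an assigned mature → isoform; otherwise a novel
family.  The 2-substitution radius stands in for the unparameterised
BLAST criterion of the original protocol and is configurable.

Novel families are numbered SeqNN in coordinate order of their first
locus; loci connected by a shared mature sequence (or the two arms of
one precursor) form one family, lettered a, b, … by coordinate, with
-5p/-3p suffixes only when both arms of a precursor were observed.

IsomiR groups are summarised as `+n5/CORE/+n3`: the core is the
positional intersection of all end-variants on the precursor and n5/n3
are the largest extensions observed beyond it on either end.

## Target prediction

An ungapped window of miRNA length slides along each transcript; the
miRNA is paired antiparallel to the window and every position classified
as `|` (Watson-Crick), `:` (G:U) or `-` (mismatch).  The site score is
`1.0 × mismatches + 0.5 × wobbles` and sites with score ≤ 3.0 are
reported.  The comparison is ≤ rather than strictly < because printed
reference targets score exactly 3.0 under the stated weights; a
strict-less mode is available (`cutoff_strict_less`).  Gapped sites,
seed-region weighting and target-site accessibility are out of scope.

## RT-qPCR analysis

The stem-loop RT primer is the 44-nt conserved backbone
`GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC` plus six variable 3'
nucleotides complementary to the miRNA 3' terminus; the forward primer
is the mature sequence as DNA and the universal reverse primer
`GTGCAGGGTCCGAGGT` is a backbone substring.  Relative expression uses
2^−ΔΔCt: per replicate, ΔCt = Ct(target) − mean Ct(references)
(arithmetic mean of the reference Cts; the combination rule is not
specified by the protocol this follows, and a geometric-mean-of-RQ
alternative would change nothing at equal reference efficiencies);
ΔΔCt is the difference of mean ΔCt between two conditions and condition
pairs are compared with Welch's two-tailed t-test on the per-replicate
ΔCt values (unpaired, matching a biological-triplicate design), at
α = 0.05 with no multiple-testing correction.  The eight-library design
is summarised with the significance codes `*` (control vs control
between genotypes), `a` (control vs stress, sensitive/susceptible),
`b` (control vs stress, tolerant/resistant) and `1` (stress vs stress
between genotypes).

## Synthetic data: what it emulates and what it does not

The generator plants `n_hairpins` criteria-compliant pre-miRNA hairpins
in a random multi-chromosome genome (defaults: 3 × 20 kb, 20 hairpins,
seed 7 — sizes chosen so a full run folds in seconds while leaving the
flanks overwhelmingly non-complementary).  Each hairpin has a mature of
19–24 nt with a configurable 5'-U bias (default 0.8, matching the
strong uracil start bias of plant miRNAs), a star built by pairing
position i of the mature with position L−3−i of the star (the 2-nt 3'
overhang geometry), 0–2 interior duplex mismatches by default, a random
loop sized so the precursor lands in 55–240 nt, and a 40 % chance of
minus-strand insertion (as a reverse complement).  A fraction of
hairpins is embedded in synthetic gene models to exercise the
CDS/intronic/intergenic context labels.

Two generator details matter for interpretation:

* Every cassette is re-checked with the package's own folder and duplex
  criteria at generation time and resampled until it passes, and mature
  uniqueness in the genome is enforced during placement.  Planted
  hairpins are therefore criteria-compliant *by construction*, which is
  what makes the 100 %-sensitivity recovery test meaningful as a
  self-consistency property — it does not measure sensitivity on real
  genomes, where precursors violate the idealised geometry in many ways
  (long asymmetric stems, multiloops, repeat-derived hairpins).
* An inverted repeat folds on both strands, so a sequenced star arm can
  validate the hairpin on the antisense strand of its own locus —
  mirroring the sense/antisense miRNA pairs seen in real data.
  Background false positives are therefore assessed per locus; the
  sensitivity check still requires the correct strand and mature.

The admissible duplex-mismatch domain is 0–4, but the generator default
is (0, 2): with four mismatches in a 19-nt duplex the best local rc-tag
alignment can fall below the 60 % star-score floor, so four-mismatch
hairpins are legal inputs for the evaluator but are not planted as
guaranteed-recoverable truth.

Libraries: mature tags at 90 expected counts per library, stars at 12,
isomiR end-variants at 9 (values chosen to sit comfortably above the
count filter while keeping the read expansion small; no per-library
totals are prescribed by the protocol this follows and these defaults
are documented as arbitrary), scaled by a per-hairpin per-library
fold-change map.  Counts are exact rounded expectations by default so
tests are deterministic; a multinomial sampling mode draws one
multinomial per library with the expectations as weights.  Background
tags are uniform random 19–24-mers rejected if they occur anywhere in
the genome (guaranteed mapping true-negatives) with counts cycling 1–6
so that some also exercise the low-count filter.  No adapter content,
sequencing error or quality-score realism is simulated.

Ct tables are simulated as Gaussian noise around a base Ct, with one
cycle subtracted per log2 unit of planted up-regulation; reference genes
are flat across conditions.

## Numerical and design choices

* Smith–Waterman ties are broken toward the smallest subject start, then
  the smallest query start; traceback prefers substitution over gaps.
* The folder rejects non-ACGU input and sequences shorter than
  `min_loop + 2`; degenerate inputs (no pairable bases) fold open.
* The terminal loop of a candidate is the hairpin loop (innermost pair)
  overlapping the gap between the mature and star intervals, falling
  back to the innermost loop of the longest stem.
* Duplex bulge detection walks consecutive duplex pairs and compares the
  skipped positions on each side; equal skips (internal loops/mismatch
  pairs) are symmetric and only unequal skips count as asymmetric
  bulges.
* All randomness flows from `numpy.random.default_rng(seed)`; for a
  fixed seed every generator output and every report is byte-identical
  across runs.

## Known limitations

* The folder ignores thermodynamics entirely: stacking, dangles and
  loop-length penalties are absent, so published minimum-free-energy
  values cannot be reproduced and are not attempted.
* Exact-match mapping only; a single sequencing error makes a tag
  unmappable (the upstream protocol accepted this trade-off).
* Catalog classification is sequence-only (no genomic coordinates for
  catalog entries), so "known at a catalog locus" is approximated by
  hairpin-sequence containment.
* Target prediction is ungapped and unweighted by position, unlike
  full psRNATarget-style tools.
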