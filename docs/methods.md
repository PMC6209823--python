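# Methods

## Break capture model

The analysis assumes a linker-mediated capture protocol for double-strand
break ends in non-dividing cells: blunt-polished break ends are ligated to a
*first linker* (5′ amplification-primer segment + unique 3′ segment), the
ligated molecules are shortened by RsaI digestion (GT^AC, blunt), and a
*second linker* is ligated to the RsaI-cut end. A sequenced construct is
therefore

```
[first linker][inserted sequence, optional][genomic fragment: break → first downstream RsaI cut][second linker]
```

read on the strand of the break, in either overall orientation. The break
sits between the last base of the first linker and the first genomic base,
so after linker removal the first mapped base gives the break coordinate
and the four reference bases immediately 5′ of it (on the break strand) give
the *prior 4-mer*. Reads whose post-linker 5′ prefix fails to align are
interpreted as carrying inserted sequence at the break end (MIB).

## Coordinates and conventions

All coordinates are 0-based half-open internally; BED output is 0-based. A
break call's `break_position` is the reference coordinate of the first
captured base on the break strand (alignment start for `+`, alignment right
edge for `-`). The prior 4-mer is `ref[pos-4:pos]` on `+` and the reverse
complement of `ref[pos+1:pos+5]` on `-`, read 5′→3′ toward the break; calls
whose window runs off the chromosome end are dropped and logged.

## Linker processing

* Orientation: the first linker is infix-aligned (edit distance) against the
  read and its reverse complement; the better side wins. Ties, or best
  identity below 50% of the linker, leave the read `undetermined` — an
  undetermined orientation cannot yield a defined break coordinate, so such
  reads never enter downstream counts.
* Intactness: the protocol's guarantee lives entirely in the linker's 3′
  end, so the filter demands an exact occurrence of the final
  `unique3_length` bases (default 10); the primer segment is allowed
  `max_linker_mismatches_5prime` mismatches (default 2), since PCR
  heterogeneity affects it without invalidating the junction. Exactness is
  the strictest reading of "intact" and is configurable.
* Trimming: the longest read suffix matching a prefix of the second linker
  (minimum overlap 6) is removed, then one trailing `GT` — the RsaI
  half-site that terminates every properly cut fragment on either strand
  (the site is palindromic). Trimming the half-site costs two aligned bases
  but never affects the break-proximal end.
* Conservation: every input read receives exactly one fate
  (retained / not-intact / no-linker / undetermined); the partition is
  asserted on every run and written to the filter log.

## Alignment and break calling

A gapless seed-and-extend local aligner over the toy-scale reference:
12-mer seeds index the forward strand; each seeded diagonal is scored
exhaustively (match +1, mismatch −2) and the maximum-scoring segment is
kept. Gapless scoring keeps the query-offset ⇄ insertion semantics exact,
and any exact substring of length ≥ `min_align_length` (default 20) is
found because the seed is shorter than the floor. Defaults
`min_identity = 0.95` admit at most one mismatch per 20-40 bp fragment.
Tie-breaks: among equal-scoring segment starts the later query start wins
(shortest possible left extension); the best-score tier for multimapping is
all hits within 1 point of the top; the multimap representative is the
consensus location with the lexicographically smallest
(chromosome, break position).

The 90% multimap rule is read as counting mapped *locations*: a read is
retained when ≥ 90% of its best-tier locations share one identical prior
4-mer (locations with no defined 4-mer count against the consensus). 9/10
passes, 8/10 fails.

An insertion is the unaligned 5′ prefix of the accepted hit; `query_start
== 0` exactly means mapped-from-first-base. A MIB's prior 4-mer is taken
from the genome at the aligned-portion start, not from inserted bases —
the MIB-association analysis cross-classifies MIB reads by the OR class of
their *genomic* context, which inserted bases do not have.

## Odds-ratio break typing

The genome background counts every overlapping 4-mer window on both
strands (total `2·Σ(L−3)` for clean sequences), making C/D
reverse-complement symmetric, which is the natural choice when breaks are
called on both strands; windows with non-ACGT bases are skipped and
tallied. For each of the 256 4-mers, OR = (A·D)/(C·B) over the anchor
sample's mapped-from-first-base reads. Numerical edge cases: A = 0 gives
OR = 0 (class OR ≤ 1); B = 0 or C = 0 with A > 0 gives +inf (class OR > 1,
warned — impossible for nondegenerate genomes). OR exactly 1 falls in the
OR ≤ 1 class, matching the class names. MIB reads never contribute to A/B.

## Association statistics

Fisher's exact tests are two-sided (sum of hypergeometric probabilities not
exceeding the observed table's, margins fixed), computed via scipy and
verified in the test suite against full rational-arithmetic enumeration to
12 significant digits. Both odds-ratio estimators are reported: the
cross-product (a·d)/(c·b) — the formula stated with the 256-table
construction — and the conditional MLE of the noncentral hypergeometric
likelihood, which is what standard exact-test software prints and which
differs from the cross-product in strongly unbalanced tables. The 95% CI
inverts the exact conditional test (no mid-p). Extreme p-values are kept as
they are (double precision holds magnitudes ~1e-300; no flooring). A zero
margin flags the result degenerate instead of raising. Replicate-level
viability comparisons are provided only as thin t-test / Mann-Whitney
wrappers.

## Synthetic libraries

The simulator's defaults describe the intended study conditions: one 50 kb
chromosome at yeast-like GC 0.38, 5000 captured breaks, MIB rate 0.15 (the
wild-type share of insertion-bearing reads among retained breaks in
published counts of this assay), corrupt-linker rate 0.10, substitution
error rate 0 (indel and flow-space error models are out of scope), insert
lengths 1-20 drawn uniformly over A/C/G/T (no composition model), uniform
strand choice, and break sampling proportional to a per-4-mer weight
(weight 1 unless listed in `enriched_4mers`). The parameter-recovery study
uses weight 50 for two 4-mers, MIB rate 0.3 and insert lengths 3-8. Each
read is emitted in a uniformly random orientation to exercise strand
determination, and reads shorter than linker + 20 genomic bases are still
emitted — filtering is the pipeline's job, not the generator's.

Two generator behaviours deserve emphasis:

* **Truth canonicalization.** When a drawn insert's 3′ end coincidentally
  equals the reference immediately upstream of the break, any
  score-maximising aligner absorbs those bases into the alignment, so the
  drawn (insert, position) pair is not identifiable from the read. Truth
  records therefore store the maximal-alignment representation, computed
  with the same +1/−2 gapless extension rule the mapper uses; the read
  sequence and the insert distribution are unchanged. Without this, exact
  insert recovery is information-theoretically capped near 75% for uniform
  inserts. This ambiguity is a property of real break-capture data too:
  reported inserts are always the minimal unalignable prefix.
* **Observable truths.** A break less than ~18 bp upstream of an RsaI site
  yields a capture fragment shorter than the 20 bp alignment floor (after
  half-site trimming) and is physically unreportable by this protocol
  (~7% of uniform breaks at GC 0.5). Corrupted-linker reads are likewise
  rejected by design. Recovery metrics are therefore reported over
  *observable* truths — intact linker and mappable fragment — with the
  unconditional retention count reported alongside. A corrupting
  truncation whose missing bases would be restored by the fragment start
  is redrawn, so `linker_intact` always describes what the read shows.

What the simulator does not emulate: PCR duplicates, quality scores,
indels/homopolymer errors, chimeric ligation, coverage biases, or a real
yeast genome's repeat structure. Passing the recovery tests shows the
pipeline's logic is exact under its own assumptions, not that the
thresholds are tuned for a particular sequencing platform's error profile.

## Problem sizes

Tests and the acceptance script use 10-50 kb genomes and 400-5000 reads —
sizes at which the exhaustive-diagonal aligner is exact and the whole suite
runs in well under a minute, while every statistical check (enrichment
detection, recovery rates, permutation nulls) retains comfortable power.
The statistics on published counts use the counts as printed; nothing in
those numbers depends on simulation.

## Known limitations

* The aligner is designed for toy references (tens of kb); real genomes
  would need an indexed external aligner behind the same `AlignmentHit`
  contract.
* Insertions longer than (read length − `min_align_length`) are
  unobservable; such reads are logged `unalignable`.
* The choice of counting multimap *locations* (not reads) and the
  lexicographic representative are one reasonable reading of the 90% rule;
  both are isolated in `retain_multimapped`.
* CI values are sanity-checked (they bracket the conditional estimate) but
  no particular published CI method is claimed.
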