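# Methods

## The problem

Chloroplast genomes (plastomes) are usually treated as a single fixed
circular sequence per individual, but a pair of short inverted repeats
(sIRs) — two copies of a ~50 bp sequence in opposite orientation separated
by tens of kilobases — can act as a substrate for intramolecular homologous
recombination. Recombination between the arms inverts the enclosed segment,
so a single individual can carry a mixture of two structural isoforms: the
normal type and an inverted type. This *structural heteroplasmy* is
invisible to assembly pipelines, which collapse the mixture onto the major
form, but it leaves a characteristic signature in raw paired-end short
reads mapped to the major-form reference. `plastinv` implements the
detection of that signature and the estimation of the minor isoform's
frequency, together with a simulator that makes the whole pipeline testable
end to end without any external data.

This mechanism is distinct from canonical "flip-flop" recombination between
the large quadripartite inverted repeats (which inverts the small
single-copy region and produces isomers at near-equal frequency); detecting
flip-flop isomers is explicitly out of scope.

## Detection model

Let the normal-type reference carry an sIR pair with arms sIR-1 at
`[a1s, a1e)` and sIR-2 at `[a2s, a2e)` (0-based half-open), and let the
HR region be `[a1s, a2e)` — the segment inverted by recombination,
inclusive of both arms. A sequenced fragment drawn from the *inverted*
isoform whose ends fall on opposite sides of an arm produces, on the
normal reference, either

* a **fully aligned discordant pair**: both mates align, orientation FF or
  RR instead of FR, with an apparent mate span close to the HR span
  (~22 kb in the study system); or
* a **soft-clipped pair**: one mate crosses the divergence point, its
  alignment stops at an arm boundary, and the clipped remainder realigns
  near the *opposite* arm (in reverse orientation).

Candidates must satisfy, following the study's stated criteria:

1. discordant orientation and `|observed span − HR span| ≤ span_tolerance`
   (default 1000 bp) — the "expected insert size of approximately 22 kb"
   rule, operationalized against the actual HR span rather than a hard
   22 kb constant; soft-clip candidates are exempt from this span rule
   (their mates are close together by construction);
2. at least one read overlapping an arm; or, failing that, one read wholly
   inside the HR region with its mate wholly outside within `vicinity_bp`
   (default 1000) of an arm;
3. when remapped to the inverted-type reference, proper FR orientation with
   a mate span strictly below `inverted_max_span_bp` (default 500 bp);
4. at most `variant_tolerance` (default 3) mismatches+indels across the
   pair ("minor variation"; more is excluded with a logged reason).

Verified candidates are assigned one of eight patterns:

| Pattern | geometry on the normal reference |
|---------|----------------------------------|
| I / II  | fully aligned, read overlaps sIR-1 / sIR-2, mate not inside the HR region |
| III / IV| fully aligned, read overlaps sIR-1 / sIR-2, mate wholly inside |
| V       | fully aligned, no arm overlap: inside/outside with the mate in an arm's vicinity |
| VI / VII| soft-clipped at the sIR-1 / sIR-2 boundary, mate not inside the HR region |
| VIII    | soft-clipped at an arm boundary, mate wholly inside |

The taxonomy is an operationalization of the study's pictorial definitions;
the textual constraints (V = no direct overlap, VI–VIII = soft-clipped) are
respected, but the assignment of Roman numerals within I–IV and VI–VII may
permute relative to the original figures. Counts remain comparable because
the geometry of each label is stated above and echoed in the output.

The frequency statistic is

```
frequency_pct = 100 × (number of supporting read pairs) / (mean depth over the HR region)
```

with each pair counted once. This reproduces the study's internal
arithmetic (35 pairs at mean depth 507.25 ↔ 6.90%). The estimate is a
*scaled proxy*, not the molecular fraction: only fragments whose geometry
straddles an arm qualify, so the statistic is proportional to the true
fraction with a constant set by fragment geometry (insert distribution,
read and arm length). On simulated data at 500× the constant is ≈190 — a
5% mixture yields roughly a 9–10% reported frequency. Cross-sample
comparisons at similar library geometry remain valid; absolute molecular
fractions would require calibrating against that constant.

### Depth

Mean depth over the HR region counts M/D reference spans of mapped,
primary, non-duplicate, non-QC-fail alignments, with no MAPQ or
base-quality threshold — the default behavior of `samtools depth`. Soft
clips contribute nothing.

## Internal mapper

The production path consumes SAM from any external aligner (both
references), with `-M`-style semantics assumed for split reads. The
internal mapper exists so that tests and environments without an aligner
can run the pipeline; it is deliberately minimal:

* exact 21-mer seeds at three read offsets, looked up in a sorted index of
  the doubled (circular) reference; reads failing full-length placement are
  re-seeded densely (every 10 bp) before falling back;
* full-length ungapped verification; accepted when mismatches ≤
  `max_mismatch_rate × read length` (default 0.02, i.e. 3 per 150 bp —
  deliberately equal to the detector's `variant_tolerance` so an accepted
  full-length alignment is never later discarded as excess variation);
* otherwise the maximal-scoring ungapped segment (match +1, mismatch −4)
  of the best candidate becomes the alignment, the remainder soft-clipped;
  segments shorter than 30 bp are unmapped;
* deterministic tie-breaks: fewest mismatches, then lowest reference
  offset, then forward orientation. One primary alignment per read; no
  gapped alignment, no base-quality awareness.

A consequence worth knowing: with a complete-match pair the two references
are identical everywhere except strictly between the arms' inner edges, so
a breakpoint-crossing read can always extend its alternative placement
through the arm itself. Realizable soft clips are therefore capped near
`(read_len − arm_len)/2` (≈48 bp for 150 bp reads and 53 bp arms), and
clip junctions sit at arm edges up to a short chance-match extension
(`clip_junction_slack_bp`, default 50, absorbs this). Any primary-alignment
mapper, including BWA-MEM, shows the same geometry.

Soft-clip remapping aligns the whole clip semi-globally (edlib, both
orientations) inside the window `opposite arm ± vicinity_bp`; a hit
requires identity ≥ `clip_min_identity` (default 0.9) over the full clip.

## Simulator and truth oracle

The generator emulates the study inputs: a circular 160 kb i.i.d. genome at
38% GC, one planted 53 bp arm pair spanning 22 kb (rejection-resampled so
no other inverted repeat ≥ 20 bp exists and the planted pair's maximal
extension is exactly the planted arms), 150 bp FR read pairs with inserts
~Normal(400, 50) truncated at 300 bp, depth a few hundred fold, i.i.d.
substitution errors, and an optional mutated downstream arm to exercise the
incomplete-match paths. All randomness flows from one seeded generator in a
fixed order (genome, arm, fragment starts, inserts, isoform-origin
uniforms, errors), so outputs are byte-reproducible, and datasets differing
only in the isoform fraction share fragment coordinates — the supporting
set grows monotonically in the fraction by construction (coupled
sampling).

`truth_supporting_set` derives the exact set of supporting fragments from
fragment coordinates and the two genome sequences alone — predicting each
read's primary alignment by reflection arithmetic (plus its own
maximal-subarray junction analysis, independent of the mapper code) and
applying the candidate criteria as inequalities. It is exact for
complete-match arms and error-free reads and refuses other inputs. Against
this oracle the full pipeline (simulate → map → classify → verify) agrees
exactly — zero false positives and negatives — across seeds and fractions;
at fraction 0 with 0.5% sequencing error, no run across 20 seeds produces
any evidence.

What the simulator does *not* model: real repeat landscapes (beyond the
planted pair), indel sequencing errors, quality-score variation, GC bias,
PCR duplicates, organellar transfer segments (NUPTs) in nuclear reads, or
flip-flop isomers of the large IRs. Passing tests therefore demonstrate
correctness of the geometry and bookkeeping under clean conditions, not
robustness to every artifact of real libraries — for real data the
external-aligner path plus the logged exclusion reasons are the guard
rails.

## Numerical and design choices

* **Identity** between arms is `identities / alignment columns` of a global
  alignment with free end gaps (match +1, mismatch −1, gap −2;
  Biopython's PairwiseAligner). "Complete match" requires identity 1.0 and
  equal arm lengths.
* **Repeat discovery** seeds shared 12-mers between the genome and its
  reverse complement, extends each seed to the maximal exact anti-diagonal
  run, and (below identity 1.0) chains nearby runs across small
  anti-diagonal shifts into imperfect candidates. Defaults
  (`min_arm 30, max_arm 1000, span 5–60 kb, identity ≥ 0.8`) capture the
  53 bp / 22 kb case while excluding the canonical large IRs and
  microrepeats. On genomes ≤ 5 kb the output equals a brute-force
  all-substring scan. The identity floor of 0.8 distinguishing a degraded
  arm from "absent" is this package's choice; arm boundaries are defined by
  maximal extension.
* **The inverted isoform** reverse-complements the region inclusive of both
  arms. For complete pairs this is provably identical to inverting only the
  spacer and makes the builder an involution; for incomplete pairs it
  exchanges arm variants between the ends (a midpoint-crossover
  convention — which variant ends up where is not observable from short
  reads).
* **Wrapped HR regions are refused**, with rotation offered instead;
  coordinate maps stay linear. The simulator centers the HR region, so
  reads wrapping the origin exist but never intersect the informative
  region.
* Degenerate inputs: zero depth with zero evidence reports 0% with a
  warning; zero depth with evidence is an error; a genome with no
  qualifying pair yields a clean empty result, not a failure.

## Problem sizes used in the test suite

Unit tests run on 40 kb genomes with an 8 kb HR span (same arm, read and
insert geometry as the study system); the oracle-equivalence,
specificity, and monotonicity checks run at full scale (160 kb, 22 kb HR,
300–500×, fractions 0–10%, 5–20 seeds each). Discovery–oracle equivalence
uses 100 genomes of 1–5 kb with 0–2 planted pairs, and the isoform
involution runs over 50 seeded 40 kb plastomes.

## Known limitations

* The detector's exactness guarantee (oracle equivalence) is stated for
  complete-match arms; incomplete pairs exercise the same code paths and
  are simulated, but the closed-form oracle does not cover them.
* Only substitution errors are simulated; indel sequencing errors would
  surface as soft clips and be filtered by the remap-identity gate, but
  this is untested territory.
* A single sIR pair is analyzed per run (`--pair-index` selects among
  multiple discovered pairs); interacting multi-pair events are not
  modeled.
* SAM text only; BAM/CRAM conversion is left to external tooling.
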