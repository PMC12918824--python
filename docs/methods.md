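# Methods

This note defines the models implemented in `meiodel`, the default
parameters, and the reasoning behind the design choices. Coordinates are
0-based half-open throughout; every stochastic stage takes an explicit seed,
and pipeline stage seeds are derived as
`sha256(f"{master}:{stage}") % 2**31`.

## 1. Hotspots and signal processing (`meiodel.hotspots`)

A SPO11-oligo map is a per-base count vector over a genomic window,
optionally scaled to reads per million. Breakpoint and oligo profiles are
compared after smoothing with a normalized Hann window
`w[n] = sin^2(pi n / (N-1))` (151 bp for hotspot calling, 21 bp for
breakpoint profiles). At the signal edges the kernel is truncated and
renormalized, so the filter conserves the mass of any signal whose support
stays clear of the array boundary. Local normalization divides each base by
the mean signal in a centered window (default 3001 bp, truncated at the
edges); zero-mean windows yield 0 with an explicit warning. Hotspot centers
are the argmax of the smoothed signal within supplied bounds (leftmost on
ties); hotspot strength is the raw count sum, independent of smoothing.
Left/right members of a hotspot pair are compared on a common orientation by
mirroring flagged profiles about the center before pointwise averaging
(`flip_and_average`), which requires a symmetric position grid.

## 2. Junction canonicalization (`meiodel.junctions`)

A deletion junction whose flanks share sequence can be placed at several
equivalent coordinates. Both simulator truth and caller output are reduced to
the **leftmost placement**; the microhomology is the maximal number of
one-base slides to the right, equivalently the number of equivalent
placements minus one. The slide may exceed the deletion length inside repeat
runs (the comparison self-overlaps); the implementation is validated against
brute-force enumeration of all equivalent placements. For junctions carrying
inserted bases, insert bases that merely continue either flank are first
absorbed into the flanks (minimal-insert form); a junction then has either
microhomology or an insert, never both.

## 3. Ground-truth simulator (`meiodel.simulate`)

**Double cuts.** The left cut is drawn from the oligo map treated as a
probability distribution; the cut spacing is drawn from a mixture on the
10-bp lattice (21, 31, 41, 51, 61, 71, 81 bp with weights 0.25, 0.35, 0.25,
0.08, 0.04, 0.02, 0.01), per-component Gaussian jitter (sd 1.5 bp, truncated
at ±4), and a hard 21-bp minimum, reflecting the steric periodicity of
adjacent SPO11 complexes. Draws below the minimum are fully redrawn.

**End joining.** Two repair models:

- *unresected* — the junction forms at the cut positions; a drawn 0–2 bp
  offset (probabilities 0.5/0.3/0.2) models annealing of the 2-nt 5'
  overhangs, shrinking the deletion by that amount. The observed junction
  microhomology is whatever the flanks share by chance.
- *resected* — per-end resection lengths are gamma-distributed
  (shape 4, mean 1100 nt, the meiotic scale); a microhomology length k is
  drawn from a decaying distribution over 1–10 bp, and the junction is placed
  at a shared k-mer found within the two resected flanks (uniformly among
  hits), widening the deletion. If no shared k-mer exists the ends join at
  the cut positions and the event is tagged `no_mh_fallback`.

Both paths emit canonicalized `DeletionEvent`s so recovery tests compare
coordinates exactly.

**Insertions.** Ectopic insertions ligate the released fragment of a donor
double cut (either orientation; donors overlapping the deletion are
rejected). Inverted insertions re-insert a local segment of the deleted
interval in inverted orientation, accepted only when the insert shows ≥1 bp
microhomology at exactly one of its two junctions.

**Well assay.** The limiting-dilution screen seeds each well with 16,000
genome equivalents; per-well event counts are Poisson with mean
`rate × genomes`, and the frequency estimator is total events over total
genomes (one event in 300 wells ⇒ 0.2 × 10⁻⁶).

**Amplicon sequencing.** Each input molecule is amplified by a Galton-Watson
branching process (22 cycles, per-cycle duplication probability 0.9); the
pool is sampled to the target depth (default 3 pairs per molecule)
proportionally to copy number, with a guaranteed floor of one read pair per
molecule — the realistic regime where depth comfortably exceeds input count,
and the regime in which "every molecule is observable" is a property of the
assay rather than of sampling luck. 300-bp paired reads are taken from the
two molecule ends; substitution errors occur at the configured rate with the
erroneous positions flagged by low base quality (Q12 vs the Q33 baseline).
Read names encode molecule and event identity for truth tracking only; the
caller never parses them.

## 4. Junction caller (`meiodel.caller`)

1. **Merging.** Read pairs are merged by their best ungapped overlap
   (anchor-seeded candidate offsets, full scan fallback; ≥20 bp overlap,
   ≤10% mismatches, score = matches − mismatches). Consensus takes the
   higher-quality base at disagreements. Unmerged pairs are excluded.
2. **Amplicon inference / assignment.** Outer read endpoints are located by
   exact 20-mers at the read ends (with a one-anchor-in tolerance for a
   terminal sequencing error) and clustered with ±5 bp tolerance; clusters
   with ≥10 reads become amplicons (median endpoints). An internal deletion
   does not move the outer endpoints, so assignment is event-independent.
3. **Collapsing.** Identical sequences collapse to one record keeping the
   elementwise-maximum base quality and the group size; on error-free data
   PCR duplicates collapse here.
4. **Alignment.** Each unique sequence is aligned to its amplicon with an
   affine-gap aligner (match +1, mismatch −4, open −6, extend −0.5). Merged
   reads span primer to primer by construction, so the alignment is **global
   on both sequences**. (With free end gaps on the reference, the optimal
   path for a large internal deletion degenerates: the deletion re-expresses
   as a small insertion plus a free reference tail and the junction is lost;
   global alignment was verified to restore single-deletion-op paths.) The
   mild gap-extension penalty keeps large deletions as single ops.
   **Mapping confidence** is `min(60, 2 × (best − best competitor score))`
   across the other amplicons, and 0 when the sequence has two co-optimal
   alignment spans within its own amplicon. The 2× scaling maps the typical
   unambiguous margin between overlapping amplicons onto the conventional
   0–60 scale with its ≥55 acceptance threshold; it is a fixed calibration
   constant, not fitted per dataset.
5. **Extraction and artifact filtering.** Deletion ops ≥10 bp become
   candidates; insertion ops within 30 bp on the read are paired with the
   deletion for net-size accounting. Candidates with net deletion
   (deletion − paired insertion) <10 bp are discarded: a low-quality read
   segment that fails to align produces exactly this balanced-indel
   signature. (Some balanced indels instead fragment into sub-threshold ops
   during alignment; they never become candidates and equally never reach
   the output.)
6. **Junction inference.** Candidate coordinates and any junction insert are
   canonicalized (leftmost placement, minimal insert), yielding microhomology
   or inserted bases, mutually exclusively.
7. **Deduplication.** Reads with identical alignment paths — same amplicon
   and same ordered junction list — are conservatively collapsed into one
   unique molecular event (potential PCR duplicates), keeping the
   best-quality representative and recording read multiplicity.
8. **Quality filters.** Calls require mean base quality ≥25 and mapping
   confidence ≥55; every rejection is attributed to exactly one reason in
   the run log.

## 5. Statistics (`meiodel.stats`)

- **Chance microhomology.** `P(x) = (x+1)(1/4)^x(3/4)^2`: the total
  microhomology is the sum of two independent one-sided extensions, each
  geometric with stop probability 3/4; `(x+1)` counts the left/right splits.
  Validated in the tests against exhaustive enumeration of all flank pairs
  up to length 6.
- **2x2 tests.** Two-sided Fisher's exact test under the conventional rule
  (sum of hypergeometric probabilities not exceeding the observed table's),
  delegated to `scipy.stats.fisher_exact` and validated against exact
  rational enumeration. The published 234/804-vs-66/309 and 24/469-vs-0/131
  comparisons reproduce at printed precision (0.0102, 0.004); the published
  value for the 8/29-vs-0/33 table does not reproduce under this rule
  (enumeration gives ≈0.0013) and is deliberately not asserted.
- **Spread and shift.** Brown-Forsythe Levene (absolute deviations from
  group medians) for breakpoint spread; Wilcoxon rank-sum (normal
  approximation, tie-corrected) for location shifts, reported with the
  median difference. All-constant groups return a degenerate p = 1 with a
  warning rather than an exception.
- **Summaries.** Center-window fraction (±100 bp), deletion-size strata with
  default edges 1/11/18/25/46/76/200/∞ isolating the very-small (11–17,
  18–24), ~30-bp, ~60-bp, and ≥200-bp classes, each with a 21-bp-smoothed
  breakpoint profile and a 2-bp-bandwidth Gaussian KDE of sizes.
- **Adjusted frequency.** Observed well-assay frequency scaled by
  (reference-pair weight / pair weight) with pair weight = product of the
  two hotspot strengths, i.e. independent cutting. The product form is an
  assumption; it makes the adjustment invariant to rescaling all strengths.
- **Insertion classification.** Inserts ≥15 bp are searched
  (exact + reverse-complement) in candidate source-hotspot windows; local
  inverted insertions are detected as reverse-complement matches within
  400 bp of the deletion. Unmappable inserts are reported unclassified and
  excluded from source statistics.

## 6. Pipeline and cohorts (`meiodel.pipeline`)

The toy dataset is a 50-kb random reference carrying two hotspot pairs (5-kb
and 2-kb separations) and one strong single hotspot tiled by four
overlapping 560-bp amplicons. Cohort simulation draws intra-hotspot double
cuts and keeps events that fall inside at least one amplicon with primer
margins — the events the assay can physically observe. For the *resected*
amplicon cohort the pipeline uses an effective resection mean of 80 nt
rather than the biological ~1100 nt: a junction displaced by a kilobase
leaves the amplicon entirely and is unobservable in this assay, so the
amplicon cohort models the observable minimally-processed tail of the
resection distribution. Hotspot-pair cohorts (kilobase-scale deletions
between two hotspots) keep the full 1100-nt model.

Runs are a pure function of (inputs, config): the same YAML config and seed
produce byte-identical FASTQ, truth, and call tables. The run log records
per-stage counts satisfying `merged + unmerged = pairs_in` and
`calls = unique_events − quality_discards`, plus recovery against truth
(fraction of distinct canonical truth junctions called at exactly canonical
coordinates with matching inserted bases).

## 7. What the simulator does and does not emulate

Modeled: double-cut spacing periodicity, overhang annealing, resection-scale
microhomology joining, ectopic/inverted fragment capture, PCR duplication
and substitution errors, per-well Poisson sampling. Not modeled: indel
sequencing errors, chimeric PCR artifacts between amplicons, read-quality
degradation along the cycle, strand biases, translocations to other
chromosomes, and biological variation in per-hotspot cutting probability
beyond the supplied oligo maps. Problem sizes used in the tests: cohorts of
25–3000 events (~10² to ~10⁴ read pairs), which run in seconds to ~1 minute
on one CPU.
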