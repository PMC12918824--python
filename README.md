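# meiodel

Simulation and analysis of **microdeletions at meiotic DNA double-strand-break
(DSB) hotspots**: a ground-truth simulator of SPO11 double-cut mutagenesis, an
amplicon deep-sequencing junction caller, and the statistics used to compare
end-joining outcomes between genotypes.

## Scientific background

During meiosis the SPO11 complex deliberately breaks chromosomes at narrow
genomic **hotspots**. Occasionally two SPO11 complexes cut the same chromatid a
few tens of base pairs apart (a **double cut**), releasing the intervening
fragment. If the two broken ends are joined directly instead of being repaired
from the homologous template, the result is a heritable **microdeletion** —
a germline mutation signature of the recombination machinery itself. The
repair route leaves fingerprints at the junction:

- **unresected ends** (direct end joining) give junctions at or very near the
  original cut positions, with little or no microhomology beyond what random
  flanks share by chance;
- **resected ends** (microhomology-mediated joining) give wider deletions whose
  junctions sit at short sequence repeats shared by the two flanks.

The null model for junction microhomology in random DNA is
`P(x) = (x+1) (1/4)^x (3/4)^2`, so 56% of junctions are expected to show zero
microhomology by chance alone. Deviations from this, together with breakpoint
spread around the hotspot center and deletion-size spectra, discriminate the
repair pathways.

This package provides the full computational loop for studying the problem at
desk scale:

1. **`meiodel.hotspots`** — SPO11-oligo maps, Hann smoothing, local
   normalization, hotspot calling, profile flip-and-averaging, bedGraph/BED I/O.
2. **`meiodel.simulate`** — double-cut placement (10-bp spacing lattice,
   21-bp minimum), unresected/resected end-joining models, ectopic and
   inverted insertions, the limiting-dilution well assay, and paired-end
   amplicon read simulation with PCR duplication and substitution errors.
3. **`meiodel.caller`** — read-pair merging, ab initio amplicon inference,
   unique-sequence collapsing, affine-gap alignment, junction extraction with
   balanced-indel artifact filtering, leftmost canonicalization, PCR-duplicate
   deduplication, and base-quality/mapping-confidence filters.
4. **`meiodel.stats`** — chance-microhomology model, exact 2x2 tests,
   spread (Brown-Forsythe) and shift (Wilcoxon) comparisons, center-window
   fractions, deletion-size strata, strength-adjusted frequencies, insertion
   classification.
5. **`meiodel.pipeline` / `meiodel.cli`** — seeded, deterministic
   simulate → call → stats runs from a declarative YAML config.

Everything is deterministic given a master seed; per-stage seeds are derived
from the seed and the stage name.

## Worked example

Simulate 100 microdeletion events at a toy hotspot, sequence them, call
junctions, and compare the calls to the simulation truth:

```
$ meiodel --seed 1 --out-dir out run-all --n-events 100
{
  "simulate": {
    "events": 100,
    "molecules": 200,
    "read_pairs": 600
  },
  "call": {
    "pairs_in": 600,
    "merged": 600,
    "unmerged": 0,
    "amplicons": 4,
    "assigned": 600,
    "unique_seqs": 316,
    "aligned": 316,
    "candidates": 193,
    "artifact_discards": 0,
    "unique_events": 96,
    "quality_discards": 0,
    "calls": 96,
    "recovery": {
      "n_truth": 83,
      "n_called": 83,
      "n_recovered": 83,
      "n_false": 0,
      "recovery": 1.0,
      "mh_correct": 96
    }
  },
  "stats": {
    "center_window_fraction": 0.984375,
    "size_strata": {
      "1-10": 0,
      "11-17": 0,
      "18-24": 19,
      "25-45": 60,
      "46-75": 16,
      "76-199": 1,
      ">=200": 0
    },
    "mh0_fraction": 0.6458333333333334
  }
}
```

All 83 distinct simulated junctions are recovered at exactly their canonical
coordinates with zero false calls (`recovery: 1.0`); the 100 events collapse
to 83 junctions because independent events can produce identical joins. The
output directory contains the FASTQ pair, the truth table, and the junction
calls:

```
$ head -5 out/junction_calls.tsv | cut -f1-11
amplicon  chrom  left_bp  right_bp  del_len  ins_len  net  mh_len  mh_seq  ins_seq  mean_baseq
amp1      chrT   39997    40027     30       0        30   1       G                33.0
amp1      chrT   39998    40078     80       0        80   1       A                33.0
amp1      chrT   39996    40026     30       0        30   0                        33.0
amp1      chrT   40001    40059     58       0        58   2       TC               33.0
```

The statistics module reproduces published junction-microhomology contrasts
from raw 2x2 counts, e.g. 234/804 vs 66/309 junctions with at least 1 bp of
microhomology:

```
$ meiodel stats --test fisher --table 234 570 66 243
{"test": "fisher", "p": 0.010232519845605791}
```

The same operations are available as a library; see `docs/methods.md` for the
model definitions and parameter rationale.

## Layout

```
src/meiodel/        library (hotspots, junctions, simulate, caller, stats,
                    fixtures, pipeline, cli)
tests/              unit + property tests; tests/test_acceptance.py holds the
                    acceptance criteria
scripts/acceptance.py   computes the acceptance targets as JSON
docs/methods.md     model description, parameters, and design rationale
```
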