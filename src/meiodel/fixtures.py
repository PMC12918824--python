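"""Self-contained toy datasets: a random reference with hotspot-shaped
SPO11-oligo maps, hotspot pairs for the well assay, and a single strong
hotspot tiled by four overlapping amplicons for microdeletion sequencing.

Everything is generated from a seed at run time; `write_fixtures`
materializes the dataset as FASTA + bedGraph + BED + TSV for CLI use.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import AmpliconDef
from .hotspots import Hotspot, SpoOligoMap, call_hotspot, write_bedgraph, write_hotspot_bed
from .simulate import derive_seed, make_oligo_map, random_reference

__all__ = ["ToyDataset", "make_toy_dataset", "write_fixtures"]

REF_LEN = 50_000
CHROM = "chrT"

# hotspot centers: a 5-kb pair, a 2-kb pair, and a single amplicon hotspot
PAIR_CENTERS = {"hsA": 5_000, "hsB": 10_000, "hsC": 20_000, "hsD": 22_000}
SINGLE_CENTER = 40_000
SINGLE = "hsS"
MAP_HALF_SPAN = 1_500

# four overlapping ~560-bp amplicons spanning ~900 bp around the hotspot
AMPLICON_SPANS = [
    (39_550, 40_110),
    (39_660, 40_220),
    (39_770, 40_330),
    (39_890, 40_450),
]


@dataclass
class ToyDataset:
    ref: str
    chrom: str
    maps: dict  # hotspot name -> SpoOligoMap
    hotspots: dict  # hotspot name -> Hotspot
    pairs: list  # [(left name, right name)]
    amplicons: list  # AmpliconDef over the single hotspot
    single: str = SINGLE


def make_toy_dataset(seed: int = 0) -> ToyDataset:
    """Build the complete toy dataset from a master seed."""
    ref = random_reference(REF_LEN, derive_seed(seed, "reference"))
    centers = dict(PAIR_CENTERS, **{SINGLE: SINGLE_CENTER})
    maps = {}
    hotspots = {}
    for name, center in centers.items():
        m = make_oligo_map(
            chrom=CHROM,
            start=center - MAP_HALF_SPAN,
            length=2 * MAP_HALF_SPAN,
            center=center,
            total_signal=3000.0 if name == SINGLE else 1000.0,
            seed=derive_seed(seed, f"map:{name}"),
        )
        maps[name] = m
        hotspots[name] = call_hotspot(
            m, (center - 300, center + 300), name=name
        )
    amplicons = [
        AmpliconDef(
            name=f"amp{i + 1}", chrom=CHROM, start=s, end=e, seq=ref[s:e]
        )
        for i, (s, e) in enumerate(AMPLICON_SPANS)
    ]
    return ToyDataset(
        ref=ref,
        chrom=CHROM,
        maps=maps,
        hotspots=hotspots,
        pairs=[("hsA", "hsB"), ("hsC", "hsD")],
        amplicons=amplicons,
    )


def write_fixtures(ds: ToyDataset, outdir: str) -> dict:
    """Write reference FASTA, per-hotspot oligo bedGraphs, hotspot BED, and
    amplicon BED/TSV. Returns the written paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    fa = os.path.join(outdir, "reference.fa")
    with open(fa, "w") as fh:
        fh.write(f">{ds.chrom}\n")
        for i in range(0, len(ds.ref), 80):
            fh.write(ds.ref[i : i + 80] + "\n")
    paths["reference"] = fa
    for name, m in ds.maps.items():
        p = os.path.join(outdir, f"spo11_{name}.bedGraph")
        write_bedgraph(m, p)
        paths[f"map:{name}"] = p
    bed = os.path.join(outdir, "hotspots.bed")
    write_hotspot_bed(list(ds.hotspots.values()), bed)
    paths["hotspots"] = bed
    amp = os.path.join(outdir, "amplicons.bed")
    pd.DataFrame(
        [(a.chrom, a.start, a.end, a.name) for a in ds.amplicons]
    ).to_csv(amp, sep="\t", header=False, index=False)
    paths["amplicons"] = amp
    return paths
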