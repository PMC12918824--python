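"""End-to-end orchestration: simulate -> call -> stats, with deterministic
per-stage seeds, a declarative run configuration, and a structured run log.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .caller import AmpliconDef, call_amplicons, calls_to_frame
from .fixtures import ToyDataset, make_toy_dataset, write_fixtures
from .junctions import canonicalize_junction
from .simulate import (
    DeletionEvent,
    RepairModel,
    SpacingModel,
    derive_seed,
    join_ends,
    make_double_cut,
    simulate_amplicon_reads,
    write_fastq,
)
from .stats import BreakpointSet, center_window_fraction, spread_test, stratify_sizes

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "simulate_microdeletion_cohort",
    "molecules_for_events",
    "simulate_pair_cohort",
    "truth_junctions",
    "evaluate_recovery",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Declarative configuration of a full run. Every stochastic stage's
    seed is derived from the master seed and the stage name."""

    seed: int = 1
    out_dir: str = "meiodel_out"
    genotype: str = "unresected"  # repair model for the simulated cohort
    n_events: int = 300
    n_wt_molecules: int = 100
    error_rate: float = 1e-3
    depth_per_molecule: int = 3
    pcr_cycles: int = 22
    pcr_efficiency: float = 0.9
    min_net: int = 10
    min_mean_baseq: float = 25.0
    min_map_conf: float = 55.0
    stages: tuple = ("simulate", "call", "stats")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def simulate_microdeletion_cohort(
    ds: ToyDataset,
    n_events: int,
    repair: RepairModel,
    seed: int,
    genotype: str = "",
    spacing_model: SpacingModel | None = None,
    max_tries: int = 40,
) -> list[DeletionEvent]:
    """Simulate joined intra-hotspot double cuts at the single hotspot whose
    deletions fall inside at least one amplicon (with primer margins), i.e.
    the events the amplicon assay can observe."""
    rng = np.random.default_rng(derive_seed(seed, f"cohort:{genotype}"))
    spo_map = ds.maps[ds.single]
    events = []
    while len(events) < n_events:
        for _ in range(max_tries):
            dc = make_double_cut(spo_map, spacing_model, rng, ref=ds.ref)
            ev = join_ends(dc, ds.ref, repair, rng, chrom=ds.chrom, genotype=genotype)
            if ev.size < 1:
                continue
            if any(
                a.start + a.primer_len + 5 <= ev.left_bp
                and ev.right_bp <= a.end - a.primer_len - 5
                for a in ds.amplicons
            ):
                events.append(ev)
                break
        else:
            raise RuntimeError("could not place event within any amplicon")
    return events


def molecules_for_events(
    ds: ToyDataset,
    events: list[DeletionEvent],
    n_wt: int,
    seed: int,
) -> list[tuple[str, str, str]]:
    """Amplicon-spanning molecules: one per event (assigned to a random
    amplicon that contains it) plus wild-type molecules spread over all
    amplicons. Molecule/event ids allow truth tracking through read names."""
    rng = np.random.default_rng(derive_seed(seed, "molecules"))
    mols = []
    for i, ev in enumerate(events):
        containing = [
            a
            for a in ds.amplicons
            if a.start + a.primer_len + 5 <= ev.left_bp
            and ev.right_bp <= a.end - a.primer_len - 5
        ]
        a = containing[rng.integers(len(containing))]
        ins = ev.insertion.seq if ev.insertion else ""
        seq = ds.ref[a.start : ev.left_bp] + ins + ds.ref[ev.right_bp : a.end]
        mols.append((f"mol{i}", f"evt{i}:{a.name}", seq))
    for j in range(n_wt):
        a = ds.amplicons[j % len(ds.amplicons)]
        mols.append((f"wt{j}", "none", ds.ref[a.start : a.end]))
    return mols


def simulate_pair_cohort(
    ds: ToyDataset,
    pair: tuple[str, str],
    n_events: int,
    repair: RepairModel,
    seed: int,
    genotype: str = "",
) -> list[DeletionEvent]:
    """Deletions between two DSBs at an adjacent hotspot pair: one cut drawn
    from each hotspot's oligo map, joined under the repair model."""
    rng = np.random.default_rng(derive_seed(seed, f"pair:{genotype}"))
    from .simulate import sample_cut_sites

    left_map, right_map = ds.maps[pair[0]], ds.maps[pair[1]]
    lcs = sample_cut_sites(left_map, n_events, rng)
    rcs = sample_cut_sites(right_map, n_events, rng)
    return [
        join_ends((int(lc), int(rc)), ds.ref, repair, rng, chrom=ds.chrom, genotype=genotype)
        for lc, rc in zip(lcs, rcs)
    ]


def truth_junctions(ds: ToyDataset, events: list[DeletionEvent]) -> set:
    """Canonical (left, right, ins) truth signatures for recovery checks."""
    out = set()
    for ev in events:
        ins = ev.insertion.seq if ev.insertion else ""
        l, r, ins_c, _ = canonicalize_junction(ds.ref, ev.left_bp, ev.right_bp, ins)
        out.add((l, r, ins_c))
    return out


def evaluate_recovery(ds: ToyDataset, events: list[DeletionEvent], calls) -> dict:
    """Compare caller output with simulation truth.

    recovered: truth junctions found at exactly canonical coordinates (and
    matching inserted bases). false: called junctions not in truth. A truth
    junction counts once regardless of how many amplicons observed it.
    """
    truth = truth_junctions(ds, events)
    truth_mh = {}
    for ev in events:
        if not ev.insertion:
            truth_mh[(ev.left_bp, ev.right_bp, "")] = ev.mh_seq
    called = {(c.left_bp, c.right_bp, c.ins_seq) for c in calls}
    recovered = truth & called
    mh_correct = sum(
        1
        for c in calls
        if (c.left_bp, c.right_bp, c.ins_seq) in truth_mh
        and c.mh_seq == truth_mh[(c.left_bp, c.right_bp, c.ins_seq)]
    )
    return {
        "n_truth": len(truth),
        "n_called": len(called),
        "n_recovered": len(recovered),
        "n_false": len(called - truth),
        "recovery": len(recovered) / len(truth) if truth else float("nan"),
        "mh_correct": mh_correct,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; write artifacts under config.out_dir
    and return the complete run log. Output is a pure function of
    (inputs, config)."""
    os.makedirs(config.out_dir, exist_ok=True)
    log: dict = {"config": asdict(config), "stages": {}}
    ds = make_toy_dataset(config.seed)
    write_fixtures(ds, os.path.join(config.out_dir, "fixtures"))

    events: list[DeletionEvent] = []
    pairs = []
    if "simulate" in config.stages:
        # within a ~580-bp amplicon only junctions from minimally processed
        # ends are observable, so the resected amplicon cohort uses a short
        # effective resection; hotspot-pair cohorts use the full-length model
        repair = (
            RepairModel(mode="resected", resection_mean=80.0)
            if config.genotype == "resected"
            else RepairModel(mode=config.genotype)
        )
        events = simulate_microdeletion_cohort(
            ds, config.n_events, repair, config.seed, genotype=config.genotype
        )
        mols = molecules_for_events(ds, events, config.n_wt_molecules, config.seed)
        pairs = simulate_amplicon_reads(
            mols,
            seed=derive_seed(config.seed, "reads"),
            pcr_cycles=config.pcr_cycles,
            efficiency=config.pcr_efficiency,
            error_rate=config.error_rate,
            depth=config.depth_per_molecule * len(mols),
        )
        write_fastq([p[0] for p in pairs], os.path.join(config.out_dir, "reads_R1.fastq"))
        write_fastq([p[1] for p in pairs], os.path.join(config.out_dir, "reads_R2.fastq"))
        _events_table(events).to_csv(
            os.path.join(config.out_dir, "truth_events.tsv"), sep="\t", index=False
        )
        log["stages"]["simulate"] = {
            "events": len(events),
            "molecules": len(mols),
            "read_pairs": len(pairs),
        }

    calls = []
    if "call" in config.stages and pairs:
        calls, clog = call_amplicons(
            pairs,
            ds.ref,
            amplicons=ds.amplicons,
            chrom=ds.chrom,
            min_net=config.min_net,
            min_mean_baseq=config.min_mean_baseq,
            min_map_conf=config.min_map_conf,
        )
        calls_to_frame(calls).to_csv(
            os.path.join(config.out_dir, "junction_calls.tsv"), sep="\t", index=False
        )
        _write_bedpe(calls, os.path.join(config.out_dir, "junctions.bedpe"))
        clog["recovery"] = evaluate_recovery(ds, events, calls)
        log["stages"]["call"] = clog

    if "stats" in config.stages and calls:
        center = ds.hotspots[ds.single].center
        call_events = [
            DeletionEvent(
                chrom=c.chrom, left_bp=c.left_bp, right_bp=c.right_bp,
                mh_len=c.mh_len, mh_seq=c.mh_seq, genotype=config.genotype,
            )
            for c in calls
        ]
        bs = BreakpointSet(genotype=config.genotype, events=call_events, center=center)
        strata, _ = stratify_sizes(call_events)
        log["stages"]["stats"] = {
            "center_window_fraction": center_window_fraction(bs.positions),
            "size_strata": strata.counts(),
            "mh0_fraction": float(np.mean([c.mh_len == 0 for c in calls])),
        }

    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


def _events_table(events: list[DeletionEvent]):
    import pandas as pd

    cols = [
        "chrom", "left_bp", "right_bp", "size", "mh_len", "mh_seq",
        "ins_seq", "ins_kind", "genotype", "resected", "tag",
    ]
    return pd.DataFrame(
        [
            dict(
                chrom=e.chrom, left_bp=e.left_bp, right_bp=e.right_bp, size=e.size,
                mh_len=e.mh_len, mh_seq=e.mh_seq,
                ins_seq=e.insertion.seq if e.insertion else "",
                ins_kind=e.insertion.kind if e.insertion else "none",
                genotype=e.genotype, resected=e.resected, tag=e.tag,
            )
            for e in events
        ],
        columns=cols,
    )


def _write_bedpe(calls, path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.left_bp}\t{c.left_bp + 1}\t{c.chrom}\t"
                f"{c.right_bp}\t{c.right_bp + 1}\t{c.amplicon}\t{c.net}\t+\t+\n"
            )
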