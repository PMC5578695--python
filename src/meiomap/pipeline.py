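"""End-to-end orchestration: simulate/load -> filter -> call -> classify -> stats.

Every stage's output is written as TSV into the run directory, the run
log records the seed and parameters, and a fixed seed reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .calling import EventGroup, call_raw_events, group_events
from .classify import classify_group, summarize, summary_table, tract_length
from .core import (
    GenomeMap,
    MarkerMap,
    Tetrad,
    build_profile,
    filter_shared_aberrant,
)
from .simulate import SimParams, TruthRecord, simulate_batch

logger = logging.getLogger("meiomap")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    n_tetrads: int = 10
    seed: int = 0
    grouping_gap: int = 5000
    tract_convention: str = "mid"
    sim: SimParams = field(default_factory=SimParams)
    genome: GenomeMap = field(default_factory=GenomeMap)
    outdir: Path = Path("meiomap_run")

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.grouping_gap < 0:
            raise ValueError("grouping_gap must be >= 0")
        if self.tract_convention not in ("min", "mid", "max"):
            raise ValueError("tract_convention must be 'min', 'mid' or 'max'")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides take precedence."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim_kwargs = raw.pop("sim", {})
        genome_spec = raw.pop("genome", None)
        cfg = cls(**raw)
        if sim_kwargs:
            cfg.sim = SimParams(**sim_kwargs)
        if genome_spec:
            cfg.genome = GenomeMap(tuple((c["name"], c["length"]) for c in genome_spec))
        return cfg


def call_tetrad(
    tetrad: Tetrad, markers: MarkerMap, gap: int = 5000
) -> list[EventGroup]:
    """Profile, call, group and classify one tetrad's events."""
    groups: list[EventGroup] = []
    for chrom in markers.chromosomes:
        if chrom not in tetrad.genotypes:
            continue
        profile = build_profile(tetrad, chrom, markers)
        events = call_raw_events(profile, tetrad.matrix(chrom))
        for g in group_events(events, gap):
            g.label = classify_group(g)
            groups.append(g)
    return groups


def groups_to_tables(
    groups_by_tetrad: dict[str, list[EventGroup]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten classified groups into the event and group TSV tables."""
    event_rows, group_rows = [], []
    for tid, groups in groups_by_tetrad.items():
        gid_counter: dict[str, int] = {}
        for g in groups:
            gid = gid_counter.get(g.chrom, 0)
            gid_counter[g.chrom] = gid + 1
            lo, hi = g.span
            group_rows.append(
                {
                    "tetrad_id": tid, "chrom": g.chrom, "group_id": gid,
                    "class": g.label, "span_start": lo, "span_end": hi,
                    "n_co": len(g.crossovers), "n_tracts": len(g.tracts),
                }
            )
            for e in g.events:
                row = {
                    "tetrad_id": tid, "chrom": e.chrom, "start": e.start,
                    "end": e.end, "kind": e.kind,
                    "chromatids": ",".join(map(str, sorted(e.chromatids))),
                    "flank_relation": e.flank_relation or "",
                    "group_id": gid,
                }
                if e.kind == "GC_TRACT":
                    tl = tract_length(e)
                    row.update(
                        tract_min=tl.min, tract_mid=tl.mid, tract_max=tl.max,
                        tract_edge=int(tl.edge),
                    )
                else:
                    row.update(tract_min=0.0, tract_mid=0.0, tract_max=0.0,
                               tract_edge=0)
                event_rows.append(row)
    cols = ["tetrad_id", "chrom", "start", "end", "kind", "chromatids",
            "flank_relation", "group_id", "tract_min", "tract_mid",
            "tract_max", "tract_edge"]
    gcols = ["tetrad_id", "chrom", "group_id", "class", "span_start",
             "span_end", "n_co", "n_tracts"]
    return (
        pd.DataFrame(event_rows, columns=cols),
        pd.DataFrame(group_rows, columns=gcols),
    )


def per_chromosome_counts(
    groups_df: pd.DataFrame, genome: GenomeMap, which: str = "CO"
) -> pd.DataFrame:
    """Tetrad x chromosome table of CO (E2+E3) or NCO (E1) group counts."""
    classes = {"CO": ("E2", "E3"), "NCO": ("E1",)}[which]
    sel = groups_df[groups_df["class"].isin(classes)]
    table = (
        sel.groupby(["tetrad_id", "chrom"]).size().unstack(fill_value=0)
    )
    for chrom in genome.names:
        if chrom not in table.columns:
            table[chrom] = 0
    all_tids = groups_df["tetrad_id"].unique()
    table = table.reindex(index=all_tids, fill_value=0)
    return table[genome.names].astype(int)


# -- truth evaluation -------------------------------------------------------


def _covered_markers(
    markers: MarkerMap, chrom: str, intervals
) -> np.ndarray:
    pos = markers.positions[chrom]
    mask = np.zeros(pos.size, dtype=bool)
    for s, e in intervals:
        mask |= (pos >= s) & (pos <= e)
    return pos[mask]


def truth_recall(
    truth: dict[str, list[TruthRecord]],
    groups_by_tetrad: dict[str, list[EventGroup]],
    markers: MarkerMap,
) -> pd.DataFrame:
    """Score the caller against simulator ground truth, per tetrad.

    Columns: true and called crossover counts; conversion tracts covering
    at least one marker (visible); the subset that is
    chromatid-identifiable in principle (both flanking markers exist and
    no other planted event intrudes into the flank window — a tract
    clipped at a chromosome end, or one abutting another event with no
    2:2 marker in between, cannot be attributed to a strand by any
    caller); and how many identifiable tracts were recovered with the
    true chromatid.  For a crossover-associated tract either the exact
    recipient strand or the two-candidate crossover pair counts as a
    match (a one-sided conversion at a junction is intrinsically
    two-fold ambiguous).
    """
    rows = []
    for tid, events in truth.items():
        groups = groups_by_tetrad.get(tid, [])
        called_co = sum(len(g.crossovers) for g in groups)
        true_co = sum(1 for e in events if e.type == "CO")
        called_tracts = [t for g in groups for t in g.tracts]
        visible = identifiable = matched = 0
        for ev in events:
            if not ev.tracts:
                continue
            covered = _covered_markers(markers, ev.chrom, ev.tracts)
            if covered.size == 0:
                continue
            visible += 1
            pos = markers.positions[ev.chrom]
            left_w = pos[pos < covered[0]]
            right_w = pos[pos > covered[-1]]
            if left_w.size == 0 or right_w.size == 0:
                continue  # chromosome-end tract: one flank missing
            window = (int(left_w[-1]), int(right_w[0]))
            collision = False
            for other in events:
                if other is ev or other.chrom != ev.chrom:
                    continue
                foot = list(other.tracts)
                if other.type == "CO":
                    foot.append((other.position, other.position))
                if any(window[0] <= oe and os_ <= window[1] for os_, oe in foot):
                    collision = True
                    break
            if collision:
                continue
            identifiable += 1
            hit = [
                t for t in called_tracts
                if t.chrom == ev.chrom
                and np.any((covered >= t.start) & (covered <= t.end))
            ]
            if hit:
                union = frozenset().union(*(t.chromatids for t in hit))
                ok = union == frozenset({ev.recipient})
                if ev.type == "CO":
                    ok = ok or union == frozenset(ev.chromatids)
                if ok:
                    matched += 1
        rows.append(
            {
                "tetrad_id": tid, "true_co": true_co, "called_co": called_co,
                "tracts_visible": visible, "tracts_identifiable": identifiable,
                "tracts_chromatid_matched": matched,
            }
        )
    return pd.DataFrame(rows)


# -- the end-to-end run -----------------------------------------------------


def run_pipeline(
    config: RunConfig,
    segregation_path: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute all stages and write the report bundle to ``config.outdir``.

    With ``segregation_path`` the tetrads are loaded from file; otherwise
    a batch is simulated (and ground truth written and scored).  Returns
    the tables keyed by name.  Fully deterministic under a fixed seed.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        logger.info("seed=%d params=%s", config.seed, dataclasses.asdict(config.sim))
        truth: dict[str, list[TruthRecord]] | None = None
        if segregation_path is None:
            stage = "simulate"
            rng = np.random.default_rng(config.seed)
            markers, tetrads, truth = simulate_batch(
                config.sim, config.genome, config.n_tetrads, rng
            )
            mio.write_segregation_file(out / "segregation.tsv", markers, tetrads)
            mio.write_truth_file(out / "truth.tsv", truth)
        else:
            stage = "load"
            markers, tetrads = mio.read_segregation_file(segregation_path)

        stage = "filter"
        if len(tetrads) >= 2:
            tetrads, report = filter_shared_aberrant(tetrads, markers)
        else:
            report = pd.DataFrame(columns=["chrom", "pos", "n_tetrads_aberrant"])
        mio.write_table(out / "filter_report.tsv", report)

        stage = "call"
        groups_by_tetrad = {
            t.id: call_tetrad(t, markers, config.grouping_gap) for t in tetrads
        }
        events_df, groups_df = groups_to_tables(groups_by_tetrad)
        mio.write_table(out / "events.tsv", events_df)
        mio.write_table(out / "groups.tsv", groups_df)

        stage = "summarize"
        summaries = [
            summarize(t.id, groups_by_tetrad[t.id]) for t in tetrads
        ]
        summary_df = summary_table(summaries)
        mio.write_table(out / "summary.tsv", summary_df)
        tables = {
            "events": events_df, "groups": groups_df, "summary": summary_df,
            "filter_report": report,
        }

        stage = "stats"
        for which in ("CO", "NCO"):
            counts = per_chromosome_counts(groups_df, config.genome, which)
            counts_out = counts.reset_index().rename(columns={"index": "tetrad_id"})
            mio.write_table(out / f"per_chrom_{which.lower()}.tsv", counts_out)
            tables[f"per_chrom_{which.lower()}"] = counts

        if truth is not None:
            stage = "truth-recall"
            recall = truth_recall(truth, groups_by_tetrad, markers)
            mio.write_table(out / "recall.tsv", recall)
            tables["recall"] = recall
        logger.info("pipeline complete: %d tetrads", len(tetrads))
        return tables
    except Exception:
        logger.error("stage %r failed", stage)
        print(f"meiomap: stage {stage!r} failed", file=sys.stderr)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
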