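"""Reading and writing segregation files and related TSV tables.

The segregation file is a tab-delimited table with a header line and
optional ``#`` comment lines.  Columns are ``chrom``, ``pos``, then four
columns per tetrad named ``<tetrad_id>_1`` .. ``<tetrad_id>_4``.  Calls
are coded with single-letter parent codes, default ``S``/``Y``/``N``
(S288c allele / YJM789 allele / missing), configurable to any pair of
strain roles.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import MISSING, P1, P2, MarkerMap, Tetrad

DEFAULT_CODES = ("S", "Y", "N")  # P1 code, P2 code, missing code


class SegregationFileError(ValueError):
    """Malformed segregation file (message names the offending line)."""


def _spore_columns(columns: list[str]) -> list[tuple[str, list[str]]]:
    """Group spore columns into (tetrad_id, [4 column names])."""
    spore_cols = columns[2:]
    if len(spore_cols) % 4 != 0:
        raise SegregationFileError(
            f"expected 4 spore columns per tetrad, got {len(spore_cols)} spore columns"
        )
    groups: list[tuple[str, list[str]]] = []
    for i in range(0, len(spore_cols), 4):
        block = spore_cols[i : i + 4]
        ids = {re.sub(r"_[1-4]$", "", c) for c in block}
        if len(ids) != 1:
            raise SegregationFileError(f"inconsistent tetrad column block: {block}")
        groups.append((ids.pop(), block))
    return groups


def read_segregation_file(
    path: str | Path, codes: tuple[str, str, str] = DEFAULT_CODES
) -> tuple[MarkerMap, list[Tetrad]]:
    """Parse a segregation TSV into a marker map and tetrads.

    Rejects files whose positions are not strictly increasing within a
    chromosome, and unknown call codes, naming the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise SegregationFileError("first two columns must be 'chrom' and 'pos'")
    groups = _spore_columns(list(df.columns))
    code_map = {codes[0]: P1, codes[1]: P2, codes[2]: MISSING}

    # data line numbers (1-based, header = line 1, comments skipped)
    with open(path) as fh:
        lines = [i + 1 for i, ln in enumerate(fh) if not ln.startswith("#")]
    data_lines = lines[1:]

    df["pos"] = df["pos"].astype(np.int64)
    positions: dict[str, np.ndarray] = {}
    matrices: dict[str, dict[str, np.ndarray]] = {tid: {} for tid, _ in groups}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if pos.size > 1:
            bad = np.flatnonzero(np.diff(pos) <= 0)
            if bad.size:
                line_no = data_lines[sub.index[bad[0] + 1]]
                raise SegregationFileError(
                    f"{path.name}: non-increasing position at line {line_no}"
                )
        positions[chrom] = pos
        for tid, cols in groups:
            mat = np.empty((4, pos.size), dtype=np.int8)
            for s, col in enumerate(cols):
                vals = sub[col].to_numpy()
                for j, v in enumerate(vals):
                    try:
                        mat[s, j] = code_map[v]
                    except KeyError:
                        line_no = data_lines[sub.index[j]]
                        raise SegregationFileError(
                            f"{path.name}: unknown code {v!r} at line {line_no}"
                        ) from None
            matrices[tid][chrom] = mat
    markers = MarkerMap(positions)
    tetrads = [Tetrad(tid, matrices[tid]) for tid, _ in groups]
    return markers, tetrads


def write_segregation_file(
    path: str | Path,
    markers: MarkerMap,
    tetrads: Iterable[Tetrad],
    codes: tuple[str, str, str] = DEFAULT_CODES,
) -> None:
    """Write the inverse of :func:`read_segregation_file` (canonical form)."""
    tetrads = list(tetrads)
    inv = {P1: codes[0], P2: codes[1], MISSING: codes[2]}
    cols: dict[str, list] = {"chrom": [], "pos": []}
    for t in tetrads:
        for s in range(4):
            cols[f"{t.id}_{s + 1}"] = []
    for chrom in markers.chromosomes:
        pos = markers.positions[chrom]
        cols["chrom"].extend([chrom] * pos.size)
        cols["pos"].extend(pos.tolist())
        for t in tetrads:
            mat = t.matrix(chrom)
            for s in range(4):
                cols[f"{t.id}_{s + 1}"].extend(inv[v] for v in mat[s])
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_truth_file(path: str | Path, truth_by_tetrad: dict[str, list]) -> None:
    """Write simulator ground truth as TSV.

    One row per event tract-less events get an empty tract; discontinuous
    tracts produce one row per sub-tract sharing the event index.
    """
    rows = []
    for tid, events in truth_by_tetrad.items():
        for k, ev in enumerate(events):
            tracts = ev.tracts or ((None, None),)
            for ts, te in tracts:
                rows.append(
                    {
                        "tetrad_id": tid,
                        "event": k,
                        "chrom": ev.chrom,
                        "pos": ev.position,
                        "type": ev.type,
                        "chromatids": ",".join(map(str, ev.chromatids)),
                        "tract_start": "" if ts is None else ts,
                        "tract_end": "" if te is None else te,
                        "discontinuous": int(ev.discontinuous),
                        "recipient": "" if ev.recipient is None else ev.recipient,
                    }
                )
    pd.DataFrame(
        rows,
        columns=[
            "tetrad_id", "event", "chrom", "pos", "type",
            "chromatids", "tract_start", "tract_end", "discontinuous", "recipient",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
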