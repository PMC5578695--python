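"""Forward simulator of single yeast meioses with known ground truth.

One meiosis produces four chromatids per chromosome: spores 0 and 1 start
as copies of parent P1, spores 2 and 3 as copies of parent P2.  Crossovers
reciprocally exchange the distal chromosome arms of one non-sister
chromatid pair; gene-conversion tracts overwrite a short stretch of one
recipient chromatid with the allele of the donor homolog.  A wild-type
S. cerevisiae meiosis induces on the order of 200 double-strand breaks,
of which ~90 resolve as crossovers; genome-wide tetrad sequencing detects
roughly 41 simple noncrossover conversions per meiosis with conversion
tract medians of ~1.4-1.8 kb.  Those figures are the simulator defaults.

Crossover placement follows a stationary gamma-renewal process along each
chromosome: inter-crossover distances are Gamma(shape, scale) with the
scale set so the expected count is proportional to chromosome length.
Shape 1 gives a Poisson process (no interference); larger shapes give the
even spacing characteristic of crossover interference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import MISSING, P1, P2, GenomeMap, MarkerMap, Tetrad

#: the four non-sister chromatid pairs (spores 0,1 = P1; spores 2,3 = P2)
NON_SISTER_PAIRS: tuple[tuple[int, int], ...] = ((0, 2), (0, 3), (1, 2), (1, 3))


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the meiosis simulator.

    mean_co_per_meiosis : expected genome-wide crossover count (~90 in
        wild type).
    mean_detectable_nco : expected count of noncrossover conversion events
        of detectable scale (~41 simple NCOs observed per wild-type
        meiosis); how many cover a marker is emergent from SNP density.
    interference_shape : gamma-renewal shape for inter-crossover
        distances; 1 = no interference.
    co_tract_median / nco_tract_median : median conversion-tract length in
        bp (1790 / 1460 observed for wild type).
    tract_dispersion : sigma of the lognormal tract-length distribution.
    p_discontinuous : probability a conversion tract is interrupted by an
        internal restored (heteroduplex patch-repair) segment.
    p_co_assoc_tract : probability a crossover carries a detectable
        conversion tract.
    genotyping_error : per-call allele flip probability.
    shared_artifact_rate : per-marker probability of forcing a 4:0 call in
        every tetrad of a batch (the artifact class the shared-aberrant
        filter removes).
    marker_spacing_mean : mean SNP spacing in bp (exponential spacings).
    """

    mean_co_per_meiosis: float = 90.0
    mean_detectable_nco: float = 41.0
    interference_shape: float = 2.0
    co_tract_median: float = 1790.0
    nco_tract_median: float = 1460.0
    tract_dispersion: float = 0.75
    p_discontinuous: float = 0.05
    p_co_assoc_tract: float = 0.9
    genotyping_error: float = 0.0
    shared_artifact_rate: float = 0.0
    marker_spacing_mean: float = 500.0
    obligate_co: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_discontinuous", "p_co_assoc_tract", "genotyping_error",
                     "shared_artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.co_tract_median <= 0 or self.nco_tract_median <= 0:
            raise ValueError("tract medians must be > 0")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted recombination event.

    ``chromatids`` are *spore* indices: the two strands observed to
    switch parental phase at a crossover, or the single converted strand
    of a noncrossover.  Physically every crossover joins two non-sister
    chromatids of the bivalent; because earlier crossovers reshuffle
    which spore travels on which chromatid backbone, the observable
    switching spores are sampled from the running 2:2 phase (one spore
    per current parental set), which is distributionally identical.

    ``recipient`` is the spore whose calls the conversion tract
    overwrote: for an NCO the single entry of ``chromatids``; for a CO
    one of the two switching spores (``None`` when the CO carries no
    tract).
    """

    chrom: str
    position: int
    type: str  # "CO" or "NCO"
    chromatids: tuple[int, ...]
    tracts: tuple[tuple[int, int], ...] = ()
    discontinuous: bool = False
    recipient: int | None = None

    def __post_init__(self) -> None:
        if self.type == "CO":
            a, b = self.chromatids
            if a == b or not {a, b} <= {0, 1, 2, 3}:
                raise ValueError("CO must involve two distinct spore strands")
        if self.tracts and self.recipient is None:
            object.__setattr__(self, "recipient", self.chromatids[0])


def _renewal_positions(
    length: int, mean_spacing: float, shape: float, rng: np.random.Generator
) -> list[int]:
    """Arrival positions of a stationary gamma-renewal process on [1, length].

    The first arrival uses the exact equilibrium delay U * Gamma(shape+1)
    (length-biased interval times a uniform fraction), which makes the
    expected count length / mean_spacing for any shape.
    """
    scale = mean_spacing / shape
    out: list[int] = []
    x = rng.uniform() * rng.gamma(shape + 1.0, scale)
    while x <= length:
        out.append(max(1, int(round(x))))
        x += rng.gamma(shape, scale)
    # de-duplicate integer collisions deterministically
    seen: set[int] = set()
    uniq = []
    for p in out:
        while p in seen:
            p += 1
        if p <= length:
            seen.add(p)
            uniq.append(p)
    return uniq


def _tract_interval(
    params: SimParams, median: float, anchor: int, side: int, length: int,
    rng: np.random.Generator, centred: bool,
) -> tuple[tuple[tuple[int, int], ...], bool]:
    """Draw a lognormal tract anchored at ``anchor`` and clip to chromosome."""
    tlen = rng.lognormal(mean=np.log(median), sigma=params.tract_dispersion)
    tlen = max(1.0, tlen)
    if centred:
        start, end = anchor - tlen / 2.0, anchor + tlen / 2.0
    elif side > 0:
        start, end = float(anchor), anchor + tlen
    else:
        start, end = anchor - tlen, float(anchor)
    start = max(1, int(round(start)))
    end = min(length, int(round(end)))
    if end < start:
        start = end = max(1, min(length, anchor))
    disc = rng.uniform() < params.p_discontinuous and (end - start) >= 20
    if disc:
        f1 = rng.uniform(0.25, 0.45)
        f2 = rng.uniform(0.55, 0.75)
        span = end - start
        sub1 = (start, start + int(f1 * span))
        sub2 = (start + int(f2 * span), end)
        return (sub1, sub2), True
    return ((start, end),), False


def sample_events(
    params: SimParams, genome: GenomeMap, rng: np.random.Generator
) -> list[TruthRecord]:
    """Plant the crossover and noncrossover events of one meiosis.

    Crossover positions follow the stationary gamma-renewal process, so
    the per-chromosome expected count is proportional to chromosome
    length and the genome-wide count is Poisson-like around
    ``mean_co_per_meiosis`` (exactly Poisson at shape 1).  Noncrossover
    positions are uniform, apportioned to chromosomes by length.
    """
    total = genome.total_length
    events: list[TruthRecord] = []
    co_spacing = (
        total / params.mean_co_per_meiosis if params.mean_co_per_meiosis > 0 else None
    )
    for chrom, length in genome.chromosomes:
        positions: list[int] = []
        if co_spacing is not None:
            positions = _renewal_positions(
                length, co_spacing, params.interference_shape, rng
            )
            if params.obligate_co and not positions:
                positions = [int(rng.integers(1, length + 1))]
        # walk the running 2:2 phase: a crossover switches one spore out of
        # the current P1 set and one in (uniform choice of each), which is
        # the observable image of a uniform non-sister chromatid pair
        phase = {0, 1}
        for pos in positions:
            sa = int(rng.choice(sorted(phase)))
            sb = int(rng.choice(sorted({0, 1, 2, 3} - phase)))
            phase = (phase - {sa}) | {sb}
            pair = (sa, sb)
            tracts: tuple[tuple[int, int], ...] = ()
            disc = False
            recipient = None
            if rng.uniform() < params.p_co_assoc_tract:
                side = 1 if rng.uniform() < 0.5 else -1
                recipient = int(pair[rng.integers(2)])
                tracts, disc = _tract_interval(
                    params, params.co_tract_median, pos, side, length, rng,
                    centred=False,
                )
            events.append(
                TruthRecord(chrom, pos, "CO", tuple(sorted(pair)), tracts, disc,
                            recipient)
            )
    # noncrossovers: Poisson count, chromosome chosen proportional to length
    if params.mean_detectable_nco > 0:
        n_nco = rng.poisson(params.mean_detectable_nco)
        weights = np.array([l for _, l in genome.chromosomes], dtype=float)
        weights /= weights.sum()
        chrom_idx = rng.choice(len(weights), size=n_nco, p=weights)
        for ci in chrom_idx:
            chrom, length = genome.chromosomes[ci]
            pos = int(rng.integers(1, length + 1))
            recipient = int(rng.integers(4))
            tracts, disc = _tract_interval(
                params, params.nco_tract_median, pos, 0, length, rng, centred=True
            )
            events.append(TruthRecord(chrom, pos, "NCO", (recipient,), tracts, disc))
    events.sort(key=lambda e: (e.chrom, e.position))
    return events


# -- painting ---------------------------------------------------------------


def paint_tetrad(
    truth: Sequence[TruthRecord],
    markers: MarkerMap,
    tetrad_id: str = "sim",
) -> Tetrad:
    """Realize planted events as a four-spore genotype matrix.

    Chromatids start as (0,1) = P1 and (2,3) = P2.  Crossovers are applied
    in position order as a reciprocal exchange of the distal marker
    segment between the two designated chromatids; conversion tracts then
    flip the recipient chromatid's calls inside the tract interval(s).

    Raises ``ValueError`` if two crossovers share an identical breakpoint
    position on one chromosome (degenerate truth).
    """
    genotypes: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[TruthRecord]] = {c: [] for c in markers.chromosomes}
    for ev in truth:
        if ev.chrom in by_chrom:
            by_chrom[ev.chrom].append(ev)
    for chrom in markers.chromosomes:
        pos = markers.positions[chrom]
        mat = np.empty((4, pos.size), dtype=np.int8)
        mat[0:2, :] = P1
        mat[2:4, :] = P2
        cos = sorted((e for e in by_chrom[chrom] if e.type == "CO"),
                     key=lambda e: e.position)
        if len({e.position for e in cos}) != len(cos):
            raise ValueError(f"{chrom}: crossovers share a breakpoint position")
        for ev in cos:
            a, b = ev.chromatids
            distal = pos > ev.position
            tmp = mat[a, distal].copy()
            mat[a, distal] = mat[b, distal]
            mat[b, distal] = tmp
        for ev in by_chrom[chrom]:
            if not ev.tracts:
                continue
            for s, e in ev.tracts:
                sel = (pos >= s) & (pos <= e)
                row = mat[ev.recipient]
                row[sel] = np.where(row[sel] == P1, P2, P1)
        genotypes[chrom] = mat
    return Tetrad(tetrad_id, genotypes)


def corrupt_tetrads(
    tetrads: Sequence[Tetrad],
    markers: MarkerMap,
    params: SimParams,
    rng: np.random.Generator,
) -> list[Tetrad]:
    """Apply genotyping noise and tetrad-shared 4:0 marker artifacts.

    Each non-missing call is flipped with probability
    ``genotyping_error``; independently, each marker is converted to a
    4:0 artifact (all four spores the same random parent, in *every*
    tetrad of the batch) with probability ``shared_artifact_rate``.
    """
    out = [t.copy() for t in tetrads]
    if params.genotyping_error > 0:
        for t in out:
            for chrom, mat in t.genotypes.items():
                flip = (rng.random(mat.shape) < params.genotyping_error) & (
                    mat != MISSING
                )
                mat[flip] = (P1 + P2) - mat[flip]
    if params.shared_artifact_rate > 0:
        for chrom in markers.chromosomes:
            n = markers.n_markers(chrom)
            hit = np.flatnonzero(rng.random(n) < params.shared_artifact_rate)
            for j in hit:
                parent = P1 if rng.uniform() < 0.5 else P2
                for t in out:
                    t.matrix(chrom)[:, j] = parent
    return out


def place_markers(
    genome: GenomeMap, mean_spacing: float, rng: np.random.Generator
) -> MarkerMap:
    """Poisson-process SNP positions (exponential spacings, min 1 bp)."""
    positions = {}
    for chrom, length in genome.chromosomes:
        n_expect = int(length / mean_spacing * 1.5) + 10
        gaps = np.maximum(1, rng.exponential(mean_spacing, size=n_expect))
        pos = np.cumsum(gaps)
        pos = pos[pos <= length].astype(np.int64)
        pos = np.unique(pos)
        positions[chrom] = pos
    return MarkerMap(positions)


def simulate_batch(
    params: SimParams,
    genome: GenomeMap,
    n_tetrads: int,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
) -> tuple[MarkerMap, list[Tetrad], dict[str, list[TruthRecord]]]:
    """Simulate a batch of meioses sharing one marker map.

    Returns the marker map, the (possibly corrupted) tetrads, and the
    ground truth per tetrad.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if markers is None:
        markers = place_markers(genome, params.marker_spacing_mean, rng)
    tetrads: list[Tetrad] = []
    truth: dict[str, list[TruthRecord]] = {}
    for i in range(n_tetrads):
        tid = f"t{i + 1}"
        events = sample_events(params, genome, rng)
        tetrads.append(paint_tetrad(events, markers, tid))
        truth[tid] = events
    if params.genotyping_error > 0 or params.shared_artifact_rate > 0:
        tetrads = corrupt_tetrads(tetrads, markers, params, rng)
    return markers, tetrads, truth


def calibrate_detectable_nco(
    params: SimParams,
    genome: GenomeMap,
    target_called_nco: float,
    n_meioses: int = 20,
    rng: np.random.Generator | None = None,
) -> SimParams:
    """Scale ``mean_detectable_nco`` so the *marker-visible* NCO mean hits a target.

    Detection requires a tract to cover at least one SNP; the visible
    fraction depends on marker spacing and tract length.  The fraction is
    estimated by Monte Carlo and the generated mean inflated accordingly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    markers = place_markers(genome, params.marker_spacing_mean, rng)
    seen = 0
    tot = 0
    for _ in range(n_meioses):
        for ev in sample_events(params, genome, rng):
            if ev.type != "NCO":
                continue
            tot += 1
            pos = markers.positions[ev.chrom]
            if any(
                np.any((pos >= s) & (pos <= e)) for s, e in ev.tracts
            ):
                seen += 1
    frac = seen / tot if tot else 1.0
    if frac <= 0:
        raise ValueError("no NCO tract covered any marker; increase SNP density")
    return replace(params, mean_detectable_nco=target_called_nco / frac)
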