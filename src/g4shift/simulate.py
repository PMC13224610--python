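"""Synthetic genomes, event sets, peak sets and mutation cohorts with planted truth.

The generator reproduces the statistical structure the pipeline is built to
detect: a genome carrying canonical G4 motifs at known coordinates over a
background that is provably motif-free (every G-run and C-run is capped below
the minimum tract length), and event sets drawn from a two-component mixture —
with probability ``p`` an event falls uniformly on a motif base, otherwise
uniformly on the genome.  Under that mixture the expected percent of events
directly intersecting motifs is 100*(p + (1-p)*f) where f is the motif
footprint fraction, which is the calibration surface for every test.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomeDef,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    merge_overlapping,
)
from .pqs import PQSParams

__all__ = [
    "SynthGenomeSpec",
    "EventSimSpec",
    "PeakSimSpec",
    "CohortSimSpec",
    "make_genome",
    "simulate_events",
    "simulate_peaks",
    "simulate_cohort",
    "write_fasta",
]

# Default planted motif: four G3 tracts with TTA loops (telomere-repeat-like),
# 21 bp, satisfying the canonical grammar with no internal ambiguity.
DEFAULT_MOTIF = "GGGTTAGGGTTAGGGTTAGGG"


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Desk-scale genome with planted motifs: 1 chromosome x 1 Mb, 200 motifs."""

    chrom_lengths: tuple[int, ...] = (1_000_000,)
    gc_fraction: float = 0.41
    n_motifs: int = 200
    motif: str = DEFAULT_MOTIF
    min_spacing: int = 100
    seed: int = 0
    params: PQSParams = field(default_factory=PQSParams)

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValidationError("gc_fraction must be in (0, 1)")
        if self.min_spacing < 0:
            raise ValidationError("min_spacing must be >= 0")
        total = sum(self.chrom_lengths)
        if self.n_motifs * len(self.motif) >= 0.5 * total:
            raise ValidationError("total motif footprint must stay below 50% of the genome")


@dataclass(frozen=True)
class EventSimSpec:
    """Width-1 events from the motif/uniform mixture with enrichment fraction p."""

    n_events: int = 10_000
    p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        if not 0 <= self.p <= 1:
            raise ValidationError("p must be in [0, 1]")


@dataclass(frozen=True)
class PeakSimSpec:
    """Peak track plus condition-specific DSB sets stratified over peak/motif strata.

    ``rates`` maps condition name -> expected event counts in the four strata
    (peak&motif, peak only, motif only, background); counts are Poisson draws
    and positions uniform over the stratum's base union.
    """

    n_peaks: int = 300
    width_min: int = 150
    width_max: int = 400
    frac_overlap_motif: float = 0.3
    rates: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "parental": (50.0, 200.0, 100.0, 2000.0),
            "knockout": (200.0, 200.0, 100.0, 2000.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_overlap_motif <= 1:
            raise ValidationError("frac_overlap_motif must be in [0, 1]")
        if self.width_min < 1 or self.width_max < self.width_min:
            raise ValidationError("need 1 <= width_min <= width_max")
        for cond, r in self.rates.items():
            if len(r) != 4 or any(v < 0 for v in r):
                raise ValidationError(f"rates for {cond!r} must be 4 non-negative values")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: sample count, mutation-count distribution, enrichment p."""

    n_samples: int
    mutations_mean: float = 500.0
    mutations_dispersion: float = 0.0  # 0 -> Poisson; >0 -> negative binomial
    p: float = 0.0


@dataclass(frozen=True)
class CohortSimSpec:
    """Fig-7-style cohort: three groups, planted double mutants, optional blacklist."""

    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "geneA_mutant": GroupSpec(10, p=0.05),
            "geneB_mutant": GroupSpec(50, p=0.01),
            "neither": GroupSpec(50, p=0.01),
        }
    )
    n_double_mutant: int = 3
    indel_fraction: float = 0.1
    blacklist_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("group names must be unique")
        for name, g in self.groups.items():
            if not 0 <= g.p <= 1:
                raise ValidationError(f"group {name!r}: p must be in [0, 1]")
        if not 0 <= self.blacklist_fraction < 1:
            raise ValidationError("blacklist_fraction must be in [0, 1)")


# -- genome ------------------------------------------------------------------


def _capped_background(length: int, gc: float, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence (byte array) with every G-run and C-run shorter than cap+1.

    Bases are drawn from the GC-weighted composition; whenever the trailing
    ``cap`` bases are all G (or all C) the next draw excludes that base, which
    guarantees the background contains no tract of the minimum length and
    hence no canonical motif on either strand.
    """
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.choice(4, size=length, p=probs)
    # fix up runs sequentially; the run cap makes this a local operation
    out = draws.copy()
    run_base = -1
    run_len = 0
    resample_probs = {
        1: probs.copy(),
        2: probs.copy(),
    }
    for b, pr in resample_probs.items():
        pr[b] = 0.0
        pr /= pr.sum()
    # pre-draw replacement candidates lazily via rng when needed
    for i in range(length):
        b = out[i]
        if b == run_base:
            run_len += 1
        else:
            run_base, run_len = b, 1
        if b in (1, 2) and run_len > cap:  # C or G run too long
            nb = rng.choice(4, p=resample_probs[int(b)])
            out[i] = nb
            run_base, run_len = nb, 1
    return alphabet[out]


def make_genome(spec: SynthGenomeSpec) -> tuple[dict[str, str], GenomeDef, IntervalSet]:
    """Generate sequences, the genome definition, and the truth motif track.

    Background G/C runs are capped at min_tract-1 so the scanner can recover
    the planted motifs with perfect recall and precision; one background base
    flanking each motif is forced to A so that adjacent background guanines
    cannot extend a planted tract.
    """
    rng = np.random.default_rng(spec.seed)
    cap = spec.params.min_tract - 1
    motif = spec.motif.upper()
    motif_bytes = np.frombuffer(motif.encode(), dtype=np.uint8)
    mlen = len(motif)
    names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    genome = GenomeDef.from_pairs(zip(names, spec.chrom_lengths))

    # allocate motif counts to chromosomes proportionally to length
    total = sum(spec.chrom_lengths)
    alloc = [round(spec.n_motifs * L / total) for L in spec.chrom_lengths]
    while sum(alloc) < spec.n_motifs:
        alloc[int(np.argmax(spec.chrom_lengths))] += 1
    while sum(alloc) > spec.n_motifs:
        alloc[int(np.argmax(alloc))] -= 1

    sequences: dict[str, str] = {}
    truth: list[GenomicInterval] = []
    for chrom, length, n_here in zip(names, spec.chrom_lengths, alloc):
        seq = _capped_background(length, spec.gc_fraction, cap, rng)
        # sample non-overlapping motif start positions respecting spacing
        positions: list[int] = []
        span = mlen + spec.min_spacing
        max_start = length - mlen - 1
        if max_start < 1 and n_here > 0:
            raise ValidationError("chromosome too short to place motifs")
        tries = 0
        while len(positions) < n_here:
            tries += 1
            if tries > 1000 * max(n_here, 1):
                raise ValidationError(
                    "cannot place all motifs under the spacing constraint; "
                    "reduce n_motifs or min_spacing"
                )
            cand = int(rng.integers(1, max_start + 1))
            if all(abs(cand - p) >= span for p in positions):
                positions.append(cand)
        for pos in sorted(positions):
            seq[pos : pos + mlen] = motif_bytes
            # break any run continuation across the motif boundary
            seq[pos - 1] = ord("A")
            seq[pos + mlen] = ord("A")
            truth.append(GenomicInterval(chrom, pos, pos + mlen))
        sequences[chrom] = seq.tobytes().decode()
    return sequences, genome, IntervalSet(truth, genome, "features")


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- events ------------------------------------------------------------------


def _uniform_positions(
    n: int, genome: GenomeDef, rng: np.random.Generator
) -> list[tuple[str, int]]:
    names = [c for c, _ in genome.chroms]
    sizes = np.array([L for _, L in genome.chroms], dtype=np.int64)
    offsets = np.cumsum(sizes) - sizes
    flat = rng.integers(0, sizes.sum(), size=n)
    idx = np.searchsorted(np.cumsum(sizes), flat, side="right")
    return [(names[i], int(flat[k] - offsets[i])) for k, i in enumerate(idx)]


def _motif_positions(
    n: int, motifs: IntervalSet, rng: np.random.Generator
) -> list[tuple[str, int]]:
    merged = merge_overlapping(motifs, gap=-1)
    spans = [(iv.chrom, iv.start, iv.width) for iv in merged]
    widths = np.array([w for _, _, w in spans], dtype=np.int64)
    cum = np.cumsum(widths)
    flat = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, flat, side="right")
    prev = cum - widths
    return [
        (spans[i][0], int(spans[i][1] + flat[k] - prev[i])) for k, i in enumerate(idx)
    ]


def simulate_events(
    spec: EventSimSpec,
    genome: GenomeDef,
    motifs: IntervalSet,
    rng: np.random.Generator | None = None,
) -> tuple[IntervalSet, np.ndarray]:
    """Draw width-1 events from the mixture; returns (events, inside-motif truth flags)."""
    if spec.p > 0 and len(motifs) == 0:
        raise ValidationError("cannot plant enrichment with an empty motif track")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    in_motif = rng.random(spec.n_events) < spec.p
    n_in = int(in_motif.sum())
    motif_pos = _motif_positions(n_in, motifs, rng) if n_in else []
    unif_pos = _uniform_positions(spec.n_events - n_in, genome, rng)
    tagged: list[tuple[str, int, bool]] = []
    it_m, it_u = iter(motif_pos), iter(unif_pos)
    for flag in in_motif:
        c, p = next(it_m) if flag else next(it_u)
        tagged.append((c, p, bool(flag)))
    # sort to match IntervalSet iteration order so truth flags stay aligned
    tagged.sort(key=lambda t: (t[0], t[1]))
    events = IntervalSet(
        (GenomicInterval(c, p, p + 1) for c, p, _ in tagged), genome, "events"
    )
    flags = np.array([f for _, _, f in tagged], dtype=bool)
    return events, flags


# -- peaks -------------------------------------------------------------------


def simulate_peaks(
    spec: PeakSimSpec, genome: GenomeDef, motifs: IntervalSet
) -> tuple[IntervalSet, dict[str, IntervalSet], pd.DataFrame]:
    """Peak track with a planted motif-overlap fraction plus stratified DSB sets.

    Returns (peaks, events per condition, truth table of stratum counts).
    """
    if spec.n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    rng = np.random.default_rng(spec.seed)
    motif_list = list(motifs)
    if spec.frac_overlap_motif > 0 and not motif_list:
        raise ValidationError("cannot force motif overlap with an empty motif track")
    lengths = genome.lengths
    peaks: list[GenomicInterval] = []
    n_forced = int(round(spec.frac_overlap_motif * spec.n_peaks))
    for i in range(spec.n_peaks):
        width = int(rng.integers(spec.width_min, spec.width_max + 1))
        if i < n_forced:
            m = motif_list[int(rng.integers(0, len(motif_list)))]
            anchor = int(rng.integers(m.start, m.end))  # peak must cover this base
            lo = max(0, anchor - width + 1)
            hi = min(anchor, lengths[m.chrom] - width)
            if hi < lo:
                raise ValidationError("infeasible forced peak placement; widen chromosome")
            start = int(rng.integers(lo, hi + 1))
            peaks.append(GenomicInterval(m.chrom, start, start + width))
        else:
            chrom, pos = _uniform_positions(1, genome, rng)[0]
            start = min(pos, lengths[chrom] - width)
            peaks.append(GenomicInterval(chrom, max(0, start), max(0, start) + width))
    peak_set = IntervalSet(peaks, genome, "features")

    strata = _strata(genome, peak_set, motifs)
    events_by_condition: dict[str, IntervalSet] = {}
    records = []
    for cond, rates in spec.rates.items():
        ivs: list[GenomicInterval] = []
        for (name, stratum), rate in zip(strata.items(), rates):
            n = int(rng.poisson(rate))
            records.append({"condition": cond, "stratum": name, "n_events": n})
            if n and len(stratum) > 0:
                for c, p in _motif_positions(n, stratum, rng):
                    ivs.append(GenomicInterval(c, p, p + 1))
        events_by_condition[cond] = IntervalSet(ivs, genome, "events")
    return peak_set, events_by_condition, pd.DataFrame(records)


def _strata(
    genome: GenomeDef, peaks: IntervalSet, motifs: IntervalSet
) -> dict[str, IntervalSet]:
    """Disjoint base strata: peak&motif, peak-only, motif-only, background."""
    pk = merge_overlapping(peaks, gap=-1)
    mt = merge_overlapping(motifs, gap=-1)

    def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
        out = []
        for chrom in a.chroms:
            bc = b.coords(chrom)
            for iv in a.by_chrom(chrom):
                if len(bc) == 0:
                    continue
                idx = np.searchsorted(bc[:, 1], iv.start, side="right")
                while idx < len(bc) and bc[idx, 0] < iv.end:
                    s = max(iv.start, int(bc[idx, 0]))
                    e = min(iv.end, int(bc[idx, 1]))
                    if e > s:
                        out.append(GenomicInterval(chrom, s, e))
                    idx += 1
        return IntervalSet(out, a.genome, "features")

    def complement(a: IntervalSet) -> IntervalSet:
        out = []
        for chrom, length in genome.chroms:
            pos = 0
            for iv in merge_overlapping(a, gap=-1).by_chrom(chrom) if len(a) else []:
                if iv.start > pos:
                    out.append(GenomicInterval(chrom, pos, iv.start))
                pos = max(pos, iv.end)
            if pos < length:
                out.append(GenomicInterval(chrom, pos, length))
        return IntervalSet(out, genome, "features")

    def difference(a: IntervalSet, b: IntervalSet) -> IntervalSet:
        return intersect(a, complement(b))

    both = intersect(pk, mt)
    union = merge_overlapping(IntervalSet(list(pk) + list(mt), genome), gap=-1)
    return {
        "peak_and_motif": both,
        "peak_only": difference(pk, mt),
        "motif_only": difference(mt, pk),
        "background": complement(union),
    }


# -- cohort ------------------------------------------------------------------


def simulate_cohort(
    spec: CohortSimSpec, genome: GenomeDef, motifs: IntervalSet
) -> tuple[pd.DataFrame, pd.DataFrame, IntervalSet, pd.DataFrame]:
    """Simulate a mutation cohort.

    Returns (mutations table, sample-status table, blacklist track, truth table).
    Mutation coordinates in the table are 0-based half-open (bed_like_0based
    dialect).  Double-mutant samples are planted with baseline (minimum group)
    enrichment and flagged mutant for both genes, to exercise exclusion.
    """
    rng = np.random.default_rng(spec.seed)
    blacklist = _blacklist(spec.blacklist_fraction, genome, rng)
    mut_rows = []
    status_rows = []
    truth_rows = []
    baseline_p = min(g.p for g in spec.groups.values())

    def draw_count(g: GroupSpec) -> int:
        if g.mutations_dispersion > 0:
            # NB parameterized by mean m and dispersion k: var = m + m^2/k
            k = g.mutations_dispersion
            p = k / (k + g.mutations_mean)
            return max(1, int(rng.negative_binomial(k, p)))
        return max(1, int(rng.poisson(g.mutations_mean)))

    def emit_sample(sample_id: str, group: str, p: float, n_mut: int, a_mut: bool, b_mut: bool):
        ev_spec = EventSimSpec(n_events=n_mut, p=p, seed=0)
        events, flags = simulate_events(ev_spec, genome, motifs, rng=rng)
        for iv, flag in zip(events, flags):
            is_indel = rng.random() < spec.indel_fraction
            if is_indel:
                width = int(rng.integers(1, 51))
                end = min(iv.start + width, genome.lengths[iv.chrom])
                klass = "DEL" if rng.random() < 0.5 else "INS"
            else:
                end = iv.start + 1
                klass = "SNV"
            mut_rows.append(
                {
                    "sample": sample_id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": end,
                    "class": klass,
                }
            )
        status_rows.append(
            {"sample": sample_id, "geneA_status": a_mut, "geneB_status": b_mut}
        )
        truth_rows.append(
            {"sample": sample_id, "group": group, "planted_p": p, "n_mutations": n_mut}
        )

    for group, g in spec.groups.items():
        a_mut = group == "geneA_mutant"
        b_mut = group == "geneB_mutant"
        for i in range(g.n_samples):
            emit_sample(f"{group}_{i:03d}", group, g.p, draw_count(g), a_mut, b_mut)
    double_g = next(iter(spec.groups.values()))
    for i in range(spec.n_double_mutant):
        emit_sample(
            f"double_{i:03d}", "excluded_double", baseline_p, draw_count(double_g), True, True
        )
    return (
        pd.DataFrame(mut_rows),
        pd.DataFrame(status_rows),
        blacklist,
        pd.DataFrame(truth_rows),
    )


def _blacklist(
    fraction: float, genome: GenomeDef, rng: np.random.Generator
) -> IntervalSet:
    """Random non-overlapping blocks covering approximately `fraction` of the genome."""
    if fraction <= 0:
        return IntervalSet((), genome, "exclusion")
    out = []
    block = 2000
    for chrom, length in genome.chroms:
        n_blocks = max(1, int(fraction * length / block))
        starts = np.sort(rng.choice(length - block, size=n_blocks, replace=False))
        prev_end = -1
        for s in starts:
            s = int(s)
            if s <= prev_end:
                continue
            out.append(GenomicInterval(chrom, s, s + block))
            prev_end = s + block
    return IntervalSet(out, genome, "exclusion")
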