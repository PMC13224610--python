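"""Genomic interval model and the interval algebra used by every pipeline stage.

All coordinates are 0-based half-open ([start, end)), the BED convention.
Point events (DSB breakends, SNVs) are width-1 intervals at the recorded
nucleotide.  The central primitive is :func:`window_overlap`, which extends
each query interval symmetrically by ``w`` bp and reports the query once if
the extension intersects at least one base of any feature — the semantics of
``bedtools window -u -w``.  Everything downstream (percent-within, distance
bins, confounder exclusion) is defined in terms of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeDef",
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "window_overlap",
    "subtract_within",
    "merge_overlapping",
    "consensus",
    "shuffle",
    "distance_counts",
]


class ValidationError(ValueError):
    """Raised when inputs violate an interval-algebra precondition."""


class BedParseError(ValueError):
    """Raised on malformed BED/TSV records; carries the offending line number."""


@dataclass(frozen=True)
class GenomeDef:
    """Reference coordinate space: ordered chromosomes with lengths in bp.

    Optionally carries a handle to per-chromosome sequence (any mapping from
    chromosome name to string-like, e.g. a ``pyfaidx.Fasta``).
    """

    chroms: tuple[tuple[str, int], ...]
    sequences: object | None = field(default=None, compare=False, hash=False)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome definition")
        for name, length in self.chroms:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]], sequences=None) -> "GenomeDef":
        return cls(tuple((str(c), int(n)) for c, n in pairs), sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a chromosome; width-1 for point events."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Intervals grouped by chromosome, sorted by (start, end) within each group.

    Duplicate intervals are permitted: two breakends mapped to the same base
    are two events.  ``role`` is a free tag ('events', 'features', 'exclusion')
    used only for provenance.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: GenomeDef | None = None,
        role: str = "events",
    ) -> None:
        self.genome = genome
        self.role = role
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if genome is not None:
                length = genome.lengths.get(iv.chrom)
                if length is None:
                    raise ValidationError(f"interval chromosome {iv.chrom!r} not in genome")
                if iv.end > length:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {length}"
                    )
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = by_chrom
        self._arrays: dict[str, np.ndarray] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def coords(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) pairs for one chromosome (cached)."""
        arr = self._arrays.get(chrom)
        if arr is None:
            ivs = self._by_chrom.get(chrom, [])
            arr = np.array([(iv.start, iv.end) for iv in ivs], dtype=np.int64).reshape(-1, 2)
            self._arrays[chrom] = arr
        return arr

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self], dtype=np.int64)

    def with_role(self, role: str) -> "IntervalSet":
        out = IntervalSet((), self.genome, role)
        out._by_chrom = self._by_chrom
        return out

    def total_bases(self) -> int:
        """Number of genomic bases covered by the union of intervals."""
        merged = merge_overlapping(self, gap=-1)
        return int(sum(iv.width for iv in merged))


# -- I/O ---------------------------------------------------------------------


def read_chrom_sizes(path: str) -> GenomeDef:
    """Read a two-column (name, length) chromosome-sizes table."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected two columns (name, length)")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer length {fields[1]!r}") from exc
    return GenomeDef.from_pairs(pairs)


def read_bed(
    path: str,
    genome: GenomeDef | None = None,
    role: str = "events",
    strict: bool = True,
) -> tuple["IntervalSet", int]:
    """Read BED3+ into an IntervalSet.

    Returns (interval set, number of records skipped).  Records on chromosomes
    absent from ``genome`` raise in strict mode and are skipped (counted) in
    lenient mode.  Malformed coordinates always raise, naming the line.
    """
    known = genome.lengths if genome is not None else None
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) (zero/negative width)"
                )
            if known is not None and chrom not in known:
                if strict:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                skipped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(intervals, genome, role), skipped


def write_bed(iset: IntervalSet, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write BED6 (name/score/strand filled with '.', 0 when missing)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for iv in iset:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# -- algebra -----------------------------------------------------------------


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValidationError("interval sets are defined on different genomes")


def _overlap_mask(query: IntervalSet, features: IntervalSet, w: int) -> dict[str, np.ndarray]:
    """Per-chromosome boolean mask: query interval's w-extension hits >=1 feature base."""
    merged = merge_overlapping(features, gap=0)
    masks: dict[str, np.ndarray] = {}
    for chrom in query.chroms:
        q = query.coords(chrom)
        f = merged.coords(chrom)
        if len(q) == 0:
            masks[chrom] = np.zeros(0, dtype=bool)
            continue
        if len(f) == 0:
            masks[chrom] = np.zeros(len(q), dtype=bool)
            continue
        qs = q[:, 0] - w
        qe = q[:, 1] + w
        # merged features sorted, disjoint: the first feature with end > qs
        # overlaps iff its start < qe.  Clipping qs at 0 is unnecessary for
        # the comparison (feature ends are > 0).
        idx = np.searchsorted(f[:, 1], qs, side="right")
        hit = (idx < len(f)) & (f[np.minimum(idx, len(f) - 1), 0] < qe)
        masks[chrom] = hit
    return masks


def window_overlap(query: IntervalSet, features: IntervalSet, w: int) -> IntervalSet:
    """Subset of query intervals whose [start-w, end+w) extension intersects a feature.

    Each query interval is reported at most once, with original coordinates
    (``bedtools window -u -w`` semantics).  Duplicates in the query are
    independent events and are reported individually.
    """
    if w < 0:
        raise ValidationError(f"window width must be >= 0, got {w}")
    _check_same_genome(query, features)
    masks = _overlap_mask(query, features, w)
    kept = [
        iv
        for chrom in query.chroms
        for iv, hit in zip(query.by_chrom(chrom), masks[chrom])
        if hit
    ]
    return IntervalSet(kept, query.genome, query.role)


def subtract_within(query: IntervalSet, features: IntervalSet, w: int) -> IntervalSet:
    """Exact complement of :func:`window_overlap` within the query set."""
    if w < 0:
        raise ValidationError(f"window width must be >= 0, got {w}")
    _check_same_genome(query, features)
    masks = _overlap_mask(query, features, w)
    kept = [
        iv
        for chrom in query.chroms
        for iv, hit in zip(query.by_chrom(chrom), masks[chrom])
        if not hit
    ]
    return IntervalSet(kept, query.genome, query.role)


def merge_overlapping(iset: IntervalSet, gap: int = 0) -> IntervalSet:
    """Fuse intervals whose separation is <= gap into maximal runs.

    gap=0 fuses book-ended intervals ([a,b) + [b,c) -> [a,c)), matching
    ``bedtools merge``.  gap=-1 fuses only genuinely overlapping intervals
    (used internally for base counting).  Output is sorted and disjoint;
    strand/name/score are dropped.
    """
    out: list[GenomicInterval] = []
    for chrom in iset.chroms:
        ivs = iset.by_chrom(chrom)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(out, iset.genome, iset.role)


def consensus(sets: Sequence[IntervalSet], min_support: int) -> IntervalSet:
    """Genomic bases covered by >= min_support of the input sets, as merged intervals.

    The replicate-consensus operation: a base covered several times within one
    replicate still counts once for that replicate.
    """
    if not 1 <= min_support <= len(sets):
        raise ValidationError(
            f"min_support must be in [1, {len(sets)}], got {min_support}"
        )
    genome = next((s.genome for s in sets if s.genome is not None), None)
    merged_sets = [merge_overlapping(s, gap=-1) for s in sets]
    all_chroms = sorted({c for s in merged_sets for c in s.chroms})
    out: list[GenomicInterval] = []
    for chrom in all_chroms:
        events: list[tuple[int, int]] = []
        for s in merged_sets:
            for iv in s.by_chrom(chrom):
                events.append((iv.start, 1))
                events.append((iv.end, -1))
        # group deltas per position so a set ending exactly where another
        # starts does not transiently close a run
        deltas: dict[int, int] = {}
        for pos, delta in events:
            deltas[pos] = deltas.get(pos, 0) + delta
        depth = 0
        run_start: int | None = None
        for pos in sorted(deltas):
            depth += deltas[pos]
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                if pos > run_start:
                    out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return IntervalSet(out, genome, "features")


def shuffle(
    iset: IntervalSet,
    genome: GenomeDef,
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator = 0,
    preserve_chrom: bool = False,
    max_tries: int = 1000,
) -> IntervalSet:
    """Relocate each interval uniformly at random over valid placements.

    Widths and interval count are preserved.  Unless ``preserve_chrom``, the
    target chromosome is drawn with probability proportional to its length
    (``bedtools shuffle`` default); placements intersecting ``exclude`` are
    rejection-sampled up to ``max_tries`` per interval.  Deterministic given
    the seed; pass a Generator to draw from an existing stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [c for c, _ in genome.chroms]
    name_index = {c: i for i, c in enumerate(names)}
    sizes = np.array([n for _, n in genome.chroms], dtype=np.int64)
    probs = sizes / sizes.sum()
    excl_coords: dict[int, np.ndarray] = {}
    if exclude is not None and len(exclude) > 0:
        merged_excl = merge_overlapping(exclude, gap=0)
        for c in merged_excl.chroms:
            if c in name_index:
                excl_coords[name_index[c]] = merged_excl.coords(c)

    source = list(iset)
    n = len(source)
    widths = np.array([iv.width for iv in source], dtype=np.int64)
    src_chrom = np.array([name_index[iv.chrom] for iv in source], dtype=np.int64)

    chrom_idx = np.zeros(n, dtype=np.int64)
    starts = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    # Rejection sampling in vectorized rounds: every pending interval gets a
    # fresh (chromosome, start) proposal each round, so per-interval attempt
    # counts match the scalar formulation.
    for _ in range(max_tries):
        if len(pending) == 0:
            break
        if preserve_chrom:
            prop_chrom = src_chrom[pending]
        else:
            prop_chrom = rng.choice(len(names), size=len(pending), p=probs)
        room = sizes[prop_chrom] - widths[pending]
        fits = room >= 0
        prop_start = rng.integers(0, np.maximum(room, 0) + 1)
        ok = fits.copy()
        for ci in np.unique(prop_chrom):
            f = excl_coords.get(int(ci))
            if f is None or len(f) == 0:
                continue
            sel = prop_chrom == ci
            s = prop_start[sel]
            e = s + widths[pending[sel]]
            idx = np.searchsorted(f[:, 1], s, side="right")
            blocked = (idx < len(f)) & (f[np.minimum(idx, len(f) - 1), 0] < e)
            sub = ok[sel]
            sub &= ~blocked
            ok[sel] = sub
        accepted = pending[ok]
        chrom_idx[accepted] = prop_chrom[ok]
        starts[accepted] = prop_start[ok]
        pending = pending[~ok]
    if len(pending) > 0:
        iv = source[pending[0]]
        raise ValidationError(
            f"no valid shuffle placement for {iv.chrom}:{iv.start}-{iv.end} "
            f"within {max_tries} tries"
        )
    out = [
        replace(iv, chrom=names[chrom_idx[i]], start=int(starts[i]), end=int(starts[i] + widths[i]))
        for i, iv in enumerate(source)
    ]
    return IntervalSet(out, iset.genome, iset.role)


def distance_counts(
    query: IntervalSet, features: IntervalSet, edges: Sequence[int]
) -> np.ndarray:
    """Counts of query intervals whose nearest-feature window falls in each distance bin.

    ``edges`` are ascending maximum distances; bin i counts queries reported
    by window_overlap at edges[i] but not at edges[i-1] (the first bin uses
    edges[0] alone, edge 0 meaning direct intersection).  Bins are mutually
    exclusive and sum to the count within the outermost edge.
    """
    edges = list(edges)
    if not edges or any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] < 0:
        raise ValidationError(f"edges must be ascending and non-negative, got {edges}")
    cum = np.array(
        [len(window_overlap(query, features, w)) for w in edges], dtype=np.int64
    )
    return np.diff(cum, prepend=0)
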