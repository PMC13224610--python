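"""Canonical predicted-quadruplex-sequence (PQS) scanner.

Detects the canonical G4 motif — four or more runs of >= 3 guanines separated
by 1-7 nt loops — on both strands of a nucleotide sequence.  This is a
motif-grammar scanner, not a thermodynamic or machine-learning scorer: the
downstream enrichment machinery accepts any externally produced G4 BED track
interchangeably, and this scanner exists so that the pipeline is exercisable
on synthetic genomes with planted, provably recoverable motifs.

Minus-strand motifs (C-run mirror images) are found by scanning the reverse
complement with the same grammar and mirroring coordinates, which makes the
collapsed track exactly symmetric under reverse complementation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import GenomeDef, GenomicInterval, IntervalSet, ValidationError, merge_overlapping

__all__ = ["PQSParams", "PQSHit", "scan_sequence", "scan_genome", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]*$")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PQSParams:
    """Canonical PQS grammar parameters.

    Defaults encode the widely used definition: four tracts of >= 3 G,
    loops of 1-7 nt, total motif length capped at 50 bp.
    """

    min_tract: int = 3
    n_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 7
    max_len: int = 50
    scan_both_strands: bool = True
    collapse_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_tract < 2:
            raise ValidationError("min_tract must be >= 2")
        if self.n_tracts < 2:
            raise ValidationError("n_tracts must be >= 2")
        if not 0 <= self.loop_min <= self.loop_max:
            raise ValidationError("need 0 <= loop_min <= loop_max")
        floor = self.n_tracts * self.min_tract + (self.n_tracts - 1) * self.loop_min
        if self.max_len < floor:
            raise ValidationError(
                f"max_len {self.max_len} below minimal motif length {floor}"
            )

    @property
    def pattern(self) -> re.Pattern:
        # Greedy tracts, greedy loops; N matches neither, so any ambiguity
        # code breaks a candidate motif.
        t = f"G{{{self.min_tract},}}"
        loop = f"[ACGT]{{{self.loop_min},{self.loop_max}}}"
        return re.compile(f"{t}(?:{loop}{t}){{{self.n_tracts - 1}}}")


@dataclass(frozen=True)
class PQSHit:
    """One detected motif; interval in + strand coordinates, sequence as matched."""

    interval: GenomicInterval
    sequence: str
    tract_starts: tuple[int, ...] = field(default=())


def _scan_plus(seq: str, chrom: str, params: PQSParams) -> list[PQSHit]:
    """Leftmost-greedy non-overlapping matches of the G-tract grammar on one strand."""
    pat = params.pattern
    tract = re.compile(f"G{{{params.min_tract},}}")
    hits: list[PQSHit] = []
    pos = 0
    n = len(seq)
    while pos < n:
        m = pat.search(seq, pos)
        if m is None:
            break
        s, e = m.start(), m.end()
        if e - s > params.max_len:
            # regex found a sprawling match; retry within a capped window so a
            # shorter valid motif starting at or after s is still reported
            sub = pat.search(seq[s : s + params.max_len])
            if sub is not None and sub.end() - sub.start() <= params.max_len:
                s2, e2 = s + sub.start(), s + sub.end()
                matched = seq[s2:e2]
                tracts = tuple(t.start() for t in tract.finditer(matched))
                hits.append(
                    PQSHit(GenomicInterval(chrom, s2, e2, "+"), matched, tracts)
                )
                pos = e2
            else:
                pos = s + 1
            continue
        matched = seq[s:e]
        tracts = tuple(t.start() for t in tract.finditer(matched))
        hits.append(PQSHit(GenomicInterval(chrom, s, e, "+"), matched, tracts))
        pos = e
    return hits


def scan_sequence(seq: str, chrom: str, params: PQSParams | None = None) -> list[PQSHit]:
    """Scan one sequence for canonical PQS on the + strand and (optionally) the - strand.

    Minus-strand hits are reported in + strand coordinates with strand '-';
    their stored sequence is the motif as read on the - strand (G-rich).
    """
    params = params or PQSParams()
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValidationError(f"invalid characters in sequence: {bad}")
    hits = _scan_plus(seq, chrom, params)
    if params.scan_both_strands:
        n = len(seq)
        for h in _scan_plus(revcomp(seq), chrom, params):
            iv = h.interval
            mirrored = GenomicInterval(chrom, n - iv.end, n - iv.start, "-")
            hits.append(PQSHit(mirrored, h.sequence, h.tract_starts))
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.interval.strand))
    return hits


def scan_genome(
    genome: GenomeDef,
    params: PQSParams | None = None,
    sequences: object | None = None,
) -> IntervalSet:
    """Per-chromosome scan; returns the PQS feature track.

    ``sequences`` (or ``genome.sequences``) maps chromosome name to sequence,
    e.g. a ``pyfaidx.Fasta``.  With ``collapse_strands`` (default) + and -
    hits are merged (gap=0) into an unstranded track; otherwise stranded
    intervals are returned with score = motif width.
    """
    params = params or PQSParams()
    source = sequences if sequences is not None else genome.sequences
    if source is None:
        raise ValidationError("no sequence source attached to genome")
    intervals = []
    for chrom, length in genome.chroms:
        try:
            seq = str(source[chrom][:])
        except KeyError as exc:
            raise ValidationError(f"chromosome {chrom!r} missing from sequence source") from exc
        if len(seq) != length:
            raise ValidationError(
                f"sequence length {len(seq)} for {chrom!r} does not match genome ({length})"
            )
        for h in scan_sequence(seq, chrom, params):
            iv = h.interval
            intervals.append(
                GenomicInterval(chrom, iv.start, iv.end, iv.strand, score=float(iv.width))
            )
    track = IntervalSet(intervals, genome, "features")
    if params.collapse_strands:
        track = merge_overlapping(track, gap=0)
    return track
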