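"""Feature-category assignment, TSS-distance bins, and confounder-exclusion re-analysis.

Events are assigned to one of five categories with fixed priority
(Promoter > Exon > Intron > Downstream > Distal Intergenic).  The promoter is
a configurable window around the TSS on the gene strand (default 3 kb each
side); Downstream is a window past the gene end.  The category set is
deliberately simplified — gene spans plus optional exons, no UTR split —
because the pipeline consumes interval gene models rather than full
transcript structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    ValidationError,
    subtract_within,
)
from .stats import ChiSquareResult, build_contingency, pearson_chi_square

__all__ = [
    "Gene",
    "GeneAnnotation",
    "FeatureAssignment",
    "assign_features",
    "tss_distance_bins",
    "stratified_exclusion_analysis",
]

CATEGORIES = ("Promoter", "Exon", "Intron", "Downstream", "Distal Intergenic")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # gene span, half-open
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside span")

    @property
    def tss(self) -> int:
        """TSS coordinate (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("annotation contains no genes")

    @classmethod
    def from_gff3(cls, path: str) -> "GeneAnnotation":
        """Read gene and exon features from GFF3 via gffutils.

        GFF3 is 1-based inclusive; coordinates are converted to the internal
        0-based half-open convention here.  Exons are linked to genes through
        the Parent hierarchy (transcripts in between are followed).
        """
        import gffutils

        db = gffutils.create_db(
            path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
        )
        out = []
        for g in db.features_of_type("gene"):
            gid = g.id
            exons = sorted(
                {(e.start - 1, e.end) for e in db.children(g, featuretype="exon")}
            )
            out.append(
                Gene(gid, g.seqid, g.strand, g.start - 1, g.end, tuple(exons))
            )
        return cls(out)

    @classmethod
    def from_bed12(cls, path: str) -> "GeneAnnotation":
        """Read gene models from BED12 (blocks become exons)."""
        out = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    raise ValidationError(f"{path}:{lineno}: BED12 requires 12 columns")
                chrom, start, end, name, _, strand = f[:6]
                start, end = int(start), int(end)
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offsets, sizes)
                )
                out.append(Gene(name, chrom, strand, start, end, exons))
        return cls(out)


@dataclass
class FeatureAssignment:
    """Per-event category and signed nearest-TSS distance (negative = upstream)."""

    events: list[GenomicInterval]
    categories: list[str]
    tss_distances: list[int]
    nearest_gene: list[str]

    def distribution(self) -> pd.Series:
        counts = pd.Series(self.categories).value_counts()
        dist = counts.reindex(CATEGORIES, fill_value=0)
        return 100.0 * dist / dist.sum()


def _event_position(iv: GenomicInterval) -> int:
    """Representative coordinate of an event: its midpoint base."""
    return iv.start + (iv.end - iv.start - 1) // 2


def _signed_tss_distance(pos: int, gene: Gene) -> int:
    """Signed distance on the gene strand; negative = upstream of the TSS."""
    if gene.strand == "+":
        return pos - gene.tss
    return gene.tss - pos


def assign_features(
    events: IntervalSet,
    annotation: GeneAnnotation,
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_limit: int = 3000,
) -> FeatureAssignment:
    """Assign each event to one category and record its nearest-TSS distance.

    Nearest-TSS ties are broken by lexicographic gene id for determinism.
    """
    up, down = promoter_window
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in sorted(annotation.genes, key=lambda g: g.gene_id):
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    ev_list, cats, dists, nearest = [], [], [], []
    for iv in events:
        pos = _event_position(iv)
        chrom_genes = genes_by_chrom.get(iv.chrom, [])
        best_gene: Gene | None = None
        best_abs = None
        category = "Distal Intergenic"
        in_promoter = in_exon = in_intron = in_downstream = False
        for g in chrom_genes:
            d = _signed_tss_distance(pos, g)
            if best_abs is None or abs(d) < best_abs:
                best_abs, best_gene = abs(d), g
            if -up <= d <= down:
                in_promoter = True
            if g.start <= pos < g.end:
                if any(s <= pos < e for s, e in g.exons):
                    in_exon = True
                elif g.exons:
                    in_intron = True
                else:
                    in_intron = True  # span without exon model: treat interior as intron
            # downstream: within downstream_limit past the gene end on its strand
            if g.strand == "+" and g.end <= pos < g.end + downstream_limit:
                in_downstream = True
            if g.strand == "-" and g.start - downstream_limit <= pos < g.start:
                in_downstream = True
        if in_promoter:
            category = "Promoter"
        elif in_exon:
            category = "Exon"
        elif in_intron:
            category = "Intron"
        elif in_downstream:
            category = "Downstream"
        ev_list.append(iv)
        cats.append(category)
        if best_gene is None:
            dists.append(0)
            nearest.append("")
        else:
            dists.append(_signed_tss_distance(pos, best_gene))
            nearest.append(best_gene.gene_id)
    if not ev_list:
        raise ValidationError("no events to assign")
    return FeatureAssignment(ev_list, cats, dists, nearest)


def tss_distance_bins(
    events: IntervalSet,
    annotation: GeneAnnotation,
    edges_kb: list[float] = (1, 3, 5, 10, 100),
) -> pd.Series:
    """Percent of events per |nearest-TSS distance| bin; last bin is open-ended."""
    edges = [e * 1000 for e in edges_kb]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("edges must be ascending")
    fa = assign_features(events, annotation)
    absd = np.abs(np.array(fa.tss_distances))
    labels = []
    prev = 0
    for e in edges:
        labels.append(f"{prev / 1000:g}-{e / 1000:g} kb")
        prev = e
    labels.append(f">{edges[-1] / 1000:g} kb")
    # a distance exactly on an edge belongs to the lower bin (searchsorted left)
    idx = np.searchsorted(edges, absd, side="left")
    counts = np.bincount(idx, minlength=len(labels))[: len(labels)]
    return pd.Series(100.0 * counts / counts.sum(), index=labels)


def stratified_exclusion_analysis(
    events_by_condition: dict[str, IntervalSet],
    features: IntervalSet,
    confounders: list[IntervalSet],
    w: int,
    confounder_w: int | None = None,
) -> tuple[ChiSquareResult, dict[str, int]]:
    """Re-run the pooled contingency analysis after dropping confounded events.

    Events within ``confounder_w`` (default: same as ``w``) of ANY confounder
    track are removed from every condition; the chi-square is recomputed on
    the remainder.  Returns the result and retained counts per condition.
    """
    if not confounders:
        raise ValidationError("at least one confounder track is required")
    cw = w if confounder_w is None else confounder_w
    retained: dict[str, IntervalSet] = {}
    counts: dict[str, int] = {}
    for label, events in events_by_condition.items():
        kept = events
        for track in confounders:
            kept = subtract_within(kept, track, cw)
        if len(kept) == 0:
            raise ValidationError(
                f"all events of condition {label!r} removed by confounder exclusion"
            )
        retained[label] = kept
        counts[label] = len(kept)
    table = build_contingency(retained, features, w)
    return pearson_chi_square(table), counts
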