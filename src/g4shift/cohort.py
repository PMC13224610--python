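"""Patient-cohort analysis: mutation loading, two-gene group stratification,
per-sample percent of mutations near G4 features, shuffled controls with
blacklist exclusion, subsampling of larger groups, and rank-based comparison.

Samples mutant in both stratifying genes are excluded outright ("double
mutant") to avoid confounded group assignment; the remaining samples form a
partition over {geneA_mutant, geneB_mutant, neither}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomeDef, GenomicInterval, IntervalSet, ValidationError, shuffle
from .stats import kruskal_dunn, percent_within

__all__ = [
    "MutationRecord",
    "SampleGrouping",
    "load_mutations",
    "assign_groups",
    "per_sample_percent",
    "subsample_group",
    "cohort_shuffled_control",
    "run_cohort_analysis",
]

VARIANT_CLASSES = ("SNV", "MNV", "INS", "DEL")
GROUPS = ("geneA_mutant", "geneB_mutant", "neither", "excluded_double")


@dataclass(frozen=True)
class MutationRecord:
    sample: str
    interval: GenomicInterval
    variant_class: str
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if self.variant_class == "SNV" and self.interval.width != 1:
            raise ValidationError("SNV records must have width 1")


@dataclass(frozen=True)
class SampleGrouping:
    """Partition of samples over the four cohort groups."""

    assignment: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        return sorted(s for s, g in self.assignment.items() if g == group)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in GROUPS}


def load_mutations(
    path: str,
    dialect: str,
    genome: GenomeDef | None = None,
    strict: bool = True,
) -> tuple[list[MutationRecord], int]:
    """Read a mutation TSV into records with 0-based half-open coordinates.

    ``dialect`` is 'maf_like_1based' (start is 1-based inclusive, converted at
    this boundary) or 'bed_like_0based'.  Returns (records, skipped count);
    records on unknown chromosomes raise in strict mode, are skipped otherwise.
    """
    if dialect not in ("maf_like_1based", "bed_like_0based"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    known = genome.lengths if genome is not None else None
    records: list[MutationRecord] = []
    skipped = 0
    offset = 1 if dialect == "maf_like_1based" else 0
    has_ref = "ref" in df.columns
    has_alt = "alt" in df.columns
    for i, row in enumerate(df.to_dict("records"), 2):  # data starts on line 2
        chrom = str(row["chrom"])
        if known is not None and chrom not in known:
            if strict:
                raise ValidationError(f"{path}:{i}: unknown chromosome {chrom!r}")
            skipped += 1
            continue
        try:
            start = int(row["start"]) - offset
            end = int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{i}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise ValidationError(f"{path}:{i}: invalid interval [{start}, {end})")
        ref = row.get("ref") if has_ref else None
        alt = row.get("alt") if has_alt else None
        records.append(
            MutationRecord(
                str(row["sample"]),
                GenomicInterval(chrom, start, end),
                str(row["class"]),
                None if ref is None or pd.isna(ref) else str(ref),
                None if alt is None or pd.isna(alt) else str(alt),
            )
        )
    return records, skipped


def assign_groups(status: pd.DataFrame) -> SampleGrouping:
    """Partition samples by the two gene-status flags.

    ``status`` has columns (sample, geneA_status, geneB_status) with boolean
    flags; double mutants go to 'excluded_double'.
    """
    required = {"sample", "geneA_status", "geneB_status"}
    missing = required - set(status.columns)
    if missing:
        raise ValidationError(f"status table missing columns {sorted(missing)}")
    out = {}
    for row in status.itertuples(index=False):
        a, b = bool(row.geneA_status), bool(row.geneB_status)
        if a and b:
            group = "excluded_double"
        elif a:
            group = "geneA_mutant"
        elif b:
            group = "geneB_mutant"
        else:
            group = "neither"
        out[str(row.sample)] = group
    return SampleGrouping(out)


def _records_by_sample(
    records: list[MutationRecord], genome: GenomeDef | None
) -> dict[str, IntervalSet]:
    by_sample: dict[str, list[GenomicInterval]] = {}
    for r in records:
        by_sample.setdefault(r.sample, []).append(r.interval)
    return {
        s: IntervalSet(ivs, genome, "events") for s, ivs in sorted(by_sample.items())
    }


def per_sample_percent(
    records: list[MutationRecord],
    features: IntervalSet,
    w: int,
    genome: GenomeDef | None = None,
) -> pd.DataFrame:
    """Percent of each sample's mutations within w of a feature.

    Samples with zero mutations cannot appear in ``records``; callers passing
    a sample list separately should treat absent samples as dropped.
    """
    rows = []
    for sample, events in _records_by_sample(records, genome).items():
        rows.append(
            {
                "sample": sample,
                "n_mutations": len(events),
                "percent_within": percent_within(events, features, w),
            }
        )
    if not rows:
        raise ValidationError("no mutation records supplied")
    return pd.DataFrame(rows)


def subsample_group(
    sample_ids: list[str], n: int, seed: int = 0
) -> list[str]:
    """Uniform subsample without replacement; deterministic given seed."""
    if n > len(sample_ids):
        raise ValidationError(f"cannot subsample {n} from group of {len(sample_ids)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sample_ids), size=n, replace=False)
    return [sample_ids[i] for i in sorted(idx)]


def cohort_shuffled_control(
    records: list[MutationRecord],
    genome: GenomeDef,
    blacklist: IntervalSet | None,
    features: IntervalSet,
    w: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffle each sample's mutations (widths preserved, blacklist avoided)
    and recompute its percent-within."""
    rows = []
    for r, (sample, events) in enumerate(_records_by_sample(records, genome).items()):
        shuffled = shuffle(events, genome, blacklist, seed=seed + r)
        rows.append(
            {
                "sample": sample,
                "n_mutations": len(events),
                "shuffled_percent": percent_within(shuffled, features, w),
            }
        )
    return pd.DataFrame(rows)


def run_cohort_analysis(
    records: list[MutationRecord],
    status: pd.DataFrame,
    features: IntervalSet,
    genome: GenomeDef,
    w: int = 5,
    blacklist: IntervalSet | None = None,
    subsample_seed: int = 0,
    shuffle_seed: int = 0,
    n_shuffles: int = 1,
) -> dict:
    """Full cohort procedure: group, drop double mutants, per-sample percents,
    shuffled controls, subsampling of larger groups to the smallest retained
    group's size, and Kruskal-Wallis + Dunn comparison across the three
    retained groups."""
    grouping = assign_groups(status)
    retained_groups = ("geneA_mutant", "geneB_mutant", "neither")
    keep = {s for s, g in grouping.assignment.items() if g != "excluded_double"}
    kept_records = [r for r in records if r.sample in keep]
    dropped_no_mut = sorted(
        keep - {r.sample for r in kept_records}
    )
    if dropped_no_mut:
        warnings.warn(
            f"dropping {len(dropped_no_mut)} zero-mutation samples: {dropped_no_mut[:5]}"
        )
    percents = per_sample_percent(kept_records, features, w, genome)
    percents["group"] = percents["sample"].map(grouping.assignment)

    ctrl = cohort_shuffled_control(
        kept_records, genome, blacklist, features, w, seed=shuffle_seed
    )
    percents = percents.merge(ctrl[["sample", "shuffled_percent"]], on="sample")

    medians = percents.groupby("group")["percent_within"].median().to_dict()
    group_values = {
        g: percents.loc[percents["group"] == g, "percent_within"].tolist()
        for g in retained_groups
        if (percents["group"] == g).any()
    }
    if len(group_values) >= 3:
        h, p_omni, pairwise = kruskal_dunn(group_values)
    else:
        h, p_omni, pairwise = float("nan"), float("nan"), []

    sizes = {g: len(v) for g, v in group_values.items()}
    target = min(sizes.values()) if sizes else 0
    subsample_medians = {}
    subsets = {}
    for i, g in enumerate(sorted(sizes)):
        ids = sorted(percents.loc[percents["group"] == g, "sample"])
        sub = subsample_group(ids, target, seed=subsample_seed + i)
        subsets[g] = sub
        subsample_medians[g] = float(
            percents.set_index("sample").loc[sub, "percent_within"].median()
        )
    return {
        "grouping": grouping,
        "per_sample": percents,
        "group_medians": medians,
        "kruskal_h": h,
        "kruskal_p": p_omni,
        "dunn_pairwise": pairwise,
        "subsample_target": target,
        "subsample_ids": subsets,
        "subsample_medians": subsample_medians,
        "excluded_double": grouping.samples_in("excluded_double"),
        "zero_mutation_dropped": dropped_no_mut,
    }
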