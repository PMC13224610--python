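"""Enrichment statistics: percent-within-window, shuffled-control percents,
pooled 2x2 Pearson chi-square with residuals, pseudocount fold changes,
distance-decay profiles, and the rank-based group tests.

The 2x2 contingency analysis follows the mosaic-plot convention: expected
counts from the row/column marginals, statistic = sum of squared Pearson
residuals (O-E)/sqrt(E), no continuity correction — residuals are defined
without it, and they are the displayed quantity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .intervals import (
    GenomeDef,
    IntervalSet,
    ValidationError,
    distance_counts,
    shuffle,
    window_overlap,
)

__all__ = [
    "ContingencyTable2x2",
    "ChiSquareResult",
    "EnrichmentSummary",
    "DistanceProfile",
    "percent_within",
    "shuffled_control_percent",
    "build_contingency",
    "pearson_chi_square",
    "fold_change_pseudocount",
    "rank_sum_test",
    "kruskal_dunn",
    "wilcoxon_one_sample",
    "distance_profile",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed counts: rows = condition, columns = (associated, not associated)."""

    observed: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("condition_1", "condition_2")
    col_labels: tuple[str, str] = ("associated", "not_associated")

    def __post_init__(self) -> None:
        o = np.asarray(self.observed)
        if o.shape != (2, 2) or (o < 0).any():
            raise ValidationError("contingency table must be 2x2 with non-negative counts")
        if o.sum() == 0:
            raise ValidationError("contingency table grand total must be > 0")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.observed, dtype=np.float64)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: tuple[tuple[float, float], tuple[float, float]]
    residuals: tuple[tuple[float, float], tuple[float, float]]
    table: ContingencyTable2x2 | None = field(default=None, compare=False)


@dataclass
class EnrichmentSummary:
    """Per-sample observed and shuffled-control percents for one feature track."""

    w: int
    feature_track: str
    samples: list[str]
    conditions: list[str]
    n_events: list[int]
    n_associated: list[int]
    percents: list[float]
    shuffled_percents: list[float]
    fold_changes: list[float]
    seeds: list[int]

    def condition_percents(self, condition: str) -> list[float]:
        return [p for p, c in zip(self.percents, self.conditions) if c == condition]


@dataclass
class DistanceProfile:
    """Per-sample distance-bin counts and percents (of that sample's total events)."""

    edges: list[int]
    samples: list[str]
    counts: np.ndarray  # (n_samples, n_bins)
    percents: np.ndarray
    totals: list[int]


# -- window statistics -------------------------------------------------------


def percent_within(events: IntervalSet, features: IntervalSet, w: int) -> float:
    """100 * fraction of events whose w-extension intersects >= 1 feature base."""
    n = len(events)
    if n == 0:
        raise ValidationError("percent_within undefined for an empty event set")
    return 100.0 * len(window_overlap(events, features, w)) / n


def shuffled_control_percent(
    events: IntervalSet,
    features: IntervalSet,
    genome: GenomeDef,
    exclude: IntervalSet | None,
    w: int,
    n_shuffles: int = 1,
    seed: int = 0,
) -> list[float]:
    """Percent-within for n_shuffles independent shuffled relocations of the events.

    Replicate r draws from stream seed + r, so individual replicates are
    reproducible in isolation.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    out = []
    for r in range(n_shuffles):
        shuffled = shuffle(events, genome, exclude, seed=seed + r)
        out.append(percent_within(shuffled, features, w))
    return out


def build_contingency(
    events_by_condition: dict[str, IntervalSet],
    features: IntervalSet,
    w: int,
) -> ContingencyTable2x2:
    """Pool each condition's events into one row: (associated, not associated)."""
    if len(events_by_condition) != 2:
        raise ValidationError("contingency analysis needs exactly two conditions")
    rows = []
    labels = []
    for label, events in events_by_condition.items():
        n = len(events)
        if n == 0:
            raise ValidationError(f"condition {label!r} has no events")
        k = len(window_overlap(events, features, w))
        rows.append((k, n - k))
        labels.append(label)
    return ContingencyTable2x2(tuple(rows), tuple(labels))


def pearson_chi_square(table: ContingencyTable2x2) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Residuals (O-E)/sqrt(E) are the mosaic-plot shading values; the statistic
    is their sum of squares.
    """
    o = table.array
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("degenerate contingency table: a zero marginal")
    e = np.outer(row, col) / o.sum()
    resid = (o - e) / np.sqrt(e)
    stat = float((resid**2).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ChiSquareResult(
        statistic=stat,
        df=1,
        p_value=p,
        expected=tuple(map(tuple, e)),
        residuals=tuple(map(tuple, resid)),
        table=table,
    )


def fold_change_pseudocount(obs_count: int, ctrl_count: int) -> float:
    """(obs + 1) / (ctrl + 1); the pseudocount prevents division by zero."""
    if obs_count < 0 or ctrl_count < 0:
        raise ValidationError("counts must be non-negative")
    return (obs_count + 1) / (ctrl_count + 1)


# -- rank tests --------------------------------------------------------------


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_sum_test(x: list[float], y: list[float]) -> float:
    """Two-sided Mann-Whitney p.

    Exact null distribution when both samples have size <= 8 and there are no
    ties; tie-corrected normal approximation (no continuity correction)
    otherwise.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([xa, ya])
    exact = len(xa) <= 8 and len(ya) <= 8 and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def wilcoxon_one_sample(x: list[float], mu0: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p for median = mu0.

    Zero deviations are dropped; exact null for n <= 15 remaining values,
    normal approximation beyond.
    """
    if len(x) == 0:
        raise ValidationError("wilcoxon_one_sample requires a non-empty sample")
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    if len(d) == 0:
        raise ValidationError("all values equal mu0: signed-rank test undefined")
    method = "exact" if len(d) <= 15 and not _has_ties(np.abs(d)) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def kruskal_dunn(
    groups: dict[str, list[float]], adjust: str = "bonferroni"
) -> tuple[float, float, list[dict]]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise comparisons.

    Returns (H statistic, omnibus p, pairwise records).  Dunn z-statistics
    compare mean pooled ranks with the tie-corrected variance; pairwise
    p-values are Bonferroni-adjusted over all pairs (the standard Dunn
    procedure).
    """
    if len(groups) < 3:
        raise ValidationError("kruskal_dunn requires >= 3 groups")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValidationError(f"group {name!r} is empty")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    h_stat, p_omni = sps.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(ranks[offsets[i] : offsets[i + 1]].mean()) for i in range(len(names))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
        pairwise.append(
            {
                "group_1": names[i],
                "group_2": names[j],
                "z": float(z),
                "p_raw": p_raw,
                "p_adjusted": p_adj,
            }
        )
    return float(h_stat), float(p_omni), pairwise


# -- distance profiles -------------------------------------------------------


def distance_profile(
    events_by_sample: dict[str, IntervalSet],
    features: IntervalSet,
    edges: list[int],
) -> DistanceProfile:
    """Per-sample distance-bin counts, as percents of each sample's total events."""
    samples = list(events_by_sample)
    counts = np.zeros((len(samples), len(edges)), dtype=np.int64)
    totals = []
    for i, s in enumerate(samples):
        events = events_by_sample[s]
        totals.append(len(events))
        counts[i] = distance_counts(events, features, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        percents = np.where(
            np.array(totals)[:, None] > 0,
            100.0 * counts / np.maximum(np.array(totals)[:, None], 1),
            0.0,
        )
    return DistanceProfile(list(edges), samples, counts, percents, totals)
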