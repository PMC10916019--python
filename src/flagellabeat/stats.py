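"""Nonparametric group comparison of per-band maximum forces.

Band-force distributions across cells are small-sample, skewed and
heteroscedastic, so groups are compared per band with the Kruskal–Wallis
rank test (omnibus) followed by Dunn's post hoc pairwise comparisons on
the pooled midranks, Bonferroni-adjusted over all pairs.  Significance is
annotated in the conventional star scheme: p <= 0.05 (*), <= 0.01 (**),
<= 0.001 (***).  Each band is tested on its own, with no cross-band
multiplicity correction — results are per-band annotations, and readers
comparing many bands should keep that in mind.

Box summaries report mean, median, quartiles (linear interpolation) and
range, matching the box-plot convention where (+) marks the mean and (-)
the median.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .spectral import BandScheme, make_band_scheme

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_label(p: float) -> str:
    """Map an (adjusted) p-value to the star annotation, 'ns' if p > 0.05."""
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class GroupComparisonResult:
    band_label: str
    groups: tuple[GroupSummary, ...]
    kw_H: float
    kw_p: float
    dunn_pairs: tuple[tuple[str, str, float], ...]
    stars: dict[tuple[str, str], str]


def _validate_groups(samples: list[np.ndarray]) -> list[np.ndarray]:
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if sum(s.size for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    return samples


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H on midranks with tie correction; chi-squared p.

    The fully degenerate case (every observation identical) has no rank
    information and returns ``(0.0, 1.0)``.
    """
    samples = _validate_groups(samples)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(
    samples: list[np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[int, int], float]:
    """Dunn's pairwise z-tests on pooled midranks with tie correction.

    Returns ``{(i, j): adjusted two-sided p}`` over all group-index pairs.
    ``adjust`` is ``"bonferroni"`` (multiply by the number of pairs, the
    convention paired with Dunn's comparison) or ``"none"``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    samples = _validate_groups(samples)
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [s.size for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[bounds[i]: bounds[i + 1]])) for i in range(len(samples))
    ]
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(samples)), 2))
    out: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:  # fully tied data: no evidence of separation
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        out[(i, j)] = float(p)
    return out


def summarize_box(values: np.ndarray) -> GroupSummary:
    """Six-number box summary (mean, median, Q1, Q3, min, max)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(
        name="",
        n=values.size,
        mean=float(np.mean(values)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


def compare_bands(
    table: pd.DataFrame,
    group_by: str,
    scheme: BandScheme | None = None,
    adjust: str = "bonferroni",
) -> list[GroupComparisonResult]:
    """Per-band Kruskal–Wallis + Dunn comparison across groups of cells.

    ``table`` is a band-force table (one row per cell, ``band_*_nN``
    columns); ``group_by`` names the column partitioning the cells.
    Groups appear in first-appearance order.  Raises on an empty group or
    a missing band column.
    """
    scheme = scheme or make_band_scheme()
    if group_by not in table.columns:
        raise ValueError(f"grouping column {group_by!r} not in table")
    group_names = list(dict.fromkeys(table[group_by]))
    if len(group_names) < 2:
        raise ValueError(f"grouping {group_by!r} yields fewer than 2 groups")
    grouped = {name: table[table[group_by] == name] for name in group_names}
    for name, sub in grouped.items():
        if len(sub) == 0:
            raise ValueError(f"group {name!r} is empty")

    results = []
    for band in scheme.bands:
        col = band.column_name
        if col not in table.columns:
            raise ValueError(f"band column {col!r} missing from table")
        samples = [grouped[name][col].to_numpy(dtype=float) for name in group_names]
        h, p = kruskal_wallis(samples)
        dunn = dunn_posthoc(samples, adjust=adjust)
        pairs = tuple(
            (group_names[i], group_names[j], p_adj) for (i, j), p_adj in dunn.items()
        )
        stars = {(a, b): star_label(p_adj) for a, b, p_adj in pairs}
        summaries = []
        for name, sample in zip(group_names, samples):
            s = summarize_box(sample)
            summaries.append(
                GroupSummary(
                    name=str(name), n=s.n, mean=s.mean, median=s.median,
                    q1=s.q1, q3=s.q3, min=s.min, max=s.max,
                )
            )
        results.append(
            GroupComparisonResult(
                band_label=band.label,
                groups=tuple(summaries),
                kw_H=h,
                kw_p=p,
                dunn_pairs=pairs,
                stars=stars,
            )
        )
    return results


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results: one row per band x group pair."""
    rows = []
    for res in results:
        by_name = {g.name: g for g in res.groups}
        for a, b, p_adj in res.dunn_pairs:
            rows.append(
                {
                    "band": res.band_label,
                    "group_a": a,
                    "group_b": b,
                    "n_a": by_name[a].n,
                    "n_b": by_name[b].n,
                    "median_a_nN": by_name[a].median,
                    "median_b_nN": by_name[b].median,
                    "mean_a_nN": by_name[a].mean,
                    "mean_b_nN": by_name[b].mean,
                    "kw_H": res.kw_H,
                    "kw_p": res.kw_p,
                    "dunn_p_adj": p_adj,
                    "stars": res.stars[(a, b)],
                }
            )
    return pd.DataFrame(rows)
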