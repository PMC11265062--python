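"""Cell-composition analytics: fractions, myeloid/lymphoid ratio, risk
stratification, mutation-burden normalization and group comparisons.

Risk stratification mirrors the clinical reading that high-risk MDS marrow
is depleted of mature myeloid cells (pro-neutrophils, neutrophils,
monocytes): a sample whose mature-myeloid fraction falls below a
configurable threshold is called high-risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .projection import AnnotatedSample
from .reference import Taxonomy, lineage_fraction_sets

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def fractions(labels: Sequence[str], taxonomy: Taxonomy) -> pd.Series:
    """Per-label fraction vector over the full taxonomy (absent labels -> 0)."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    unknown = set(labels) - set(taxonomy.labels)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    counts = pd.Series(labels).value_counts()
    return pd.Series(
        [counts.get(l, 0) / len(labels) for l in taxonomy.labels],
        index=list(taxonomy.labels), dtype=float, name="fraction",
    )


def ml_ratio(fraction_vector: Mapping[str, float], taxonomy: Taxonomy) -> float:
    """Myeloid/lymphoid ratio: committed myeloid output over lymphocytes.

    A lymphoid sum of zero yields +inf with an "undefined-denominator"
    warning (so tables with lymphoid-free samples still render); both sums
    zero is an error.
    """
    myeloid, lymphoid = lineage_fraction_sets(taxonomy)
    m = sum(fraction_vector.get(l, 0.0) for l in myeloid)
    l = sum(fraction_vector.get(l, 0.0) for l in lymphoid)
    if m == 0 and l == 0:
        raise ValueError("both myeloid and lymphoid fractions are zero")
    if l == 0:
        warnings.warn("undefined-denominator: lymphoid fraction is zero")
        return float("inf")
    return m / l


def mature_myeloid_fraction(fraction_vector: Mapping[str, float],
                            taxonomy: Taxonomy) -> float:
    return float(sum(fraction_vector.get(l, 0.0) for l in taxonomy.mature_myeloid))


def classify_risk(mature_fraction: float, threshold: float = 0.10) -> str:
    """High-risk iff the mature-myeloid fraction is strictly below threshold."""
    return "MDS_high" if mature_fraction < threshold else "MDS_low"


def mutation_burden(n_mutations: int, n_cells: int) -> float:
    """Per-cell mutation burden: mutations divided by cells in the sample."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    return n_mutations / n_cells


def format_significance(p: float) -> str:
    """Star convention: **** p<1e-4, *** p<1e-3, ** p<0.01, * p<0.05, else n.s.

    All thresholds strict; p exactly at a bound takes the weaker level.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    for bound, stars in STAR_LEVELS:
        if p < bound:
            return stars
    return "n.s."


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    stars: str


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    test: str = "wilcoxon",
    metric: str = "",
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``wilcoxon`` is the rank-sum (Mann–Whitney) test: exact null when the
    combined n is <= 20, otherwise the normal approximation with continuity
    correction. ``t`` is Welch's unequal-variance t-test.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (name_a, a), (name_b, b) = values_by_group.items()
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one value")
    if test == "wilcoxon":
        method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method=method, use_continuity=True)
    elif test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        metric=metric, group_a=name_a, group_b=name_b, test=test,
        statistic=float(res.statistic), p_value=p,
        stars=format_significance(p),
    )


def composition_table(
    samples: Iterable[AnnotatedSample],
    taxonomy: Taxonomy,
    risk_threshold: float = 0.10,
) -> pd.DataFrame:
    """One row per sample: fractions per label, mature-myeloid fraction,
    M/L ratio and the threshold-based risk call."""
    rows = []
    for s in samples:
        frac = fractions(list(s.label), taxonomy)
        mm = mature_myeloid_fraction(frac, taxonomy)
        row = {"sample_id": s.sample_id, "group": s.group, "n_cells": s.n_cells}
        row.update(frac.to_dict())
        row["mature_myeloid_fraction"] = mm
        row["ml_ratio"] = ml_ratio(frac, taxonomy)
        row["risk_call"] = classify_risk(mm, risk_threshold)
        rows.append(row)
    if not rows:
        raise ValueError("no samples")
    return pd.DataFrame(rows)


def compare_composition(
    table: pd.DataFrame,
    taxonomy: Taxonomy,
    group_pairs: Sequence[tuple[str, str]],
    metrics: Sequence[str] | None = None,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Group comparisons over composition metrics, one row per metric/pair."""
    if metrics is None:
        metrics = list(taxonomy.labels) + ["mature_myeloid_fraction", "ml_ratio"]
    out = []
    for metric in metrics:
        for ga, gb in group_pairs:
            va = table.loc[table["group"] == ga, metric].to_numpy()
            vb = table.loc[table["group"] == gb, metric].to_numpy()
            if len(va) == 0 or len(vb) == 0:
                continue
            c = compare_groups({ga: va, gb: vb}, test=test, metric=metric)
            out.append(vars(c))
    return pd.DataFrame(
        out, columns=["metric", "group_a", "group_b", "test",
                      "statistic", "p_value", "stars"],
    )
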