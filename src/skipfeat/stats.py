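"""Directional Mann-Whitney comparisons of feature distributions.

Each of the 14 construct features is compared between an event-exon set and
a control set with a two-sided Mann-Whitney U test; the summary grid mirrors
the event-vs-internal / event-vs-external layout for the more-skipped and
less-skipped exon sets, with direction words chosen by median comparison
and significance stars on a strict p < 0.05 / 0.01 / 0.001 / 0.0001 ladder.
No multiple-testing correction is applied to the starred grid (raw-p
reporting); Benjamini-Hochberg q-values are emitted alongside in the
long-format table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_KINDS, FEATURE_NAMES

__all__ = [
    "CONTRASTS",
    "MannWhitneyResult",
    "ComparisonCell",
    "ComparisonSummary",
    "mann_whitney",
    "stars",
    "build_summary",
]

CONTRASTS = (
    "more_vs_internal",
    "more_vs_external",
    "less_vs_internal",
    "less_vs_external",
)

#: Direction vocabulary by feature kind: (event median lower, event median higher).
DIRECTION_WORDS = {
    "length": ("Shorter", "Longer"),
    "gc": ("Lower", "Higher"),
    "score": ("Weaker", "Stronger"),
}

EXACT_MAX_N = 8  # exact enumeration p-value when both samples are this small


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    median_direction: str  # a_lower | a_higher | none


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with a median-comparison direction.

    Exact enumeration p when both samples have at most 8 observations and
    there are no ties across the pooled data; otherwise the normal
    approximation with tie and continuity correction. The direction compares
    sample medians (``none`` when equal). Inputs must be free of absent
    values and non-empty.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = np.median(a), np.median(b)
    if med_a < med_b:
        direction = "a_lower"
    elif med_a > med_b:
        direction = "a_higher"
    else:
        direction = "none"
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), direction)


def stars(p_value: float, alpha_ladder=(0.05, 0.01, 0.001, 0.0001)) -> str:
    """Significance label: NS, *, **, *** or **** on a strict ladder."""
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    label = "NS"
    for n_stars, alpha in enumerate(sorted(alpha_ladder, reverse=True), start=1):
        if p_value < alpha:
            label = "*" * n_stars
    return label


@dataclass
class ComparisonCell:
    feature: str
    contrast: str
    direction: str  # Shorter/Longer/Higher/Lower/Weaker/Stronger/NS
    p_value: float | None
    n_event: int
    n_control: int
    note: str = ""

    @property
    def stars(self) -> str:
        return "NS" if self.p_value is None else stars(self.p_value)

    def label(self) -> str:
        if self.note:
            return self.note
        if self.direction == "NS":
            return "NS"
        return f"{self.direction} ({self.stars})"


@dataclass
class ComparisonSummary:
    cells: dict[tuple[str, str], ComparisonCell]
    alpha: float = 0.05

    def cell(self, feature: str, contrast: str) -> ComparisonCell:
        return self.cells[(feature, contrast)]

    def to_table(self) -> pd.DataFrame:
        """Feature rows x contrast columns of "Direction (stars)" labels."""
        data = {
            contrast: [self.cells[(f, contrast)].label() for f in FEATURE_NAMES]
            for contrast in CONTRASTS
        }
        return pd.DataFrame(data, index=list(FEATURE_NAMES)).rename_axis("feature")

    def to_long_frame(self) -> pd.DataFrame:
        """Exact p-values, sample sizes and BH q-values, one row per cell."""
        rows = []
        for (feature, contrast), c in sorted(self.cells.items()):
            rows.append(
                {
                    "feature": feature,
                    "contrast": contrast,
                    "direction": c.direction,
                    "p_value": np.nan if c.p_value is None else c.p_value,
                    "stars": c.stars,
                    "n_event": c.n_event,
                    "n_control": c.n_control,
                    "note": c.note,
                }
            )
        df = pd.DataFrame(rows)
        mask = df["p_value"].notna()
        df["q_value_bh"] = np.nan
        if mask.any():
            df.loc[mask, "q_value_bh"] = sps.false_discovery_control(
                df.loc[mask, "p_value"], method="bh"
            )
        return df


def _compare_one(
    feature: str,
    contrast: str,
    event_values: np.ndarray,
    control_values: np.ndarray,
    alpha: float,
) -> ComparisonCell:
    ev = event_values[~np.isnan(event_values)]
    cv = control_values[~np.isnan(control_values)]
    if ev.size == 0 or cv.size == 0:
        return ComparisonCell(
            feature, contrast, "NS", None, int(ev.size), int(cv.size),
            note="insufficient data",
        )
    res = mann_whitney(ev, cv)
    low_word, high_word = DIRECTION_WORDS[FEATURE_KINDS[feature]]
    if res.p_value >= alpha or res.median_direction == "none":
        direction = "NS"
    elif res.median_direction == "a_lower":
        direction = low_word
    else:
        direction = high_word
    return ComparisonCell(feature, contrast, direction, res.p_value, int(ev.size), int(cv.size))


def build_summary(
    more_skipped: pd.DataFrame,
    less_skipped: pd.DataFrame,
    internal: pd.DataFrame | dict[str, pd.DataFrame],
    external: pd.DataFrame,
    alpha: float = 0.05,
) -> ComparisonSummary:
    """The 14-feature x 4-contrast directional grid.

    Inputs are feature tables as produced by
    :func:`skipfeat.features.features_to_frame`. ``internal`` may be a single
    table (shared internal controls) or a ``{"more": ..., "less": ...}``
    pair when internal controls are drawn per direction set. Cells with an
    entirely absent feature on either side are marked "insufficient data".
    """
    if isinstance(internal, pd.DataFrame):
        internal = {"more": internal, "less": internal}
    sets = {
        "more_vs_internal": (more_skipped, internal["more"]),
        "more_vs_external": (more_skipped, external),
        "less_vs_internal": (less_skipped, internal["less"]),
        "less_vs_external": (less_skipped, external),
    }
    cells: dict[tuple[str, str], ComparisonCell] = {}
    for contrast, (ev_df, ctrl_df) in sets.items():
        for feature in FEATURE_NAMES:
            cells[(feature, contrast)] = _compare_one(
                feature,
                contrast,
                ev_df[feature].to_numpy(dtype=float),
                ctrl_df[feature].to_numpy(dtype=float),
                alpha,
            )
    return ComparisonSummary(cells=cells, alpha=alpha)
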