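"""Count-table statistics for the air-sampling survey.

Pearson chi-square tests are computed without Yates continuity correction
and without switching to exact tests at small expected counts — the analysis
they reproduce was done that way, and the published p-values (including
small-count cells) are recovered exactly under this convention.  Cells with
expected counts below 5 carry a warning annotation instead.

Also here: the one-way ANOVA / Tukey-Kramer pair used for colony counts,
simple proportion tables, and the inhaled-conidia exposure estimator
(colonies per litre of sampled air scaled by human tidal volume and
respiratory rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountTable

__all__ = [
    "TestResult",
    "ExposureParams",
    "PairwiseComparison",
    "chi2_independence",
    "chi2_goodness_of_fit",
    "ratio_comparison_matrix",
    "one_way_anova",
    "tukey_kramer",
    "exposure_rate",
    "proportion_table",
]

#: Ratio comparisons of the survey: chrysogenum:rubens, chrysogenum:other,
#: rubens:other, and whole-complex:other.
DEFAULT_COMPARISONS = ("C:R", "C:O", "R:O", "C+R:O")
DEFAULT_CATEGORY_MAP = {"C": ("chrysogenum",), "R": ("rubens",), "O": ("other",)}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExposureParams:
    """Human breathing defaults: 0.5 l tidal volume, 15 breaths/min."""

    tidal_volume_l: float = 0.5
    breaths_per_min: float = 15.0

    def __post_init__(self) -> None:
        if self.tidal_volume_l <= 0 or self.breaths_per_min <= 0:
            raise ValueError("exposure parameters must be positive")


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, CountTable):
        return np.asarray(table.counts, dtype=float)
    return np.asarray(table, dtype=float)


def chi2_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an R x C count table.

    No continuity correction.  Zero row/column margins are an error;
    expected counts below 5 add a warning annotation.
    """
    obs = _as_matrix(table)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an R x C table with R, C >= 2")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; test undefined")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    warnings = ()
    if (expected < 5).any():
        warnings = (f"{int((expected < 5).sum())} expected cell(s) < 5",)
    return TestResult(float(chi2), float(df), float(p), "chi2-independence", warnings)


def chi2_goodness_of_fit(
    observed: Sequence[float], expected_ratio: Sequence[float] | None = None
) -> TestResult:
    """Pearson goodness-of-fit test against a ratio (default 1:1:...)."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two categories")
    ratio = (
        np.ones_like(obs) if expected_ratio is None else np.asarray(expected_ratio, float)
    )
    if ratio.size != obs.size:
        raise ValueError(
            f"ratio has {ratio.size} categories but observed has {obs.size}"
        )
    if np.any(ratio <= 0):
        raise ValueError("expected ratio entries must be positive")
    expected = ratio / ratio.sum() * obs.sum()
    chi2, p = sps.chisquare(obs, f_exp=expected)
    warnings = ()
    if (expected < 5).any():
        warnings = (f"{int((expected < 5).sum())} expected cell(s) < 5",)
    return TestResult(
        float(chi2), float(obs.size - 1), float(p), "chi2-goodness-of-fit", warnings
    )


def ratio_comparison_matrix(
    counts: CountTable,
    comparisons: Sequence[str] = DEFAULT_COMPARISONS,
    category_map: Mapping[str, tuple[str, ...]] = DEFAULT_CATEGORY_MAP,
) -> dict[str, pd.DataFrame]:
    """Pairwise-location chi-square p-values for each category ratio.

    For every location pair and every comparison (e.g. ``"C+R:O"``), a 2x2
    table (locations x the two pooled categories) feeds
    :func:`chi2_independence`.  Each returned frame is upper-triangular:
    rows are all locations but the last, columns all but the first; cells
    below the diagonal, and cells whose 2x2 table has a zero margin, are NaN.
    """
    locations = counts.row_labels
    if len(locations) < 2:
        raise ValueError("need at least two locations")
    df = counts.to_dataframe()

    def pooled(loc: str, spec: str) -> int:
        cols = []
        for letter in spec.split("+"):
            names = category_map[letter]
            cols.extend(names)
        return int(df.loc[loc, cols].sum())

    out: dict[str, pd.DataFrame] = {}
    for comp in comparisons:
        left, right = comp.split(":")
        mat = pd.DataFrame(
            np.nan, index=locations[:-1], columns=locations[1:], dtype=float
        )
        for i, a in enumerate(locations):
            for b in locations[i + 1 :]:
                table = np.array(
                    [
                        [pooled(a, left), pooled(a, right)],
                        [pooled(b, left), pooled(b, right)],
                    ]
                )
                if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                    continue  # undefined cell stays NaN
                mat.loc[a, b] = chi2_independence(table).p_value
        out[comp] = mat
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    Degenerate inputs resolve by convention: all observations identical
    gives F = 0, p = 1; zero within-group variance with distinct means gives
    F = inf, p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    N = sum(g.size for g in gs)
    k = len(gs)
    if N - k < 1:
        raise ValueError("need at least 1 within-group degree of freedom")
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(0.0, df_b, 1.0, "one-way-anova")
        return TestResult(float("inf"), df_b, 0.0, "one-way-anova")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), float(df_b), p, "one-way-anova")


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    difference: float
    q_statistic: float
    p_value: float
    significant: bool


def tukey_kramer(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """Tukey-Kramer studentized-range post-hoc test.

    Unequal group sizes use the Kramer standard error
    ``sqrt(MSW * (1/n_i + 1/n_j) / 2)``; significance compares q against the
    studentized-range quantile at (k groups, N-k df, alpha).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(gs))]
    k = len(gs)
    N = sum(g.size for g in gs)
    df_w = N - k
    if df_w < 1:
        raise ValueError("need at least 1 within-group degree of freedom")
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    qcrit = float(sps.studentized_range.ppf(1 - alpha, k, df_w))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(gs[i].mean() - gs[j].mean())
            if msw == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
            else:
                se = np.sqrt(msw * 0.5 * (1 / gs[i].size + 1 / gs[j].size))
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            out.append(
                PairwiseComparison(
                    labels[i], labels[j], diff, q, p, bool(q > qcrit)
                )
            )
    return out


def exposure_rate(
    colony_count: float,
    air_volume_l: float,
    params: ExposureParams = ExposureParams(),
) -> float:
    """Viable conidia inhaled per minute given a plate count and sampled air
    volume: (count / volume) x tidal volume x breaths per minute."""
    if air_volume_l <= 0:
        raise ValueError("air volume must be positive")
    if colony_count < 0:
        raise ValueError("colony count cannot be negative")
    return colony_count / air_volume_l * params.tidal_volume_l * params.breaths_per_min


def proportion_table(counts: CountTable) -> pd.DataFrame:
    """Percentage of each row total per cell, to one decimal place.

    Rows with zero total are NaN.
    """
    df = counts.to_dataframe().astype(float)
    totals = df.sum(axis=1)
    pct = df.div(totals.where(totals > 0), axis=0) * 100.0
    return pct.round(1)
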