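"""Census-weighted, color-independent regional ancestry.

A region's "total ancestry" averages its color-category ancestry means with
weights given by the census shares of White/Brown/Black in that region,
renormalized over those three categories (the census also counts Yellow,
Indigenous and undeclared, so the raw percentages do not sum to 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .datatypes import ANCESTRIES, COLORS

__all__ = [
    "CensusWeights",
    "TotalAncestry",
    "renormalize_census",
    "compute_total_ancestry",
    "total_ancestry_table",
]


@dataclass
class CensusWeights:
    """Renormalized (White, Brown, Black) population shares of one region."""

    region: str
    w: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.w):
            raise ValueError("census weights must be non-negative")
        if abs(sum(self.w) - 1.0) > 1e-9:
            raise ValueError(f"census weights must sum to 1, got {self.w}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COLORS, self.w))


@dataclass
class TotalAncestry:
    """Color-independent ancestry composition of one region."""

    region: str
    total: tuple[float, float, float]

    def __post_init__(self) -> None:
        # Exact closure is not guaranteed when the inputs are printed,
        # rounded category means.
        if abs(sum(self.total) - 1.0) > 5e-3:
            raise ValueError(f"total ancestry far from closure: {self.total}")


def renormalize_census(
    white_pct: float, brown_pct: float, black_pct: float, region: str = ""
) -> CensusWeights:
    """Turn raw census percentages into weights summing to 1.

    Arithmetic is carried at full float precision; rounding happens only at
    presentation time.
    """
    vals = (white_pct, brown_pct, black_pct)
    if any(v < 0 for v in vals):
        raise ValueError(f"negative census percentage in {vals}")
    total = sum(vals)
    if total <= 0:
        raise ValueError("census percentages sum to zero")
    return CensusWeights(region=region, w=tuple(v / total for v in vals))


def compute_total_ancestry(
    category_means: dict[str, tuple[float, float, float]],
    weights: CensusWeights,
) -> TotalAncestry:
    """Convex combination of color-category means under census weights.

    ``category_means`` maps each color in {White, Brown, Black} to its
    (european, african, amerindian) mean. All three colors must be present
    (regions lacking a category cannot be weighted).
    """
    missing = [c for c in COLORS if c not in category_means]
    if missing:
        raise ValueError(f"missing color categories {missing} for region {weights.region!r}")
    w = weights.as_dict()
    total = tuple(
        sum(category_means[c][a] * w[c] for c in COLORS) for a in range(len(ANCESTRIES))
    )
    return TotalAncestry(region=weights.region, total=total)


def total_ancestry_table(means: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Compute totals for every region present in both tables.

    ``means`` needs columns region, color, <ancestry>_mean; ``census``
    needs region, white_pct, brown_pct, black_pct. Regions missing a color
    category are skipped with a warning (as the source analysis skips
    cohorts lacking data). Returns a frame with columns region, european,
    african, amerindian.
    """
    rows = []
    census_idx = census.set_index("region")
    for region, grp in means.groupby("region", sort=False):
        if region not in census_idx.index:
            warnings.warn(f"no census row for region {region!r}; skipped")
            continue
        cat = {
            r["color"]: tuple(float(r[f"{a}_mean"]) for a in ANCESTRIES)
            for _, r in grp.iterrows()
        }
        c = census_idx.loc[region]
        weights = renormalize_census(
            float(c["white_pct"]), float(c["brown_pct"]), float(c["black_pct"]), region=region
        )
        try:
            ta = compute_total_ancestry(cat, weights)
        except ValueError as exc:
            warnings.warn(f"region {region!r} skipped: {exc}")
            continue
        rows.append({"region": region, **dict(zip(ANCESTRIES, ta.total))})
    return pd.DataFrame(rows, columns=["region", *ANCESTRIES])
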