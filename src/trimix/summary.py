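"""Per-(region, color) cohort summaries and simplex plot coordinates."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ANCESTRIES, COLORS
from .estimate import AncestryVector

__all__ = [
    "CohortSummary",
    "summarize",
    "ternary_coords",
    "inverse_ternary_coords",
    "cartesian_projection",
    "ternary_figure",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass
class CohortSummary:
    """Mean and standard error of ancestry components for one cohort.

    The Cartesian projection keeps only (mean european, mean african) =
    (X, Y); the Amerindian mean is recoverable as 1 - X - Y, so nothing is
    lost relative to the ternary representation.
    """

    region: str
    color: str
    n: int
    mean: tuple[float, float, float]
    se: tuple[float, float, float]

    def __post_init__(self) -> None:
        # computed summaries close to 1e-9; the loose bound admits printed,
        # 3-decimal tables whose rows can miss closure by up to 0.005
        if abs(sum(self.mean) - 1.0) > 5e-3:
            raise ValueError(f"mean components must sum to 1, got {self.mean}")
        if any(s < 0 for s in self.se):
            raise ValueError("standard errors must be non-negative")

    @property
    def X(self) -> float:
        return self.mean[0]

    @property
    def Y(self) -> float:
        return self.mean[1]


def summarize(
    ancestries: list[AncestryVector],
    labels: list[tuple[str, str]],
    known_colors: tuple[str, ...] = COLORS,
) -> list[CohortSummary]:
    """Group ancestry vectors by (region, color) and compute component-wise
    means and standard errors.

    The s.e. is the sample standard deviation (n-1 denominator) over
    sqrt(n); singleton groups report se = 0 with a warning. Individuals
    flagged with an estimation error are dropped (with a warning); a group
    left empty is omitted. Unknown color labels raise.
    """
    if len(ancestries) != len(labels):
        raise ValueError("ancestries and labels must have equal length")
    for _, color in labels:
        if color not in known_colors:
            raise ValueError(f"unknown color label {color!r}; expected one of {known_colors}")

    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    order: list[tuple[str, str]] = []
    for av, label in zip(ancestries, labels):
        if av.error is not None:
            warnings.warn(f"dropping failed estimate in group {label}: {av.error}")
            continue
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(np.asarray(av.q, dtype=float))

    out: list[CohortSummary] = []
    for label in order:
        rows = np.vstack(groups[label])
        n = rows.shape[0]
        mean = rows.mean(axis=0)
        mean = mean / mean.sum()  # guard float drift; inputs are on the simplex
        if n == 1:
            warnings.warn(f"group {label} has a single individual; reporting se = 0")
            se = np.zeros(len(ANCESTRIES))
        else:
            se = rows.std(axis=0, ddof=1) / math.sqrt(n)
        out.append(
            CohortSummary(
                region=label[0],
                color=label[1],
                n=n,
                mean=tuple(float(x) for x in mean),
                se=tuple(float(x) for x in se),
            )
        )
    return out


def ternary_coords(q, vertices: tuple[str, ...] = ANCESTRIES) -> tuple[float, float]:
    """Barycentric mapping of a simplex triple into an equilateral triangle.

    Vertex placement (default component order european, african,
    amerindian): first component at (0, 0), second at (1, 0), third at
    (1/2, sqrt(3)/2). ``vertices`` reorders which ancestry sits at which
    vertex.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (3,):
        raise ValueError("q must have exactly 3 components")
    if abs(q.sum() - 1.0) > 1e-6 or np.any(q < -1e-6):
        raise ValueError(f"q is not on the simplex: {q}")
    idx = [ANCESTRIES.index(v) for v in vertices]
    if sorted(idx) != [0, 1, 2]:
        raise ValueError(f"vertices must be a permutation of {ANCESTRIES}")
    qq = q[idx]
    return (float(qq[1] + 0.5 * qq[2]), float(_SQRT3_2 * qq[2]))


def inverse_ternary_coords(xy, vertices: tuple[str, ...] = ANCESTRIES) -> tuple[float, float, float]:
    """Invert :func:`ternary_coords`; exact on the simplex."""
    x, y = xy
    third = y / _SQRT3_2
    second = x - 0.5 * third
    first = 1.0 - second - third
    idx = [ANCESTRIES.index(v) for v in vertices]
    q = np.empty(3)
    q[idx] = (first, second, third)
    return tuple(float(v) for v in q)


def cartesian_projection(summary: CohortSummary) -> tuple[float, float]:
    """(mean european, mean african) of a cohort; lossless under closure."""
    return (summary.X, summary.Y)


def ternary_figure(points, labels=None, ax=None):
    """Scatter ancestry vectors inside the ternary triangle (needs
    matplotlib, an optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    xy = np.array([ternary_coords(q) for q in points])
    ax.plot([0, 1, 0.5, 0], [0, 0, _SQRT3_2, 0], color="0.3", lw=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=12)
    if labels is not None:
        for (x, y), lab in zip(xy, labels):
            ax.annotate(str(lab), (x, y), fontsize=7)
    for name, (vx, vy) in zip(ANCESTRIES, [(0, 0), (1, 0), (0.5, _SQRT3_2)]):
        ax.annotate(name, (vx, vy), ha="center", va="bottom" if vy else "top")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
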