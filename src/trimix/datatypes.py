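"""Core containers shared by all stages.

The analysis runs on three ancestral source populations (European, African,
Amerindian) genotyped at L biallelic loci; genotypes are counts of the
"short" allele in {0, 1, 2}, with -1 as the internal missing sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANCESTRIES",
    "COLORS",
    "MISSING",
    "AlleleFrequencyPanel",
    "GenotypeMatrix",
]

#: Canonical component order used everywhere in this package.
ANCESTRIES = ("european", "african", "amerindian")

#: Census color categories covered by the study.
COLORS = ("White", "Brown", "Black")

#: Internal sentinel for a missing genotype.
MISSING = -1


@dataclass
class AlleleFrequencyPanel:
    """Short-allele frequencies for K reference populations at L loci.

    Parameters
    ----------
    pop_ids
        Names of the K ancestral populations, in component order.
    locus_ids
        Names of the L loci.
    freqs
        Array of shape (K, L); ``freqs[k, l]`` is the frequency of the
        short allele of locus ``l`` in population ``k``.
    """

    pop_ids: list[str]
    locus_ids: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be a 2-D (K x L) array")
        k, l = self.freqs.shape
        if k != len(self.pop_ids) or l != len(self.locus_ids):
            raise ValueError(
                f"freqs shape {self.freqs.shape} inconsistent with "
                f"{len(self.pop_ids)} populations x {len(self.locus_ids)} loci"
            )
        if np.any((self.freqs < 0.0) | (self.freqs > 1.0)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def align_loci(self, locus_ids: list[str]) -> "AlleleFrequencyPanel":
        """Reorder/subset the panel to ``locus_ids``, matching by id, never
        by position."""
        index = {lid: i for i, lid in enumerate(self.locus_ids)}
        missing = [lid for lid in locus_ids if lid not in index]
        if missing:
            raise KeyError(f"loci absent from panel: {missing[:5]}")
        cols = [index[lid] for lid in locus_ids]
        return AlleleFrequencyPanel(
            pop_ids=list(self.pop_ids),
            locus_ids=list(locus_ids),
            freqs=self.freqs[:, cols].copy(),
        )

    def is_identifiable(self, tol: float = 1e-10) -> bool:
        """True when the K frequency rows are affinely independent, i.e. the
        mixture frequency determines the ancestry vector uniquely."""
        diffs = self.freqs[1:] - self.freqs[0]
        return np.linalg.matrix_rank(diffs, tol=tol) == self.n_pops - 1


@dataclass
class GenotypeMatrix:
    """N individuals x L loci of short-allele counts.

    ``values`` holds integers in {0, 1, 2} with :data:`MISSING` (-1) marking
    missing genotypes. ``regions``/``colors`` carry the cohort labels and
    default to empty strings.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    regions: list[str] = field(default_factory=list)
    colors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N x L) array")
        n, l = self.values.shape
        if n != len(self.individual_ids) or l != len(self.locus_ids):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid genotype value {self.values[i, j]} for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )
        if not self.regions:
            self.regions = [""] * n
        if not self.colors:
            self.colors = [""] * n
        if len(self.regions) != n or len(self.colors) != n:
            raise ValueError("labels length inconsistent with matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def labels(self) -> list[tuple[str, str]]:
        return list(zip(self.regions, self.colors))
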