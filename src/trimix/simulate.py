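"""Synthetic reference panels and admixed cohorts with known ground truth.

Reference population frequencies diverge from a common ancestral frequency
under the Balding-Nichols model: with divergence F and ancestral frequency
p, each population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F).
Individuals receive Dirichlet-distributed ancestry vectors and unlinked
binomial genotypes, so every downstream stage can be validated against the
retained truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .datatypes import ANCESTRIES, AlleleFrequencyPanel, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_reference_panel",
    "simulate_cohort",
]

#: Frequencies are kept away from {0, 1} so every mixture likelihood is
#: finite; fixed differences are available via ``fixed_differences``.
FREQ_CLAMP = (0.001, 0.999)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``dirichlet_params`` and ``cohort_sizes`` are keyed by (region, color)
    cohort labels; every cohort must appear in both.
    """

    fst: float = 0.15
    n_loci: int = 40
    n_pops: int = 3
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    dirichlet_params: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    cohort_sizes: dict[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0
    fixed_differences: bool = False

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must lie strictly in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        for label, alpha in self.dirichlet_params.items():
            if len(alpha) != self.n_pops:
                raise ValueError(f"dirichlet_params for {label} must have {self.n_pops} entries")
            if any(a <= 0 for a in alpha):
                raise ValueError(f"dirichlet_params for {label} must be positive")
        for label, n in self.cohort_sizes.items():
            if n < 0:
                raise ValueError(f"cohort size for {label} must be >= 0")
            if label not in self.dirichlet_params:
                raise ValueError(f"cohort {label} has a size but no dirichlet_params")


@dataclass
class SimulatedCohort:
    """Genotypes plus the ground-truth ancestry that generated them."""

    genotypes: GenotypeMatrix
    true_ancestry: np.ndarray  # (N, K) rows on the simplex
    labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.true_ancestry = np.asarray(self.true_ancestry, dtype=float)
        n = self.genotypes.n_individuals
        if self.true_ancestry.shape != (n, len(ANCESTRIES)) and n > 0:
            raise ValueError("true_ancestry shape inconsistent with genotypes")
        if len(self.labels) != n:
            raise ValueError("labels length inconsistent with genotypes")
        if n and not np.allclose(self.true_ancestry.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("true ancestry vectors must sum to 1")


def simulate_reference_panel(config: SimulationConfig) -> AlleleFrequencyPanel:
    """Draw a K x L reference panel under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``config.ancestral_freq_range``;
    each population's frequency at a locus is an independent Beta draw with
    mean the ancestral frequency and variance scaled by ``config.fst``.
    Frequencies are clamped to [0.001, 0.999] unless
    ``config.fixed_differences`` is set, in which case population k gets
    fully diverged frequencies alternating 0.999/0.001 in a k-dependent
    pattern (for trivial-recovery tests).
    """
    rng = substream(config.seed, "reference_panel")
    pop_ids = list(ANCESTRIES[: config.n_pops])
    if len(pop_ids) < config.n_pops:
        pop_ids += [f"pop{k}" for k in range(len(pop_ids), config.n_pops)]
    locus_ids = [f"L{l + 1}" for l in range(config.n_loci)]

    if config.fixed_differences:
        lo, hi = FREQ_CLAMP
        freqs = np.full((config.n_pops, config.n_loci), lo)
        for k in range(config.n_pops):
            freqs[k, k :: config.n_pops] = hi
        return AlleleFrequencyPanel(pop_ids, locus_ids, freqs)

    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)
    f = config.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    freqs = rng.beta(a, b, size=(config.n_pops, config.n_loci))
    freqs = np.clip(freqs, *FREQ_CLAMP)
    return AlleleFrequencyPanel(pop_ids, locus_ids, freqs)


def simulate_cohort(panel: AlleleFrequencyPanel, config: SimulationConfig) -> SimulatedCohort:
    """Simulate admixed individuals for every cohort in ``config``.

    Each individual draws q ~ Dirichlet(alpha of its cohort) and, at locus
    l, a Binomial(2, sum_k q_k p_kl) genotype; loci are unlinked. The true
    q is retained. Cohorts are emitted in the (sorted) order of
    ``config.cohort_sizes``; individuals get ids ``<region>_<color>_<i>``.
    """
    if panel.n_pops != config.n_pops or panel.n_loci != config.n_loci:
        raise ValueError(
            f"panel ({panel.n_pops} pops x {panel.n_loci} loci) does not match "
            f"config ({config.n_pops} x {config.n_loci})"
        )
    rng = substream(config.seed, "cohort")

    ids: list[str] = []
    labels: list[tuple[str, str]] = []
    q_blocks: list[np.ndarray] = []
    g_blocks: list[np.ndarray] = []
    for label in sorted(config.cohort_sizes):
        n = config.cohort_sizes[label]
        if n == 0:
            continue
        region, color = label
        alpha = np.asarray(config.dirichlet_params[label], dtype=float)
        q = rng.dirichlet(alpha, size=n)
        m = q @ panel.freqs  # (n, L) individual mixture frequencies
        g = rng.binomial(2, m)
        ids.extend(f"{region}_{color}_{i + 1}" for i in range(n))
        labels.extend([label] * n)
        q_blocks.append(q)
        g_blocks.append(g)

    if not ids:
        warnings.warn("all cohort sizes are zero; returning an empty cohort")
        values = np.empty((0, panel.n_loci), dtype=np.int16)
        truth = np.empty((0, panel.n_pops))
    else:
        values = np.vstack(g_blocks).astype(np.int16)
        truth = np.vstack(q_blocks)

    genotypes = GenotypeMatrix(
        individual_ids=ids,
        locus_ids=list(panel.locus_ids),
        values=values,
        regions=[r for r, _ in labels],
        colors=[c for _, c in labels],
    )
    return SimulatedCohort(genotypes=genotypes, true_ancestry=truth, labels=labels)
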