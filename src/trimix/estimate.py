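"""Supervised ancestry estimation by maximum likelihood.

Reference allele frequencies are treated as known. An individual with
ancestry vector q on the simplex carries, at locus l, a short-allele count
g_l ~ Binomial(2, m_l) with m_l = sum_k q_k p_kl. The log-likelihood is
concave in q (m is linear in q and the binomial log-pmf is concave in m),
so EM from an interior start converges to the global maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._rng import substream
from .datatypes import MISSING, AlleleFrequencyPanel, GenotypeMatrix

__all__ = [
    "AncestryVector",
    "loglikelihood",
    "em_step",
    "estimate_individual",
    "estimate_cohort",
    "bootstrap_se",
]

logger = logging.getLogger(__name__)

_LOG2 = float(np.log(2.0))


@dataclass
class AncestryVector:
    """Point estimate of one individual's ancestry proportions.

    ``q`` is (european, african, amerindian); components are non-negative
    and sum to 1 within 1e-9. ``error`` is set (and ``q`` is NaN) when the
    individual could not be estimated at all.
    """

    q: tuple[float, float, float]
    loglik: float
    n_used: int
    converged: bool = True
    identifiable: bool = True
    error: str | None = None

    def __post_init__(self) -> None:
        if self.error is None:
            q = np.asarray(self.q, dtype=float)
            if np.any(q < -1e-9) or abs(q.sum() - 1.0) > 1e-9:
                raise ValueError(f"ancestry vector off the simplex: {self.q}")


def _check_inputs(q: np.ndarray, g: np.ndarray, panel: AlleleFrequencyPanel) -> np.ndarray:
    if q.shape != (panel.n_pops,):
        raise ValueError(f"q must have {panel.n_pops} components")
    if abs(q.sum() - 1.0) > 1e-6 or np.any(q < -1e-9):
        raise ValueError(f"q is not on the simplex: {q}")
    if g.shape != (panel.n_loci,):
        raise ValueError("genotype row length does not match panel")
    used = g != MISSING
    if not used.any():
        raise ValueError("no informative loci: all genotypes missing")
    return used


def loglikelihood(q, genotypes_row, panel: AlleleFrequencyPanel) -> float:
    """Binomial admixture log-likelihood of one genotype row at ancestry q.

    Missing loci (sentinel -1) are skipped. Raises ``ValueError`` when no
    non-missing locus remains.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(genotypes_row)
    used = _check_inputs(q, g, panel)
    g = g[used].astype(float)
    m = q @ panel.freqs[:, used]
    return float(np.sum(np.where(g == 1, _LOG2, 0.0) + g * np.log(m) + (2.0 - g) * np.log1p(-m)))


def em_step(q, genotypes_row, panel: AlleleFrequencyPanel) -> np.ndarray:
    """One EM update of the allele-origin mixture.

    E-step attributes each of the individual's 2 x L_used allele copies to
    an ancestral population in proportion to q_k p_kl / m_l (short copies)
    or q_k (1 - p_kl) / (1 - m_l) (long copies); M-step renormalizes the
    expected counts. The log-likelihood never decreases.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(genotypes_row)
    used = _check_inputs(q, g, panel)
    g = g[used].astype(float)
    p = panel.freqs[:, used]  # (K, L_used)
    m = q @ p
    short = q[:, None] * p / m  # posterior origin of a short copy, (K, L)
    long_ = q[:, None] * (1.0 - p) / (1.0 - m)
    counts = short @ g + long_ @ (2.0 - g)
    return counts / counts.sum()


def _raw_loglik(q: np.ndarray, g: np.ndarray, p: np.ndarray) -> float:
    """Unchecked likelihood kernel on pre-filtered non-missing loci."""
    m = np.clip(q @ p, 1e-300, 1.0 - 1e-16)
    return float(np.sum(np.where(g == 1, _LOG2, 0.0) + g * np.log(m) + (2.0 - g) * np.log1p(-m)))


def _polish(q: np.ndarray, g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Constrained quasi-Newton refinement of the EM solution.

    EM converges only linearly when the optimum sits on the simplex
    boundary; a short SLSQP run from the EM iterate closes the remaining
    gap. The EM iterate is kept whenever the polish does not improve the
    likelihood.
    """

    def nll(x):
        x = np.clip(x, 1e-12, None)
        return -_raw_loglik(x / x.sum(), g, p)

    def grad(x):
        x = np.clip(x, 1e-12, None)
        qn = x / x.sum()
        m = np.clip(qn @ p, 1e-12, 1.0 - 1e-12)
        return -((g / m - (2.0 - g) / (1.0 - m)) * p).sum(axis=1)

    try:
        res = minimize(
            nll,
            q,
            jac=grad,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(q),
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
            options={"ftol": 1e-12, "maxiter": 200},
        )
    except Exception:  # pragma: no cover - optimizer hiccups fall back to EM
        return q
    cand = np.clip(res.x, 0.0, None)
    s = cand.sum()
    if not res.success or s <= 0:
        return q
    cand = cand / s
    return cand if _raw_loglik(cand, g, p) > _raw_loglik(q, g, p) else q


def estimate_individual(
    genotypes_row,
    panel: AlleleFrequencyPanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
    polish: bool = True,
) -> AncestryVector:
    """EM from the uniform start until the log-likelihood gain drops below
    ``tol`` (or ``max_iter`` sweeps; the best iterate is then returned with
    ``converged=False`` and a warning), followed by a boundary-aware
    quasi-Newton polish (disable with ``polish=False``)."""
    g = np.asarray(genotypes_row)
    identifiable = panel.is_identifiable()
    q = np.full(panel.n_pops, 1.0 / panel.n_pops)
    used0 = _check_inputs(q, g, panel)
    gu = g[used0].astype(float)
    p = panel.freqs[:, used0]
    pg = p * gu  # hoisted: E-step numerators are linear in these
    p2g = (1.0 - p) * (2.0 - gu)
    ll = _raw_loglik(q, gu, p)
    converged = False
    for _ in range(max_iter):
        m = q @ p
        counts = q * (pg / m + p2g / (1.0 - m)).sum(axis=1)
        q = counts / counts.sum()
        ll_new = _raw_loglik(q, gu, p)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if polish and identifiable:
        used = g != MISSING
        q = _polish(q, g[used].astype(float), panel.freqs[:, used])
        ll_polished = loglikelihood(q, g, panel)
        converged = converged or ll_polished > ll
        ll = ll_polished
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (|dll| >= {tol})")
    q = np.clip(q, 0.0, None)
    q = q / q.sum()
    return AncestryVector(
        q=tuple(float(x) for x in q),
        loglik=ll,
        n_used=int(np.sum(g != MISSING)),
        converged=converged,
        identifiable=identifiable,
    )


def estimate_cohort(
    genotypes: GenotypeMatrix,
    panel: AlleleFrequencyPanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[AncestryVector]:
    """Estimate every individual, preserving input order.

    Per-individual failures (e.g. fully missing rows) become flagged
    records with ``error`` set instead of aborting the cohort.
    """
    aligned = panel.align_loci(genotypes.locus_ids)
    out: list[AncestryVector] = []
    n_failed = 0
    for i in range(genotypes.n_individuals):
        row = genotypes.values[i]
        try:
            out.append(estimate_individual(row, aligned, tol=tol, max_iter=max_iter))
        except ValueError as exc:
            n_failed += 1
            nan = float("nan")
            out.append(
                AncestryVector(
                    q=(nan, nan, nan), loglik=nan, n_used=0, converged=False, error=str(exc)
                )
            )
    n_conv = sum(1 for a in out if a.converged)
    logger.info(
        "estimated %d individuals: %d converged, %d failed",
        genotypes.n_individuals,
        n_conv,
        n_failed,
    )
    return out


def bootstrap_se(
    genotypes_row,
    panel: AlleleFrequencyPanel,
    q_hat,
    n_reps: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Parametric-bootstrap standard errors for one individual.

    Genotypes are resimulated at ``q_hat`` over the individual's non-missing
    loci and re-estimated; returns the per-component standard deviation of
    the replicate estimates. Group-level dispersion is reported elsewhere;
    this per-individual interval is an optional extra.
    """
    g = np.asarray(genotypes_row)
    used = g != MISSING
    rng = substream(seed, "bootstrap")
    m = np.asarray(q_hat, dtype=float) @ panel.freqs[:, used]
    reps = np.empty((n_reps, panel.n_pops))
    for r in range(n_reps):
        sim = np.full(g.shape, MISSING, dtype=np.int16)
        sim[used] = rng.binomial(2, m)
        reps[r] = estimate_individual(sim, panel).q
    return reps.std(axis=0, ddof=1)
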