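"""Within-individual co-variation of locus methylation and methylation-expression tests.

Given per-individual methylation levels at a panel of loci, the
co-variation analysis asks whether the level at one locus predicts the
level at another within the same animal (a trans-acting mechanism
would produce such coupling; independent cis-acting stochastic
establishment would not).  Pairwise Pearson correlations are tested
two-tailed against a Bonferroni-adjusted alpha.  The module also
implements deltaCT relative expression and the expression-methylation
correlation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def normalize_to_range(levels) -> np.ndarray:
    """Rescale one locus's per-individual levels to its observed range: (x - min)/(max - min)."""
    arr = np.asarray(levels, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("constant methylation vector: interindividual range undefined")
    return (arr - lo) / (hi - lo)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-tailed p from the exact t reference distribution."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


@dataclass
class CovariationResult:
    """Pairwise correlation matrix with Bonferroni-flagged significance."""

    r: pd.DataFrame
    p: pd.DataFrame
    alpha_adjusted: float
    significant: pd.DataFrame
    n_individuals: int
    divisor: int
    degenerate_loci: list[str]


def bonferroni_alpha(fwer: float, divisor: int) -> float:
    """Adjusted per-test alpha: fwer / divisor."""
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    return fwer / divisor


def covariation_matrix(
    panel: pd.DataFrame, fwer: float = 0.05, divisor: int | None = None
) -> CovariationResult:
    """Pairwise Pearson correlation of locus methylation across individuals.

    ``panel`` holds one row per individual and one column per locus
    (methylation fractions).  Two-tailed p values come from the exact t
    distribution with n-2 df.  The adjusted alpha divides the
    family-wise error rate by ``divisor`` (default: the number of loci,
    matching the published analysis of six loci at alpha 0.008;
    Pearson r is invariant to the per-locus range normalisation used
    for display, so the matrix is computed on the raw levels).
    Constant loci yield undefined pairs, flagged and set to NaN.
    """
    if panel.shape[0] < 3:
        raise ValueError("covariation needs at least 3 individuals")
    loci = list(panel.columns)
    m = len(loci)
    if divisor is None:
        divisor = m
    alpha = bonferroni_alpha(fwer, divisor)
    logger.info("covariation: %d loci, divisor %d, adjusted alpha %.6g", m, divisor, alpha)
    values = panel.to_numpy(dtype=float)
    degenerate = [loci[j] for j in range(m) if np.ptp(values[:, j]) == 0]
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if loci[i] in degenerate or loci[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = _pearson(values[:, i], values[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=loci, columns=loci)
    pdf = pd.DataFrame(p, index=loci, columns=loci)
    sig = (pdf < alpha) & ~np.eye(m, dtype=bool)
    return CovariationResult(
        r=rdf, p=pdf, alpha_adjusted=alpha, significant=sig,
        n_individuals=panel.shape[0], divisor=divisor, degenerate_loci=degenerate,
    )


def relative_expression(ct_target, ct_reference) -> float | np.ndarray:
    """deltaCT relative cDNA abundance: 2^-(Ct_target - Ct_reference).

    One qPCR cycle corresponds to a doubling, so a target crossing one
    cycle after the housekeeping reference has half its abundance.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise ValueError("cycle thresholds must be finite")
    out = np.power(2.0, -(ct_t - ct_r))
    return float(out) if out.ndim == 0 else out


@dataclass
class CorrelationTest:
    r: float
    p: float
    slope_sign: int
    n: int


def expression_methylation_test(expression, methylation) -> CorrelationTest:
    """Two-tailed Pearson test of expression against methylation level."""
    x = np.asarray(methylation, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = _pearson(x, y)
    return CorrelationTest(r=r, p=p, slope_sign=int(np.sign(r)), n=x.size)
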