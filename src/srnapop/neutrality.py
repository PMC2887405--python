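"""Tajima's D neutrality test with fixed-S coalescent significance.

D contrasts the pairwise estimator pi with Watterson's S/a1: an excess of
rare variants (post-sweep or expanding populations) drives D negative,
an excess of intermediate-frequency variants (balancing selection,
structure) drives it positive.

Significance is evaluated against Hudson's fixed-S conditional null: the
observed D is ranked among replicate D values from neutral genealogies
carrying exactly S mutations placed multinomially by branch length
(two-tailed, p = (1 + #{|D_sim| >= |D_obs|}) / (n_reps + 1)).  The
beta-approximation of the original derivation is deliberately not used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .diversity import harmonic
from .coalescent import derive_rng, fixed_s_replicates


@dataclass(frozen=True)
class TajimaCoefficients:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    """Variance-normalisation coefficients of Tajima (1989) for sample size n."""
    if n < 3:
        raise ValueError("Tajima's D variance is degenerate for n < 3")
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, pi_locus: float, n: int) -> float:
    """Tajima's D; NaN when S = 0 (statistic undefined)."""
    if S == 0:
        return math.nan
    c = tajima_coefficients(n)
    denom = math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    return (pi_locus - S / c.a1) / denom


def tajimas_d_array(S: np.ndarray, pi: np.ndarray, n: int) -> np.ndarray:
    """Vectorised D over replicate (S, pi) arrays; NaN where S = 0."""
    c = tajima_coefficients(n)
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (pi - S / c.a1) / np.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    d = np.where(S == 0, np.nan, d)
    return d


def fixed_s_null_d(
    n: int, S: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate D values from the fixed-S conditional neutral null."""
    S_arr, pi = fixed_s_replicates(n, S, n_reps, rng)
    return tajimas_d_array(S_arr, pi, n)


def tajima_significance(
    d_obs: float,
    n: int,
    S: int,
    n_reps: int = 10_000,
    seed: int = 0,
    null_d: np.ndarray | None = None,
) -> float:
    """Two-tailed fixed-S p-value for an observed D.

    ``null_d`` lets callers share one null sample across loci with the same
    (n, S); otherwise a fresh seeded null of ``n_reps`` replicates is drawn.
    """
    if math.isnan(d_obs):
        raise ValueError("D is undefined (S = 0); no test to perform")
    if null_d is None:
        if n_reps < 100:
            raise ValueError("n_reps < 100 gives a meaningless p-value")
        rng = derive_rng(seed, "tajima-null", n, S)
        null_d = fixed_s_null_d(n, S, n_reps, rng)
    exceed = int(np.sum(np.abs(null_d) >= abs(d_obs)))
    return (1 + exceed) / (null_d.size + 1)


@dataclass(frozen=True)
class TajimaResult:
    locus_id: str
    subgroup: str
    n: int
    S: int
    pi_locus: float
    D: float  # NaN when S = 0
    p_value: float  # NaN when D undefined
    significant: bool  # two-tailed p < alpha; always False when S = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.D)


def test_neutrality(
    locus_id: str,
    subgroup: str,
    n: int,
    S: int,
    pi_locus: float,
    n_reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TajimaResult:
    d = tajimas_d(S, pi_locus, n)
    if math.isnan(d):
        return TajimaResult(locus_id, subgroup, n, S, pi_locus, d, math.nan, False)
    p = tajima_significance(d, n, S, n_reps=n_reps, seed=seed)
    return TajimaResult(locus_id, subgroup, n, S, pi_locus, d, p, p < alpha)


def d_distribution(d_values, bin_width: float = 0.5):
    """Histogram table (bin_left, bin_right, count) plus mean and skewness."""
    import pandas as pd

    vals = np.asarray([d for d in d_values if not math.isnan(d)], dtype=float)
    if vals.size == 0:
        raise ValueError("no defined D values to bin")
    lo = math.floor(vals.min() / bin_width) * bin_width
    hi = math.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(vals, bins=edges)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    skew = float(sps.skew(vals)) if vals.size > 2 else math.nan
    return table, float(vals.mean()), skew
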