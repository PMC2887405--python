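"""Multi-locus Hudson-Kreitman-Aguade (HKA) test.

Under neutrality, within-species polymorphism and between-species divergence
both scale with the same per-locus mutation rate, so their ratio should be
homogeneous across loci.  The test fits one mutation parameter theta_i per
locus plus a common divergence time T (in 2N units) to the observed
segregating-site counts S_i and mean pairwise divergences D_i, and measures
departure with a goodness-of-fit X^2.

Model (single-species polymorphism, one outgroup lineage, equal ancestral
population size):

    E[S_i] = theta_i * L_poly_i * a1(n_i)
    E[D_i] = theta_i * L_div_i * (T + 1)
    Var[S_i] = E[S_i] + (theta_i L_poly_i)^2 * a2(n_i)
    Var[D_i] = E[D_i] + (theta_i L_div_i)^2

Estimation follows the classical moment constraints: per-locus totals
S_i + D_i match their expectations and the divergence total matches its
expectation, reducing to a one-dimensional fixed point in x = T + 1.
Significance is parametric: datasets are simulated at the fitted parameters
with the joint ingroup+outgroup coalescent engine, each simulated dataset is
refitted, and p is the tail rank of the observed X^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import harmonic
from .coalescent import derive_rng, ingroup_outgroup_replicates


@dataclass(frozen=True)
class HKALocusInput:
    locus_id: str
    n_ingroup: int
    L_poly: int
    S_obs: int
    L_div: int
    D_obs: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.n_ingroup < 2:
            raise ValueError(f"{self.locus_id}: HKA needs >=2 ingroup sequences")
        if self.S_obs > self.L_poly:
            raise ValueError(f"{self.locus_id}: S exceeds polymorphism length")
        if self.D_obs < 0:
            raise ValueError(f"{self.locus_id}: negative divergence")


@dataclass(frozen=True)
class HKAFit:
    locus_ids: tuple[str, ...]
    theta_site: np.ndarray  # per-site theta_i
    T_hat: float
    X2: float
    expected_S: np.ndarray
    expected_D: np.ndarray
    dev_poly: np.ndarray
    dev_div: np.ndarray
    converged: bool


@dataclass(frozen=True)
class HKAResult:
    locus_id: str
    X2: float
    p_value: float
    n_sim: int
    significant: bool


def _fit_arrays(S, D, Lp, Ld, a1, tol=1e-10, max_iter=10_000):
    """Solve the HKA moment equations for x = T + 1; supports batched rows.

    S, D: (..., k) observation arrays; Lp, Ld, a1: (k,) locus constants.
    Returns (theta_locus (...,k), x (...,)), with theta_locus = theta_i * L_i
    on the polymorphism length scale divided out later.
    """
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    tot = S + D
    sumD = D.sum(axis=-1)
    ratio = Ld / Lp
    if S.shape[-1] == 1 and np.all(S > 0):
        # one locus: the moment equations are saturated and solve exactly
        x = D[..., 0] * a1[0] / (S[..., 0] * ratio[0])
        return S / a1, x
    x = np.ones_like(sumD)
    for _ in range(max_iter):
        # theta_i * Lp_i = (S_i + D_i) / (a1_i + (Ld/Lp)_i * x)
        denom = a1 + ratio * x[..., None]
        thetaLp = tot / denom
        new_x = sumD / np.maximum((thetaLp * ratio).sum(axis=-1), 1e-300)
        if np.all(np.abs(new_x - x) <= tol * np.maximum(1.0, np.abs(new_x))):
            x = new_x
            break
        x = new_x
    else:
        raise RuntimeError("HKA parameter estimation did not converge")
    thetaLp = tot / (a1 + ratio * x[..., None])
    return thetaLp, x


def _x2_arrays(S, D, thetaLp, x, Lp, Ld, a1, a2):
    """X^2 and its per-locus components for (possibly batched) fits."""
    thetaLd = thetaLp * (Ld / Lp)
    ES = thetaLp * a1
    ED = thetaLd * x[..., None]
    varS = ES + thetaLp**2 * a2
    varD = ED + thetaLd**2
    with np.errstate(invalid="ignore", divide="ignore"):
        dev_s = np.where(varS > 0, (S - ES) ** 2 / varS, np.where(S == ES, 0.0, np.inf))
        dev_d = np.where(varD > 0, (D - ED) ** 2 / varD, np.where(D == ED, 0.0, np.inf))
    return dev_s, dev_d, ES, ED


def estimate_hka_parameters(
    loci: Sequence[HKALocusInput], tol: float = 1e-10, max_iter: int = 10_000
) -> HKAFit:
    """Fit theta_i and T to a set of loci and compute the X^2 statistic."""
    if len(loci) < 1:
        raise ValueError("HKA fit needs at least one locus")
    S = np.array([l.S_obs for l in loci], dtype=float)
    D = np.array([l.D_obs for l in loci], dtype=float)
    Lp = np.array([l.L_poly for l in loci], dtype=float)
    Ld = np.array([l.L_div for l in loci], dtype=float)
    n = [l.n_ingroup for l in loci]
    a1 = np.array([harmonic(m) for m in n])
    a2 = np.array([harmonic(m, power=2) for m in n])
    if S.sum() + D.sum() == 0:
        raise ValueError("all-zero data: HKA parameters are unidentifiable")
    if D.sum() == 0:
        raise ValueError("zero total divergence: T is unidentifiable")
    if len(loci) == 1 and S[0] > 0:
        # saturated: 2 observations, 2 parameters — the fit is exact
        x = D[0] * a1[0] * Lp[0] / (S[0] * Ld[0])
        return HKAFit(
            locus_ids=(loci[0].locus_id,),
            theta_site=S / (a1 * Lp),
            T_hat=float(x - 1.0),
            X2=0.0,
            expected_S=S.copy(),
            expected_D=D.copy(),
            dev_poly=np.zeros(1),
            dev_div=np.zeros(1),
            converged=True,
        )
    thetaLp, x = _fit_arrays(S, D, Lp, Ld, a1, tol=tol, max_iter=max_iter)
    dev_s, dev_d, ES, ED = _x2_arrays(S, D, thetaLp, x, Lp, Ld, a1, a2)
    return HKAFit(
        locus_ids=tuple(l.locus_id for l in loci),
        theta_site=thetaLp / Lp,
        T_hat=float(x - 1.0),
        X2=float(dev_s.sum() + dev_d.sum()),
        expected_S=ES,
        expected_D=ED,
        dev_poly=dev_s,
        dev_div=dev_d,
        converged=True,
    )


def hka_statistic(fit: HKAFit) -> float:
    """The fitted goodness-of-fit statistic (sum of deviance components)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if not np.isfinite(fit.X2):
        raise ValueError("zero variance at a locus with non-matching observation")
    return fit.X2


def hka_candidate_test(
    candidate: HKALocusInput,
    references: Sequence[HKALocusInput],
    n_sim: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> HKAResult:
    """Per-candidate multi-locus HKA test against neutral reference loci.

    Fits candidate + references jointly, then simulates ``n_sim`` neutral
    datasets at the fitted parameters (joint coalescent of each locus's
    ingroup sample plus one outgroup lineage entering at T), refits each,
    and reports p = (1 + #{X2_sim >= X2_obs}) / (n_sim + 1).
    """
    if candidate.is_reference:
        raise ValueError("candidate must not be flagged as a reference locus")
    if not references:
        raise ValueError("HKA candidate test needs >=1 reference locus")
    loci = [candidate, *references]
    fit = estimate_hka_parameters(loci)
    x2_obs = hka_statistic(fit)

    Lp = np.array([l.L_poly for l in loci], dtype=float)
    Ld = np.array([l.L_div for l in loci], dtype=float)
    ns = [l.n_ingroup for l in loci]
    a1 = np.array([harmonic(m) for m in ns])
    a2 = np.array([harmonic(m, power=2) for m in ns])
    T_sim = max(fit.T_hat, 0.0)

    S_sim = np.empty((n_sim, len(loci)))
    D_sim = np.empty((n_sim, len(loci)))
    for i, locus in enumerate(loci):
        rng = derive_rng(seed, "hka-null", candidate.locus_id, locus.locus_id)
        S_i, D_i = ingroup_outgroup_replicates(
            locus.n_ingroup,
            theta_poly=float(fit.theta_site[i] * Lp[i]),
            theta_div=float(fit.theta_site[i] * Ld[i]),
            T=T_sim,
            reps=n_sim,
            rng=rng,
        )
        S_sim[:, i] = S_i
        D_sim[:, i] = D_i

    x2_sim = refit_x2(S_sim, D_sim, Lp, Ld, a1, a2)
    p = (1 + int(np.sum(x2_sim >= x2_obs))) / (n_sim + 1)
    return HKAResult(candidate.locus_id, x2_obs, p, n_sim, p < alpha)


def refit_x2(S, D, Lp, Ld, a1, a2) -> np.ndarray:
    """Refit every simulated dataset and return its X^2 (vectorised)."""
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    ok = (S.sum(axis=-1) + D.sum(axis=-1) > 0) & (D.sum(axis=-1) > 0)
    x2 = np.zeros(S.shape[0])
    if np.any(ok):
        thetaLp, x = _fit_arrays(S[ok], D[ok], Lp, Ld, a1)
        dev_s, dev_d, _, _ = _x2_arrays(S[ok], D[ok], thetaLp, x, Lp, Ld, a1, a2)
        x2[ok] = dev_s.sum(axis=-1) + dev_d.sum(axis=-1)
    return x2
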