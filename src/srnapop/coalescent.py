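"""Vectorised Kingman-coalescent null engines.

Three simulators share one tree sampler:

* neutral single-population replicates (Poisson infinite-sites mutations) —
  used for estimator calibration and sequence emission;
* the fixed-S null for Tajima's D significance (Hudson's conditional-on-S
  approach: a genealogy is simulated and exactly S mutations are placed
  multinomially by branch length);
* the joint ingroup + outgroup simulator behind the HKA test's parametric
  null, which returns per-replicate segregating-site counts S and mean
  pairwise ingroup-to-outgroup divergence D.

Time is measured in 2N generations throughout, so a pair of lineages
coalesces at rate 1 and a per-locus mutation rate theta places mutations at
rate theta/2 per lineage per unit time (E[S] = theta * a1(n)).

Trees are simulated in batches: all replicates advance through the same
merge schedule (k = n..2), so every step is a handful of numpy operations
on replicate-length vectors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a (seed, keys...) address.

    Every stochastic operation in the package derives its stream this way,
    so reruns with the same master seed are bit-identical regardless of
    execution order.
    """
    tokens = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tokens])


def sample_trees(
    n: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``reps`` genealogies of ``n`` tips.

    Returns (lengths, counts), each of shape (reps, 2n-2): the branch length
    and descendant-leaf count of every non-root branch.  All branches have
    1 <= count <= n-1, so every mutation placed on them is segregating.
    """
    if n < 2:
        raise ValueError("a genealogy needs n >= 2 tips")
    R = reps
    lens = np.zeros((R, n))
    cnts = np.ones((R, n), dtype=np.int64)
    out_len = np.empty((R, 2 * (n - 1)))
    out_cnt = np.empty((R, 2 * (n - 1)), dtype=np.int64)
    rows = np.arange(R)
    ptr = 0
    for k in range(n, 1, -1):
        lens[:, :k] += rng.exponential(2.0 / (k * (k - 1)), size=R)[:, None]
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = j + (j >= i)
        out_len[:, ptr] = lens[rows, i]
        out_cnt[:, ptr] = cnts[rows, i]
        out_len[:, ptr + 1] = lens[rows, j]
        out_cnt[:, ptr + 1] = cnts[rows, j]
        ptr += 2
        cnts[rows, i] += cnts[rows, j]
        lens[rows, i] = 0.0
        move = j != k - 1
        mr = rows[move]
        cnts[mr, j[move]] = cnts[mr, k - 1]
        lens[mr, j[move]] = lens[mr, k - 1]
    return out_len, out_cnt


def _pi_from_mutations(muts: np.ndarray, counts: np.ndarray, n: int) -> np.ndarray:
    """k-hat per replicate from per-branch mutation counts."""
    pairs = n * (n - 1) / 2.0
    return (muts * counts * (n - counts)).sum(axis=1) / pairs


def fixed_s_replicates(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(S_array, pi_array) under the fixed-S conditional null.

    Exactly S mutations are distributed over the genealogy's branches with
    probability proportional to branch length.
    """
    if S < 1:
        raise ValueError("fixed-S simulation needs S >= 1")
    lens, cnts = sample_trees(n, reps, rng)
    p = lens / lens.sum(axis=1, keepdims=True)
    muts = rng.multinomial(S, p)
    pi = _pi_from_mutations(muts, cnts, n)
    return np.full(reps, S), pi


def neutral_replicates(
    n: int, theta_locus: float, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(S, pi) per replicate under the neutral infinite-sites model."""
    if theta_locus < 0:
        raise ValueError("theta must be >= 0")
    lens, cnts = sample_trees(n, reps, rng)
    muts = rng.poisson(0.5 * theta_locus * lens)
    return muts.sum(axis=1), _pi_from_mutations(muts, cnts, n)


def neutral_alignment(
    n: int,
    theta_locus: float,
    length: int,
    rng: np.random.Generator,
    saturation_warn: float = 0.1,
) -> list[str]:
    """Emit one neutral replicate as gap-free sequences of ``length`` bases.

    Infinite-sites mutations are mapped onto distinct columns (sampled
    without replacement), so sequence-level S and pi recover the tree-level
    values exactly.  If mutations outnumber columns the surplus is dropped
    after a warning (finite-sequence saturation).
    """
    import warnings

    lens, cnts = sample_trees(n, 1, rng)
    muts = rng.poisson(0.5 * theta_locus * lens[0])
    total = int(muts.sum())
    if total > length:
        warnings.warn(
            f"{total} mutations for {length} sites; truncating to {length}"
        )
    elif total > saturation_warn * length:
        warnings.warn(
            f"mutation count {total} exceeds {saturation_warn:.0%} of "
            f"sequence length {length}; infinite-sites mapping is saturating"
        )
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=length)
    seqs = np.tile(ref, (n, 1))
    positions = rng.choice(length, size=min(total, length), replace=False)
    # assign each mutation a carrier set by re-drawing the branch's leaf set
    pos_iter = iter(positions)
    leaf_sets = _leaf_sets_single_tree(n, cnts[0], muts, rng)
    for leaves, pos in zip(leaf_sets, pos_iter):
        cur = seqs[0, pos]
        alt = rng.choice(bases[bases != cur])
        seqs[leaves, pos] = alt
    return ["".join(row) for row in seqs]


def _leaf_sets_single_tree(n, cnts, muts, rng):
    """Random leaf subsets consistent with branch descendant counts.

    Exchangeability of tips means a branch with c descendants subtends a
    uniformly random c-subset; for summary statistics on a single emitted
    alignment this is distributionally exact.
    """
    sets = []
    for b in np.flatnonzero(muts):
        c = int(cnts[b])
        leaves = rng.choice(n, size=c, replace=False)
        for _ in range(int(muts[b])):
            sets.append(leaves)
    rng.shuffle(sets)
    return sets


# ---------------------------------------------------------------------------
# joint ingroup + outgroup engine for the HKA null


@dataclass
class LabeledTrees:
    """Batch of genealogies with branch spans and parent pointers."""

    n: int
    tstart: np.ndarray  # (R, 2n-1)
    tend: np.ndarray  # (R, 2n-1); NaN for the root lineage
    count: np.ndarray  # (R, 2n-1) ingroup descendant counts
    parent: np.ndarray  # (R, 2n-1); -1 for the root
    mrca: np.ndarray  # (R,) ingroup MRCA times


def sample_labeled_trees(n: int, reps: int, rng: np.random.Generator) -> LabeledTrees:
    R = reps
    B = 2 * n - 1
    tstart = np.zeros((R, B))
    tend = np.full((R, B), np.nan)
    count = np.zeros((R, B), dtype=np.int64)
    count[:, :n] = 1
    parent = np.full((R, B), -1, dtype=np.int64)
    slot = np.tile(np.arange(n), (R, 1))
    t = np.zeros(R)
    rows = np.arange(R)
    for step, k in enumerate(range(n, 1, -1)):
        t = t + rng.exponential(2.0 / (k * (k - 1)), size=R)
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = j + (j >= i)
        a = slot[rows, i]
        b = slot[rows, j]
        new = n + step
        tend[rows, a] = t
        tend[rows, b] = t
        parent[rows, a] = new
        parent[rows, b] = new
        tstart[:, new] = t
        count[:, new] = count[rows, a] + count[rows, b]
        slot[rows, i] = new
        move = j != k - 1
        slot[rows[move], j[move]] = slot[rows[move], k - 1]
    return LabeledTrees(n, tstart, tend, count, parent, t)


def ingroup_outgroup_replicates(
    n: int,
    theta_poly: float,
    theta_div: float,
    T: float,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (S, D) for one locus under the neutral two-species model.

    The ingroup genealogy is a standard n-coalescent; a single outgroup
    lineage enters at the species-split time T and attaches to the ingroup
    tree with hazard equal to the number of extant ancestral lineages
    (consistency construction of the Kingman coalescent, equal ancestral
    population size).  ``theta_poly`` is the per-locus rate on columns
    scored for polymorphism, ``theta_div`` the rate on columns shared with
    the outgroup; shared mutations are drawn once at the common rate so the
    S/D correlation is preserved, and rate surpluses are added privately.

    Returns S (segregating sites among the n ingroup sequences) and D (mean
    pairwise ingroup-vs-outgroup differences).
    """
    if T < 0:
        raise ValueError("split time T must be >= 0")
    trees = sample_labeled_trees(n, reps, rng)
    B = 2 * n - 2  # non-root branches
    blen = trees.tend[:, :B] - trees.tstart[:, :B]
    cnt = trees.count[:, :B]

    theta_shared = min(theta_poly, theta_div)
    m_shared = rng.poisson(0.5 * theta_shared * blen)
    S = m_shared.sum(axis=1).astype(float)
    D = (m_shared * cnt).sum(axis=1) / n
    if theta_poly > theta_div:
        S = S + rng.poisson(0.5 * (theta_poly - theta_div) * blen).sum(axis=1)
        m_div = m_shared
    elif theta_div > theta_poly:
        extra = rng.poisson(0.5 * (theta_div - theta_poly) * blen)
        D = D + (extra * cnt).sum(axis=1) / n
        m_div = m_shared + extra
    else:
        m_div = m_shared

    # outgroup attachment time tau per replicate
    events = trees.tstart[:, n:]  # (R, n-1), ascending merge times
    u = rng.exponential(1.0, size=reps)
    tau = np.empty(reps)
    for r in range(reps):
        ev = events[r]
        idx = int(np.searchsorted(ev, T, side="right"))
        cur = T
        k = n - idx
        rem = u[r]
        while k > 1:
            seg = ev[idx] - cur
            if rem <= k * seg:
                break
            rem -= k * seg
            cur = ev[idx]
            idx += 1
            k -= 1
        tau[r] = cur + rem / k

    D = D + rng.poisson(0.5 * theta_div * tau)  # outgroup branch, weight 1

    # per-replicate attachment branch and ancestor weight corrections
    root = 2 * n - 2
    tstart, tend, parent, count = (
        trees.tstart, trees.tend, trees.parent, trees.count,
    )
    for r in range(reps):
        if tau[r] >= trees.mrca[r]:
            # attaches above the ingroup MRCA: mutations there are fixed
            # differences, weight 1 each
            D[r] += rng.poisson(0.5 * theta_div * (tau[r] - trees.mrca[r]))
            continue
        alive = np.flatnonzero(
            (tstart[r] <= tau[r]) & ~(tend[r] <= tau[r])
        )
        b = int(alive[rng.integers(0, alive.size)])
        if b == root:  # pragma: no cover - excluded by the mrca branch above
            continue
        span = tend[r, b] - tstart[r, b]
        m_above = rng.binomial(int(m_div[r, b]), (tend[r, b] - tau[r]) / span)
        c = count[r, b]
        D[r] += m_above * (n - 2 * c) / n
        a = parent[r, b]
        while a != root and a != -1:
            D[r] += m_div[r, a] * (n - 2 * count[r, a]) / n
            a = parent[r, a]
    return S.astype(np.int64), D
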