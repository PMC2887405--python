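"""Self-validation experiments: estimator and test calibration, end-to-end
sweep recovery.

These are the experiments the package runs on itself to demonstrate that
its estimators are unbiased, its tests hold their nominal size, and the
full screen recovers an engineered cultivated-only sweep.  Problem sizes
default to values that give informative Monte-Carlo precision on a single
CPU in a few minutes; every experiment is driven by one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coalescent import (
    derive_rng,
    ingroup_outgroup_replicates,
    neutral_alignment,
)
from .diversity import diversity_stats, harmonic, region_diversity
from .hka import HKALocusInput, hka_candidate_test
from .neutrality import fixed_s_null_d, tajimas_d_array
from .panel import AlignedLocus, extract_core_alignment
from .pipeline import PipelineConfig, bundle_from_dataset, run_selection_screen
from .simulate import (
    SimulationConfig,
    inject_sweep_locus,
    simulate_domestication_panel,
)


def estimator_calibration(
    seed: int,
    n: int = 20,
    theta_site: float = 0.01,
    length: int = 600,
    reps: int = 2000,
    null_reps: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Neutral-coalescent calibration of pi, theta_W, D and the fixed-S test.

    Each replicate is emitted as a finite alignment and measured through the
    ordinary diversity path; type-I error of the fixed-S test is the
    rejection rate of two-tailed p < alpha over the defined-D replicates
    (nulls shared between replicates with equal S).
    """
    theta_locus = theta_site * length
    pis, thetas, S_all = [], [], []
    for r in range(reps):
        rng = derive_rng(seed, "estcal", r)
        seqs = neutral_alignment(n, theta_locus, length, rng)
        locus = AlignedLocus(f"rep{r}", tuple(
            (f"s{i}", s) for i, s in enumerate(seqs)
        ))
        st = diversity_stats(extract_core_alignment(locus))
        pis.append(st.pi_site)
        thetas.append(st.theta_w_site)
        S_all.append(st.S)
    pis = np.asarray(pis)
    thetas = np.asarray(thetas)
    S_all = np.asarray(S_all)
    d = tajimas_d_array(S_all, pis * length, n)

    rejected = 0
    tested = 0
    for s in np.unique(S_all[S_all > 0]):
        null = fixed_s_null_d(n, int(s), null_reps, derive_rng(seed, "estnull", int(s)))
        for obs in d[S_all == s]:
            p = (1 + np.sum(np.abs(null) >= abs(obs))) / (null.size + 1)
            rejected += p < alpha
            tested += 1
    return {
        "mean_pi_site": float(pis.mean()),
        "mean_theta_w_site": float(thetas.mean()),
        "se_pi_site": float(pis.std(ddof=1) / math.sqrt(reps)),
        "se_theta_w_site": float(thetas.std(ddof=1) / math.sqrt(reps)),
        "mean_tajima_d": float(np.nanmean(d)),
        "tajima_type1_rate": rejected / tested,
        "n_tested": tested,
        "reps": reps,
    }


def hka_calibration(
    seed: int,
    k_loci: int = 5,
    n: int = 20,
    theta_site: float = 0.01,
    length: int = 600,
    T: float = 5.0,
    n_datasets: int = 800,
    n_sim: int = 300,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the per-candidate HKA test under joint neutrality.

    Datasets of k loci are simulated at the true parameters; the first locus
    plays the candidate, the rest the neutral references.
    """
    theta_locus = theta_site * length
    obs = []
    for i in range(k_loci):
        rng = derive_rng(seed, "hkacal-obs", i)
        S, D = ingroup_outgroup_replicates(
            n, theta_locus, theta_locus, T, n_datasets, rng
        )
        obs.append((S, D))
    rejected = 0
    for d in range(n_datasets):
        loci = [
            HKALocusInput(
                f"L{i}", n, length, int(obs[i][0][d]), length,
                float(obs[i][1][d]), is_reference=(i > 0),
            )
            for i in range(k_loci)
        ]
        res = hka_candidate_test(
            loci[0], loci[1:], n_sim=n_sim,
            seed=int(derive_rng(seed, "hkacal-null", d).integers(2**31 - 1)),
            alpha=alpha,
        )
        rejected += res.p_value < alpha
    return {
        "hka_type1_rate": rejected / n_datasets,
        "n_datasets": n_datasets,
        "n_sim": n_sim,
    }


@dataclass(frozen=True)
class SweepRecoveryResult:
    sole_putative_rate: float
    sweep_putative_rate: float
    neutral_false_putative_rate: float
    replicates: int


def sweep_recovery(
    seed: int,
    replicates: int = 100,
    tajima_reps: int = 1000,
    hka_sims: int = 500,
) -> SweepRecoveryResult:
    """End-to-end screen power on a compact panel with one engineered sweep.

    The panel holds 4 neutral reference genes and 2 candidate loci, one of
    which is replaced by a cultivated-only post-sweep star genealogy.  A
    replicate scores a success when the swept locus is the *sole* Putative
    call.  The panel is deliberately small: the sole-call probability is
    bounded above by the wild-population false-veto rate times
    (1 - per-locus false-Putative rate)^K for K neutral candidates, so the
    sole-call probability decays with every neutral candidate added (see
    the methods note for the power analysis).
    """
    master = derive_rng(seed, "sweepexp")
    sole = sweep_put = neutral_fp = 0
    for rep in range(replicates):
        rep_seed = int(master.integers(2**31 - 1))
        cfg = SimulationConfig(seed=rep_seed, n_loci=6, n_reference=4)
        ds = inject_sweep_locus(simulate_domestication_panel(cfg), "SIM001")
        pc = PipelineConfig(
            loci_dir="", panel_path="", annotations_path="", out_dir="",
            seed=rep_seed, tajima_reps=tajima_reps, hka_sims=hka_sims,
        )
        out = run_selection_screen(pc, bundle=bundle_from_dataset(ds))
        sel = out["selection"].set_index("locus_id")["candidate_status"]
        putative = set(sel[sel == "Putative"].index)
        sweep_put += "SIM001" in putative
        neutral_fp += "SIM002" in putative
        sole += putative == {"SIM001"}
    return SweepRecoveryResult(
        sole_putative_rate=sole / replicates,
        sweep_putative_rate=sweep_put / replicates,
        neutral_false_putative_rate=neutral_fp / replicates,
        replicates=replicates,
    )


def stratified_region_contrast(seed: int, n_loci: int = 80) -> dict:
    """Mature vs flank diversity under per-region mutation-rate multipliers.

    With the default profile (mature 0.3x, flanks 1.0x) the aggregated
    mature-region pi must fall below the flank pi, mirroring purifying
    selection on the mature small RNA.
    """
    cfg = SimulationConfig(seed=seed, n_loci=n_loci, n_reference=0)
    ds = simulate_domestication_panel(cfg)
    mature, flank = [], []
    for locus in ds.loci:
        ann = ds.annotation(locus.locus_id)
        ids = ds.panel.accessions("cultivated", within=locus.accession_ids)
        rd = region_diversity(extract_core_alignment(locus, ids), ann)
        m = rd["mature"].pi_site
        f = np.nanmean([rd["upstream"].pi_site, rd["downstream"].pi_site])
        if not math.isnan(m):
            mature.append(m)
        if not math.isnan(f):
            flank.append(f)
    return {
        "mature_pi_site": float(np.mean(mature)),
        "flank_pi_site": float(np.mean(flank)),
        "n_loci": n_loci,
    }
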