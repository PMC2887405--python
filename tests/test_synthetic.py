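import math

import numpy as np
import pytest

from srnapop.coalescent import derive_rng, neutral_alignment
from srnapop.diversity import diversity_stats, harmonic
from srnapop.panel import AlignedLocus, extract_core_alignment
from srnapop.pipeline import load_bundle
from srnapop.simulate import (
    SimulationConfig,
    inject_sweep_locus,
    simulate_domestication_panel,
    simulate_fixed_s,
    simulate_neutral_locus,
)


def test_zero_theta_gives_identical_sequences():
    seqs = neutral_alignment(6, 0.0, 100, derive_rng(1, "z"))
    assert len(set(seqs)) == 1


def test_expected_segregating_sites_analytic():
    # E[S] = theta * a1(n)
    for n, theta in ((2, 4.0), (10, 5.0)):
        S, _ = simulate_neutral_locus(n, theta, seed=13, reps=20_000)
        expect = theta * harmonic(n)
        se = S.std(ddof=1) / math.sqrt(S.size)
        assert abs(S.mean() - expect) < 3 * se


def test_fixed_s_mean_d_near_zero():
    from srnapop.neutrality import tajimas_d_array

    # the conditional null is centred close to (not exactly at) zero: the
    # 1989 variance normalisation is itself approximate
    S, pi = simulate_fixed_s(20, 10, seed=29, reps=10_000)
    d = tajimas_d_array(S, pi, 20)
    assert abs(np.mean(d)) < 0.15


def test_seeded_determinism():
    a = simulate_neutral_locus(10, 5.0, seed=3, reps=50)
    b = simulate_neutral_locus(10, 5.0, seed=3, reps=50)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c1 = simulate_domestication_panel(SimulationConfig(seed=8, n_loci=2, n_reference=0))
    c2 = simulate_domestication_panel(SimulationConfig(seed=8, n_loci=2, n_reference=0))
    assert c1.loci[0].sequences == c2.loci[0].sequences


def test_alignment_emission_matches_tree_statistics():
    """Sequence-level S equals the tree-level mutation count (distinct
    positions, no saturation)."""
    rng = derive_rng(4, "emit")
    seqs = neutral_alignment(8, 3.0, 600, rng)
    locus = AlignedLocus("t", tuple((f"s{i}", s) for i, s in enumerate(seqs)))
    stats = diversity_stats(extract_core_alignment(locus))
    assert stats.L == 600
    assert stats.S >= 0  # structural: no gaps, full core


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, bottleneck_strength=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, bottleneck_duration=0.6, split_time_wild_cult=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, outgroup_divergence=0.3)


def test_panel_round_trips_through_panel_io(tmp_path):
    cfg = SimulationConfig(seed=21, n_loci=3, n_reference=1, indel_rate=0.5)
    ds = simulate_domestication_panel(cfg)
    ds.write(tmp_path)
    bundle = load_bundle(tmp_path / "loci", tmp_path / "panel.tsv",
                         tmp_path / "annotations.tsv")
    assert set(bundle.loci) == {l.locus_id for l in ds.loci}
    for lid, locus in bundle.loci.items():
        assert locus.sequences == ds.locus(lid).sequences
    total = cfg.n_indica + cfg.n_japonica + cfg.n_wild + cfg.n_outgroup
    assert len(bundle.panel.entries) == total


def test_bottleneck_reduces_cultivated_diversity_monotonically():
    """Mean wild/cultivated fold reduction grows as the bottleneck deepens."""
    folds = []
    for strength in (1.0, 0.3, 0.05):
        cfg = SimulationConfig(
            seed=31, n_loci=30, n_reference=30,
            bottleneck_strength=strength,
        )
        ds = simulate_domestication_panel(cfg)
        pw, pc = [], []
        for locus in ds.loci:
            wid = ds.panel.accessions("wild", within=locus.accession_ids)
            cid = ds.panel.accessions("cultivated", within=locus.accession_ids)
            pw.append(diversity_stats(extract_core_alignment(locus, wid)).pi_site)
            pc.append(diversity_stats(extract_core_alignment(locus, cid)).pi_site)
        folds.append(np.mean(pw) / np.mean(pc))
    assert folds[0] == pytest.approx(1.0, abs=0.35)  # no bottleneck
    assert folds[0] < folds[1] < folds[2]


def test_parameter_recovery_watterson():
    """Watterson estimates across 200 neutral loci recover theta_site with
    relative bias < 5%."""
    theta = 0.005
    cfg = SimulationConfig(seed=37, n_loci=200, n_reference=200, theta_site=theta)
    ds = simulate_domestication_panel(cfg)
    est = []
    for locus in ds.loci:
        wid = ds.panel.accessions("wild", within=locus.accession_ids)
        est.append(diversity_stats(extract_core_alignment(locus, wid)).theta_w_site)
    assert abs(np.mean(est) - theta) / theta < 0.05


def test_sweep_injection_reduces_cultivated_diversity_only():
    cfg = SimulationConfig(seed=41, n_loci=5, n_reference=0)
    ds = simulate_domestication_panel(cfg)
    swept = inject_sweep_locus(ds, "SIM002")
    locus0, locus1 = ds.locus("SIM002"), swept.locus("SIM002")
    wid = ds.panel.accessions("wild", within=locus0.accession_ids)
    cid = ds.panel.accessions("cultivated", within=locus0.accession_ids)
    # wild untouched
    w0 = [s for a, s in locus0.sequences if a in wid]
    w1 = [s for a, s in locus1.sequences if a in wid]
    assert w0 == w1
    pi0 = diversity_stats(extract_core_alignment(locus1, wid)).pi_site
    pi1 = diversity_stats(extract_core_alignment(locus1, cid)).pi_site
    assert pi1 < pi0
    assert bool(swept.truth.set_index("locus_id").loc["SIM002", "swept"])


def test_sweep_gives_negative_d_in_cultivated():
    from srnapop.neutrality import tajimas_d

    neg = 0
    for rep in range(10):
        cfg = SimulationConfig(seed=300 + rep, n_loci=1, n_reference=0)
        ds = inject_sweep_locus(simulate_domestication_panel(cfg), "SIM001")
        locus = ds.locus("SIM001")
        cid = ds.panel.accessions(subgroup="indica", within=locus.accession_ids)
        st = diversity_stats(extract_core_alignment(locus, cid))
        d = tajimas_d(st.S, st.pi_locus, st.n)
        neg += (not math.isnan(d)) and d < -1.5
    assert neg >= 8
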