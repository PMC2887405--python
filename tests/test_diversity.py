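import math

import numpy as np
import pytest

from srnapop.panel import AlignedLocus, LocusAnnotation, Region, extract_core_alignment
from srnapop.diversity import (
    aggregate,
    diversity_stats,
    find_segregating_sites,
    harmonic,
    pairwise_pi,
    region_diversity,
    watterson_theta,
)

from conftest import random_locus


def brute_force_pi(seqs):
    """Independent O(n^2 L) recount of mean pairwise differences."""
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2)


def make_core(seqs):
    locus = AlignedLocus("t", tuple((f"s{i}", s) for i, s in enumerate(seqs)))
    return extract_core_alignment(locus)


def test_segregating_sites_basic():
    cat = find_segregating_sites(make_core(["ACGT", "ACGA", "ACGT"]))
    assert cat.S == 1
    site = cat.sites[0]
    assert site.core_position == 3
    assert site.alleles == {"T": 2, "A": 1}


def test_segregating_sites_identity_and_indel():
    assert find_segregating_sites(make_core(["ACGT", "ACGT"])).S == 0
    cat = find_segregating_sites(make_core(["AC--T", "ACGGT"]))
    assert cat.S == 0
    assert len(cat.indels) == 1
    assert cat.indels[0].length == 2


def test_multiallelic_column_is_one_site():
    cat = find_segregating_sites(make_core(["A", "C", "G"]))
    assert cat.S == 1
    assert len(cat.sites[0].alleles) == 3


@pytest.mark.parametrize(
    "S,n,expected",
    [(3, 4, 3 / (1 + 1 / 2 + 1 / 3)), (0, 7, 0.0), (10, 2, 10.0)],
)
def test_watterson_theta(S, n, expected):
    assert watterson_theta(S, n) == pytest.approx(expected, rel=1e-12)


def test_watterson_theta_rejects_n1():
    with pytest.raises(ValueError):
        watterson_theta(1, 1)


def test_pairwise_pi_examples():
    k, per_site = pairwise_pi(make_core(["AA", "AT", "TT"]))
    assert k == pytest.approx(4 / 3)
    assert per_site == pytest.approx(2 / 3)
    assert pairwise_pi(make_core(["ACGT", "ACGT"]))[0] == 0.0


def test_pi_matches_brute_force_recount():
    """Allele-count pi equals the brute-force pairwise double loop exactly."""
    rng = np.random.default_rng(20240901)
    for _ in range(300):
        locus = random_locus(rng)
        core = extract_core_alignment(locus)
        seqs = ["".join(r) for r in core.matrix]
        k_hat, _ = pairwise_pi(core)
        assert k_hat == pytest.approx(brute_force_pi(seqs), abs=1e-12)


def test_diversity_stats_consistency():
    core = make_core(["ACGT", "ACGA", "TCGA"])
    st = diversity_stats(core)
    assert st.S == 2
    assert st.theta_w_locus == pytest.approx(st.S / harmonic(3))
    assert st.snp_per_kb == pytest.approx(1000 * st.S / st.L)
    assert st.theta_w_site == pytest.approx(st.theta_w_locus / st.L)


def test_empty_core_is_flagged_undefined():
    st = diversity_stats(make_core(["----", "AAAA"]))
    assert st.L == 0 and not st.defined
    assert math.isnan(st.pi_site)


def test_s_monotone_in_sequences():
    """Adding a sequence never decreases S on the same kept columns."""
    rng = np.random.default_rng(7)
    locus = random_locus(rng, n=8, L=40)
    ids = list(locus.accession_ids)
    core_all = extract_core_alignment(locus, ids)
    s_small = find_segregating_sites(
        core_all.restrict(np.arange(core_all.L))
    ).S
    # same columns, fewer rows
    sub = extract_core_alignment(locus, ids[:4])
    s_sub = find_segregating_sites(sub.restrict(core_all.kept_columns)).S
    assert s_sub <= s_small


def test_region_diversity_partitions_variation():
    seqs = ["AAAAACCCCC", "AAAAACCCCC", "AATAACCCCC"]  # SNP at column 2
    ann = LocusAnnotation(
        "t", "MIRNA", "conserved",
        (Region("mature", 0, 5), Region("downstream", 5, 10)),
    )
    out = region_diversity(make_core(seqs), ann)
    assert out["mature"].S == 1 and out["mature"].pi_site > 0
    assert out["downstream"].S == 0 and out["downstream"].pi_site == 0.0


def test_region_lost_from_core_is_undefined():
    seqs = ["--AAA", "--AAA", "CCAAA"]
    ann = LocusAnnotation("t", "MIRNA", "conserved", (Region("mature", 0, 2),))
    out = region_diversity(make_core(seqs), ann)
    assert not out["mature"].defined


def test_aggregate_mean_sem():
    agg = aggregate("g", [1.0, 2.0, 3.0])
    assert agg.mean == pytest.approx(2.0)
    assert agg.sem == pytest.approx(1 / math.sqrt(3))
    assert aggregate("one", [5.0]).sem == 0.0
    with pytest.raises(ValueError):
        aggregate("none", [])


def test_estimators_unbiased_under_neutral_coalescent():
    """E[pi] = E[theta_W] = theta under the neutral model (reduced reps)."""
    from srnapop.coalescent import derive_rng, neutral_replicates

    theta, n, reps = 5.0, 12, 4000
    S, pi = neutral_replicates(n, theta, reps, derive_rng(17, "unbiased"))
    theta_w = S / harmonic(n)
    for est in (pi, theta_w):
        se = est.std(ddof=1) / math.sqrt(reps)
        assert abs(est.mean() - theta) < 3 * se
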