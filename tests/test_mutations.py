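import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnapop.panel import AlignedLocus, LocusAnnotation, Region, extract_core_alignment
from srnapop.diversity import find_segregating_sites
from srnapop.mutations import (
    allele_frequencies_by_population,
    catalog_region_mutations,
    scan_targets,
    target_penalty_score,
)

COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp_rna(seq):
    return "".join(COMP[b] for b in reversed(seq))


def brute_force_scan(mirna, transcripts, max_penalty):
    """Dumb per-window, per-position rescoring oracle."""
    k = len(mirna)
    hits = []
    for tid, seq in transcripts.items():
        for w in range(len(seq) - k + 1):
            site = seq[w : w + k]
            pen = 0.0
            for j in range(k):
                mi = mirna[j].upper().replace("T", "U")
                sb = site[k - 1 - j].upper().replace("T", "U")
                if COMP.get(mi) == sb:
                    pass
                elif (mi, sb) in (("G", "U"), ("U", "G")):
                    pen += 0.5
                else:
                    pen += 1.0
            if pen <= max_penalty:
                hits.append((pen, tid, w))
    return sorted(hits)


def test_penalty_examples():
    mir = "UGGAGCUCCCUUCAUUCCAAU"
    assert target_penalty_score(mir, revcomp_rna(mir)) == 0.0
    # one G:U wobble: miRNA position 1 (G) pairs with site position len-2
    site = list(revcomp_rna(mir))
    site[len(site) - 2] = "U"
    assert target_penalty_score(mir, "".join(site)) == 0.5
    # additivity: the wobble plus two mismatches scores 2.5
    for j in (3, 5):
        cur = site[len(site) - 1 - j]
        site[len(site) - 1 - j] = {"A": "C", "C": "A", "G": "A", "U": "C"}[cur]
    assert target_penalty_score(mir, "".join(site)) == 2.5


def test_penalty_t_u_equivalence_and_errors():
    assert target_penalty_score("AUGC", "GCAU") == target_penalty_score("ATGC", "GCAT")
    with pytest.raises(ValueError):
        target_penalty_score("AUG", "AUGC")


def test_scan_finds_exact_site():
    mir = "UGGAGCUCCCUUCAUUCCAAU"
    site = revcomp_rna(mir).replace("U", "T")
    transcript = "A" * 30 + site + "G" * 30
    hits = scan_targets("mir", mir, {"tx1": transcript}, max_penalty=0.0)
    assert len(hits) == 1
    assert hits[0].site_start == 30
    assert hits[0].penalty == 0.0


def test_scan_wobble_excluded_at_zero_penalty():
    mir = "UGGAGCUCCCUUCAUUCCAAU"
    site = list(revcomp_rna(mir))
    site[len(site) - 2] = "U"  # wobble against miRNA G at position 1
    transcript = ("".join(site)).replace("U", "T")
    assert scan_targets("m", mir, {"t": transcript}, max_penalty=0.0) == []
    hits = scan_targets("m", mir, {"t": transcript}, max_penalty=0.5)
    assert len(hits) == 1 and hits[0].penalty == 0.5


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_scan_equals_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    k = int(rng.integers(5, 22))
    mirna = "".join(rng.choice(np.array(list("ACGU")), size=k))
    transcripts = {
        f"t{i}": "".join(rng.choice(bases, size=int(rng.integers(k, 200))))
        for i in range(3)
    }
    max_pen = float(rng.integers(0, 9)) / 2
    hits = scan_targets("m", mirna, transcripts, max_penalty=max_pen)
    expected = brute_force_scan(mirna, transcripts, max_pen)
    assert [(h.penalty, h.transcript_id, h.site_start) for h in hits] == expected


def test_catalog_region_mutations(small_panel):
    # SNP at column 2 (inside mature [0,5)); gap run at columns 6-7
    seqs = {
        "I1": "AATAAC--CC",
        "I2": "AAGAACGGCC",
        "J1": "AAGAACGGCC",
        "J2": "AATAACGGCC",
        "W1": "AAGAACGGCC",
        "W2": "AAGAAC--CC",
        "O1": "AAGAACGGCC",
    }
    locus = AlignedLocus("loc", tuple(seqs.items()))
    ann = LocusAnnotation(
        "loc", "TAS3", "not_applicable",
        (Region("phase", 0, 5, "P5'_5"), Region("phase", 5, 10, "P5'_9")),
    )
    core = extract_core_alignment(locus)
    catalog = find_segregating_sites(core)
    records = catalog_region_mutations(catalog, ann, locus, small_panel)
    snps = [r for r in records if r.mutation_type == "SNP"]
    indels = [r for r in records if r.mutation_type == "indel"]
    assert len(snps) == 1 and len(indels) == 1
    snp = snps[0]
    assert snp.region_name == "P5'_5" and snp.position_in_region == 3
    assert snp.alleles["indica"] == {"T": 1, "G": 1}
    assert snp.alleles["wild"] == {"G": 2}
    assert indels[0].region_name == "P5'_9"

    # completeness: every catalogued SNP in a region appears exactly once,
    # and nothing is reported outside the regions
    ann_partial = LocusAnnotation("loc", "TAS3", "not_applicable",
                                  (Region("phase", 5, 10, "P"),))
    recs = catalog_region_mutations(catalog, ann_partial, locus, small_panel)
    assert all(r.mutation_type == "indel" for r in recs)


def test_allele_frequencies(small_panel):
    seqs = {
        "I1": "G", "I2": "G", "J1": "A", "J2": "A",
        "W1": "G", "W2": "G", "O1": "G",
    }
    locus = AlignedLocus("loc", tuple((a, s) for a, s in seqs.items()))
    ann = LocusAnnotation("loc", "MIRNA", "conserved", (Region("mature", 0, 1),))
    catalog = find_segregating_sites(extract_core_alignment(locus))
    rec = catalog_region_mutations(catalog, ann, locus, small_panel)[0]
    freq = allele_frequencies_by_population(rec)
    cult = freq[freq.population == "cultivated"].set_index("allele")["percent"]
    assert cult["G"] == pytest.approx(50.0)
    wild = freq[freq.population == "wild"].set_index("allele")["percent"]
    assert wild["G"] == pytest.approx(100.0)
    for pop, chunk in freq.groupby("population"):
        assert chunk["percent"].sum() == pytest.approx(100.0)
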