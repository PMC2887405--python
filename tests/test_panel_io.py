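import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnapop.panel import (
    AlignedLocus,
    AlignmentError,
    FormatError,
    PanelError,
    extract_core_alignment,
    read_alignment_fasta,
    read_locus_annotations,
    read_panel_table,
    write_alignment_fasta,
)

from conftest import random_locus


def test_fasta_round_trip(tmp_path):
    locus = AlignedLocus("mir1", (("a", "ACGT-N"), ("b", "ACGTTT"), ("c", "AAGTTT")))
    path = tmp_path / "mir1.fasta"
    write_alignment_fasta(locus, path)
    back = read_alignment_fasta(path)
    assert back == locus
    assert back.alignment_length == 6


def test_fasta_uppercases_and_names_from_stem(tmp_path):
    p = tmp_path / "mir166e.fasta"
    p.write_text(">x\nacgt\n>y\nACGA\n")
    locus = read_alignment_fasta(p)
    assert locus.locus_id == "mir166e"
    assert locus.sequences[0][1] == "ACGT"


def test_fasta_errors(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">x\nACGTA\n>y\nACGT\n")
    with pytest.raises(AlignmentError, match="unequal alignment lengths"):
        read_alignment_fasta(p)
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(FormatError):
        read_alignment_fasta(empty)
    single = tmp_path / "single.fasta"
    single.write_text(">x\nACGT\n")
    with pytest.raises(FormatError, match=">=2 records"):
        read_alignment_fasta(single)


def test_panel_table(tmp_path):
    p = tmp_path / "panel.tsv"
    p.write_text(
        "accession_id\tpopulation\tsubgroup\n"
        "A1\tcultivated\tindica\nW1\twild\tnone\nO1\toutgroup\tnone\n"
    )
    panel = read_panel_table(p)
    assert len(panel.entries) == 3
    assert panel.accessions("wild") == ("W1",)

    dup = tmp_path / "dup.tsv"
    dup.write_text(
        "accession_id\tpopulation\tsubgroup\nA1\tcultivated\tindica\n"
        "A1\tcultivated\tjaponica\n"
    )
    with pytest.raises(PanelError, match="duplicate"):
        read_panel_table(dup)

    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "accession_id\tpopulation\tsubgroup\nO1\toutgroup\tindica\n"
    )
    with pytest.raises(PanelError, match="subgroup 'none'"):
        read_panel_table(bad)


def test_annotations_parse_and_deferred_validation(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text(
        "locus_id\tclass\tconservation\tlabel\tname\tstart\tend\n"
        "mir166e\tMIRNA\tconserved\tprecursor\t\t100\t220\n"
        "mir166e\tMIRNA\tconserved\tmature\t\t120\t141\n"
        "TAS3a2\tTAS3\tnot_applicable\tphase\tP5'_5\t10\t31\n"
        "TAS3a2\tTAS3\tnot_applicable\tphase\tP5'_9\t94\t115\n"
    )
    anns = {a.locus_id: a for a in read_locus_annotations(p)}
    mature = anns["mir166e"].regions_by_label("mature")[0]
    assert mature.end - mature.start == 21
    assert len(anns["TAS3a2"].regions_by_label("phase")) == 2
    # deferred coordinate check fires only against a too-short alignment
    short = AlignedLocus("mir166e", (("a", "A" * 130), ("b", "C" * 130)))
    with pytest.raises(PanelError, match="exceeds"):
        anns["mir166e"].validate_against(short)

    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "locus_id\tclass\tconservation\tlabel\tname\tstart\tend\n"
        "x\tMIRNA\tconserved\tmature\t\t50\t50\n"
    )
    with pytest.raises(FormatError, match="bad span"):
        read_locus_annotations(bad)


def test_core_extraction_drops_gap_and_n_columns():
    locus = AlignedLocus("x", (("a", "AC-TN"), ("b", "ACGTA")))
    core = extract_core_alignment(locus)
    assert core.kept_columns.tolist() == [0, 1, 3]
    assert core.L == 3
    # the gap run is catalogued as one indel event; the N column is not
    assert len(core.indel_events) == 1
    assert (core.indel_events[0].start, core.indel_events[0].end) == (2, 3)


def test_core_extraction_identity_and_remap():
    locus = AlignedLocus("x", (("a", "ACGT"), ("b", "ACGA")))
    core = extract_core_alignment(locus)
    assert core.L == locus.alignment_length
    locus2 = AlignedLocus("y", (("a", "A--CGT"), ("b", "ATTCGA")))
    core2 = extract_core_alignment(locus2)
    # region [1, 5) loses the two gap columns
    assert core2.map_region(1, 5).tolist() == [1, 2]


def test_core_subset_errors():
    locus = AlignedLocus("x", (("a", "ACGT"), ("b", "ACGA")))
    with pytest.raises(PanelError):
        extract_core_alignment(locus, ["a", "zz"])
    with pytest.raises(PanelError):
        extract_core_alignment(locus, [])


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(2, 8))
def test_core_is_idempotent_and_monotone(seed, extra):
    """Re-extracting a core changes nothing; adding sequences never grows L."""
    rng = np.random.default_rng(seed)
    locus = random_locus(rng, n=extra + 2, L=30, gap_frac=0.1)
    ids = list(locus.accession_ids)
    small = extract_core_alignment(locus, ids[:2])
    big = extract_core_alignment(locus, ids)
    assert big.L <= small.L
    again = extract_core_alignment(
        AlignedLocus("c", tuple(zip(big.accession_ids,
                                    ("".join(r) for r in big.matrix))))
    )
    assert again.L == big.L
    # remapping is order-preserving and injective
    cols = big.map_region(5, 25)
    assert np.all(np.diff(cols) > 0) or cols.size <= 1
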