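"""Functional-region mutation catalogue and miRNA target-site scanning.

The catalogue lists every SNP or indel event overlapping an annotated
functional region (mature miRNA, ta-siRNA phase, miR390 binding site) with
per-subpopulation allele counts, reported 1-based from the region's 5' end.

The target scanner slides a mature-miRNA-length window along transcripts
and scores miRNA:site duplexes with the standard plant-miRNA penalty
scheme: 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch
(weights configurable); sites with total penalty <= max_penalty (default 4)
are reported.  No gaps or bulges are allowed in a site, and T and U are
interchangeable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import SiteCatalog
from .panel import AlignedLocus, LocusAnnotation, PopulationPanel


@dataclass(frozen=True)
class MutationRecord:
    locus_id: str
    region_label: str
    region_name: str
    position_in_region: int  # 1-based from the region's 5' end
    mutation_type: str  # SNP / indel
    alleles: Mapping[str, Mapping[str, int]]  # group -> allele -> count


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based transcript coordinate
    penalty: float
    site_sequence: str


def _group_of(panel: PopulationPanel, accession: str) -> str:
    e = panel.population_of(accession)
    return e.subgroup if e.population == "cultivated" else e.population


def catalog_region_mutations(
    catalog: SiteCatalog,
    annotation: LocusAnnotation,
    locus: AlignedLocus,
    panel: PopulationPanel,
    accessions: Sequence[str] | None = None,
) -> list[MutationRecord]:
    """Every segregating site or indel event inside a functional region.

    Allele counts are tallied per group (indica / japonica / wild /
    outgroup) over ``accessions`` (default: all sequences in the locus).
    SNP records appear exactly once per (site, region) overlap; sites
    outside every region produce no record.
    """
    ids = tuple(accessions) if accessions is not None else locus.accession_ids
    seqs = dict(locus.sequences)
    groups = {a: _group_of(panel, a) for a in ids}
    records: list[MutationRecord] = []
    for region in annotation.regions:
        for site in catalog.sites:
            pos = site.alignment_position
            if not (region.start <= pos < region.end):
                continue
            counts: dict[str, dict[str, int]] = {}
            for a in ids:
                base = seqs[a][pos]
                g = counts.setdefault(groups[a], {})
                g[base] = g.get(base, 0) + 1
            records.append(
                MutationRecord(
                    locus_id=locus.locus_id,
                    region_label=region.label,
                    region_name=region.name,
                    position_in_region=pos - region.start + 1,
                    mutation_type="SNP",
                    alleles=counts,
                )
            )
        for ev in catalog.indels:
            if ev.end <= region.start or ev.start >= region.end:
                continue
            gap_set = set(ev.gap_accessions)
            counts = {}
            for a in ids:
                allele = "-" * ev.length if a in gap_set else "+"
                g = counts.setdefault(groups[a], {})
                g[allele] = g.get(allele, 0) + 1
            records.append(
                MutationRecord(
                    locus_id=locus.locus_id,
                    region_label=region.label,
                    region_name=region.name,
                    position_in_region=max(ev.start, region.start) - region.start + 1,
                    mutation_type="indel",
                    alleles=counts,
                )
            )
    return records


def allele_frequencies_by_population(
    record: MutationRecord, levels: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Percentage table per population level.

    ``levels`` maps output population names to the groups pooled into them
    (default: cultivated = indica + japonica, wild, outgroup).  Populations
    with zero sequences are omitted; percentages sum to 100 per population.
    """
    if levels is None:
        levels = {
            "cultivated": ("indica", "japonica"),
            "wild": ("wild",),
            "outgroup": ("outgroup",),
        }
    rows = []
    for pop, members in levels.items():
        pooled: dict[str, int] = {}
        for m in members:
            for allele, c in record.alleles.get(m, {}).items():
                pooled[allele] = pooled.get(allele, 0) + c
        total = sum(pooled.values())
        if total == 0:
            continue
        for allele, c in sorted(pooled.items()):
            rows.append(
                {"population": pop, "allele": allele, "count": c,
                 "percent": 100.0 * c / total}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target scanning

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _penalty_table(mismatch: float, wobble: float) -> np.ndarray:
    """5x5 penalty lookup, miRNA base x site base (code 4 = unknown)."""
    table = np.full((5, 5), mismatch)
    # Watson-Crick (antiparallel): A:U, C:G, G:C, U:A
    for mi, site in ((0, 3), (1, 2), (2, 1), (3, 0)):
        table[mi, site] = 0.0
    table[2, 3] = wobble  # G:U
    table[3, 2] = wobble  # U:G
    table[4, :] = mismatch
    table[:, 4] = mismatch
    return table


def _encode_rna(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def target_penalty_score(
    mirna: str, site: str, mismatch: float = 1.0, wobble: float = 0.5
) -> float:
    """Penalty of a miRNA:site duplex (antiparallel, no gaps).

    ``site`` is the target-site sequence read 5'->3' on the transcript, so
    miRNA position j pairs with site position len-1-j.
    """
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal lengths")
    table = _penalty_table(mismatch, wobble)
    mi = _encode_rna(mirna)
    st = _encode_rna(site)[::-1]
    return float(table[mi, st].sum())


def scan_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str],
    max_penalty: float = 4.0,
    mismatch: float = 1.0,
    wobble: float = 0.5,
) -> list[TargetHit]:
    """All candidate target sites with penalty <= max_penalty.

    Slides a window of the mature-miRNA length over each transcript and
    scores every window; hits are sorted by penalty, transcript id, then
    coordinate.
    """
    if not transcripts:
        raise ValueError("no transcripts to scan")
    table = _penalty_table(mismatch, wobble)
    mi = _encode_rna(mirna)
    k = mi.size
    hits: list[TargetHit] = []
    for tid, seq in transcripts.items():
        codes = _encode_rna(seq)
        W = codes.size - k + 1
        if W <= 0:
            continue
        penalties = np.zeros(W)
        for j in range(k):
            # site base pairing miRNA[j] sits at window offset k-1-j
            penalties += table[mi[j], codes[k - 1 - j : k - 1 - j + W]]
        for w in np.flatnonzero(penalties <= max_penalty):
            hits.append(
                TargetHit(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=int(w),
                    penalty=float(penalties[w]),
                    site_sequence=seq[w : w + k],
                )
            )
    hits.sort(key=lambda h: (h.penalty, h.transcript_id, h.site_start))
    return hits
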