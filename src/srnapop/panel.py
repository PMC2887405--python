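"""Input handling for per-locus alignment panels.

The pipeline operates on small genomic loci (~600 bp, one aligned FASTA per
locus) resequenced across a panel of rice accessions: two cultivated
subgroups (indica, japonica), the wild progenitor O. rufipogon, and an
O. barthii outgroup.  All statistics are computed on the *core alignment*:
the subset of columns at which every analysed sequence carries an
unambiguous base (no gaps, no Ns).

Coordinates are 0-based half-open internally; report writers print 1-based
inclusive positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
MISSING = frozenset("-N")
POPULATIONS = ("cultivated", "wild", "outgroup")
SUBGROUPS = ("indica", "japonica", "none")
LOCUS_CLASSES = ("MIRNA", "TAS3", "long_hairpin", "neutral_reference")
CONSERVATION = ("conserved", "species_specific", "not_applicable")
REGION_LABELS = (
    "mature",
    "precursor",
    "upstream",
    "downstream",
    "phase",
    "mir_binding_site",
)


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class AlignmentError(ValueError):
    """An alignment violates a structural invariant."""


class PanelError(ValueError):
    """A sample panel or annotation is inconsistent with the alignments."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AlignedLocus:
    """One locus's multiple-sequence alignment with stable accession order."""

    locus_id: str
    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal alignment lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentError(f"{self.locus_id}: zero-length alignment")
        ids = [a for a, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"{self.locus_id}: duplicate accession ids")
        bad = set("".join(s for _, s in self.sequences)) - VALID_BASES - MISSING
        if bad:
            raise AlignmentError(
                f"{self.locus_id}: invalid alignment characters {sorted(bad)}"
            )

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.sequences)

    def matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        seqs = dict(self.sequences)
        ids = self.accession_ids if subset is None else tuple(subset)
        missing = [a for a in ids if a not in seqs]
        if missing:
            raise PanelError(f"{self.locus_id}: unknown accessions {missing}")
        return np.array([list(seqs[a]) for a in ids], dtype="U1")

    def subset(self, ids: Sequence[str]) -> "AlignedLocus":
        seqs = dict(self.sequences)
        missing = [a for a in ids if a not in seqs]
        if missing:
            raise PanelError(f"{self.locus_id}: unknown accessions {missing}")
        return AlignedLocus(self.locus_id, tuple((a, seqs[a]) for a in ids))


@dataclass(frozen=True)
class PanelEntry:
    population: str
    subgroup: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise PanelError(f"unknown population {self.population!r}")
        if self.subgroup not in SUBGROUPS:
            raise PanelError(f"unknown subgroup {self.subgroup!r}")
        if self.population != "cultivated" and self.subgroup != "none":
            raise PanelError(
                f"{self.population} entries must have subgroup 'none', "
                f"got {self.subgroup!r}"
            )
        if self.population == "cultivated" and self.subgroup == "none":
            raise PanelError("cultivated entries need subgroup indica/japonica")


@dataclass(frozen=True)
class PopulationPanel:
    """Accession -> (population, subgroup) assignment for the whole study."""

    entries: Mapping[str, PanelEntry]

    def population_of(self, accession: str) -> PanelEntry:
        try:
            return self.entries[accession]
        except KeyError:
            raise PanelError(f"accession {accession!r} not in panel") from None

    def accessions(
        self,
        population: str | None = None,
        subgroup: str | None = None,
        within: Iterable[str] | None = None,
    ) -> tuple[str, ...]:
        """Accession ids matching the filters, in panel order.

        ``subgroup`` may also be one of the population names for convenience
        (``"wild"`` selects the wild population).  ``within`` restricts to ids
        present in a given alignment, preserving *panel* order.
        """
        if subgroup in ("wild", "outgroup", "cultivated"):
            population, subgroup = subgroup, None
        ids = [
            a
            for a, e in self.entries.items()
            if (population is None or e.population == population)
            and (subgroup is None or e.subgroup == subgroup)
        ]
        if within is not None:
            keep = set(within)
            ids = [a for a in ids if a in keep]
        return tuple(ids)

    def validate_locus(self, locus: AlignedLocus) -> None:
        unknown = [a for a in locus.accession_ids if a not in self.entries]
        if unknown:
            raise PanelError(
                f"{locus.locus_id}: accessions missing from panel: {unknown}"
            )


@dataclass(frozen=True)
class Region:
    label: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise FormatError(f"unknown region label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"region {self.label}/{self.name}: bad span [{self.start}, {self.end})"
            )

    @property
    def key(self) -> str:
        return f"{self.label}:{self.name}" if self.name else self.label


@dataclass(frozen=True)
class LocusAnnotation:
    locus_id: str
    locus_class: str
    conservation: str
    regions: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        if self.locus_class not in LOCUS_CLASSES:
            raise FormatError(f"unknown locus class {self.locus_class!r}")
        if self.conservation not in CONSERVATION:
            raise FormatError(f"unknown conservation {self.conservation!r}")

    def regions_by_label(self, label: str) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.label == label)

    def validate_against(self, locus: AlignedLocus) -> None:
        """Deferred coordinate check, run when annotation meets alignment."""
        L = locus.alignment_length
        for r in self.regions:
            if r.end > L:
                raise PanelError(
                    f"{self.locus_id}: region {r.key} end {r.end} exceeds "
                    f"alignment length {L}"
                )
        mats = self.regions_by_label("mature")
        pres = self.regions_by_label("precursor")
        for m in mats:
            if pres and not any(p.start <= m.start and m.end <= p.end for p in pres):
                raise PanelError(
                    f"{self.locus_id}: mature region {m.key} not nested in a precursor"
                )


@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of gap-containing alignment columns.

    Indels never enter the SNP-based diversity statistics; they are kept for
    the functional-region mutation catalogue only.
    """

    start: int
    end: int
    n_gap: int
    n_base: int
    gap_accessions: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoreAlignment:
    """Gap-free restriction of an alignment to a subset of accessions."""

    locus_id: str
    accession_ids: tuple[str, ...]
    kept_columns: np.ndarray  # sorted original column indices
    matrix: np.ndarray  # (n, L) single characters, all in ACGT
    alignment_length: int
    indel_events: tuple[IndelEvent, ...] = ()

    @property
    def L(self) -> int:
        return int(self.kept_columns.size)

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def empty(self) -> bool:
        return self.L == 0

    def map_region(self, start: int, end: int) -> np.ndarray:
        """Core-column indices of original columns in [start, end).

        Columns lost from the core simply shrink the region; order is
        preserved and the map is injective.
        """
        lo = int(np.searchsorted(self.kept_columns, start, side="left"))
        hi = int(np.searchsorted(self.kept_columns, end, side="left"))
        return np.arange(lo, hi)

    def restrict(self, core_columns: np.ndarray) -> "CoreAlignment":
        return CoreAlignment(
            locus_id=self.locus_id,
            accession_ids=self.accession_ids,
            kept_columns=self.kept_columns[core_columns],
            matrix=self.matrix[:, core_columns],
            alignment_length=self.alignment_length,
            indel_events=(),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment_fasta(path: str | os.PathLike, locus_id: str | None = None) -> AlignedLocus:
    """Read one locus's aligned FASTA (>=2 records, equal lengths).

    Bases are uppercased; the locus id defaults to the filename stem.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    if len(records) < 2:
        raise FormatError(f"{path}: an alignment needs >=2 records")
    seqs = tuple((r.id, str(r.seq).upper()) for r in records)
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: unequal alignment lengths {sorted(lengths)}")
    return AlignedLocus(locus_id or path.stem, seqs)


def write_alignment_fasta(locus: AlignedLocus, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in locus.sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_panel_table(path: str | os.PathLike) -> PopulationPanel:
    """Read the accession panel TSV (accession_id, population, subgroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"accession_id", "population", "subgroup"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: panel table needs columns {sorted(required)}")
    if df["accession_id"].duplicated().any():
        dups = df.loc[df["accession_id"].duplicated(), "accession_id"].tolist()
        raise PanelError(f"{path}: duplicate accession ids {dups}")
    entries = {}
    for row in df.itertuples(index=False):
        entries[row.accession_id] = PanelEntry(row.population, row.subgroup)
    return PopulationPanel(entries)


def write_panel_table(panel: PopulationPanel, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {"accession_id": a, "population": e.population, "subgroup": e.subgroup}
            for a, e in panel.entries.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_locus_annotations(path: str | os.PathLike) -> list[LocusAnnotation]:
    """Read the annotation TSV.

    Columns: locus_id, class, conservation, label, name, start, end.  One row
    per region; rows with an empty label declare a region-less locus (e.g.
    neutral reference genes).  Coordinates are validated against alignment
    lengths later, when annotations are joined to loci.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"locus_id", "class", "conservation", "label", "name", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation table needs columns {sorted(required)}")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        rec = out.setdefault(
            row["locus_id"],
            {"locus_class": row["class"], "conservation": row["conservation"],
             "regions": []},
        )
        if row["label"]:
            rec["regions"].append(
                Region(row["label"], int(row["start"]), int(row["end"]), row["name"])
            )
    return [
        LocusAnnotation(
            locus_id=lid,
            locus_class=rec["locus_class"],
            conservation=rec["conservation"],
            regions=tuple(rec["regions"]),
        )
        for lid, rec in out.items()
    ]


def write_locus_annotations(
    annotations: Iterable[LocusAnnotation], path: str | os.PathLike
) -> None:
    rows = []
    for ann in annotations:
        if not ann.regions:
            rows.append(
                {"locus_id": ann.locus_id, "class": ann.locus_class,
                 "conservation": ann.conservation, "label": "", "name": "",
                 "start": "", "end": ""}
            )
        for r in ann.regions:
            rows.append(
                {"locus_id": ann.locus_id, "class": ann.locus_class,
                 "conservation": ann.conservation, "label": r.label,
                 "name": r.name, "start": r.start, "end": r.end}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# core-alignment extraction


def extract_core_alignment(
    locus: AlignedLocus, subset: Sequence[str] | None = None
) -> CoreAlignment:
    """Restrict to ``subset`` accessions and keep only all-ACGT columns.

    '-' and 'N' are both treated as missing: a column containing either in any
    retained sequence is dropped.  Maximal runs of *gap*-containing columns
    are recorded as indel events (one event per run) for the mutation
    catalogue; columns dropped for 'N' alone are not indels.
    """
    ids = tuple(subset) if subset is not None else locus.accession_ids
    if not ids:
        raise PanelError(f"{locus.locus_id}: empty accession subset")
    mat = locus.matrix(ids)
    ok = np.isin(mat, list(VALID_BASES))
    keep = ok.all(axis=0)
    kept_columns = np.flatnonzero(keep)

    gap = mat == "-"
    gap_cols = gap.any(axis=0)
    events: list[IndelEvent] = []
    in_run = False
    start = 0
    for col in range(locus.alignment_length + 1):
        is_gap = col < locus.alignment_length and gap_cols[col]
        if is_gap and not in_run:
            in_run, start = True, col
        elif not is_gap and in_run:
            in_run = False
            run_gap = gap[:, start:col].any(axis=1)
            events.append(
                IndelEvent(
                    start=start,
                    end=col,
                    n_gap=int(run_gap.sum()),
                    n_base=int((~run_gap).sum()),
                    gap_accessions=tuple(np.asarray(ids)[run_gap]),
                )
            )
    return CoreAlignment(
        locus_id=locus.locus_id,
        accession_ids=ids,
        kept_columns=kept_columns,
        matrix=mat[:, keep],
        alignment_length=locus.alignment_length,
        indel_events=tuple(events),
    )
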