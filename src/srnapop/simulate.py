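"""Synthetic resequencing panels via the structured coalescent.

The generator emulates a two-subgroup domestication study design: an
ancestral wild population, two cultivated subgroups (indica, japonica)
founded independently from the wild population and squeezed through a
domestication bottleneck, and a distant outgroup used for divergence-based
tests.  Each locus is an independent non-recombining ~600 bp fragment with
an annotated mature/precursor/flank layout whose per-region mutation-rate
multipliers emulate purifying selection on the mature small RNA.

Time is in 2N generations (a lineage pair coalesces at rate 1); the
per-site population mutation rate is theta_site = 4*N*mu.  msprime drives
the structured ancestry and finite-sites JC69 mutations; the package's own
vectorised coalescent engines (``srnapop.coalescent``) supply the
fixed-S and HKA null replicates.

A selective sweep at a locus is emulated by a star genealogy: all
cultivated sequences descend from a single wild haplotype sampled at the
sweep time, each carrying only private mutations accumulated since —
reduced diversity and an excess of rare variants in the cultivated
subgroups only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from . import coalescent
from .coalescent import derive_rng
from .panel import (
    AlignedLocus,
    LocusAnnotation,
    PanelEntry,
    PopulationPanel,
    Region,
    write_alignment_fasta,
    write_locus_annotations,
    write_panel_table,
)

_BASES = np.array(list("ACGT"))

DEFAULT_MULTIPLIERS = {
    "mature": 0.3,
    "precursor": 0.6,
    "upstream": 1.0,
    "downstream": 1.0,
}

# default locus layout (alignment coordinates, 0-based half-open):
# upstream flank | precursor with embedded 21-nt mature | downstream flank
DEFAULT_LAYOUT = {
    "upstream": (0, 240),
    "precursor": (240, 360),
    "mature": (290, 311),
    "downstream": (360, 600),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a synthetic panel.

    Defaults emulate the survey design this pipeline targets: ~600 bp loci,
    17 indica / 16 japonica / 15 wild / 2 outgroup samples, wild-level
    diversity theta_site = 0.005, independent domestication bottlenecks
    reducing neutral cultivated diversity ~2.2-fold, and an outgroup
    divergence of T = 5 (2N units).
    """

    seed: int
    n_loci: int = 10
    n_reference: int = 4  # leading loci are neutral reference genes
    length: int = 600
    theta_site: float = 0.005
    n_indica: int = 17
    n_japonica: int = 16
    n_wild: int = 15
    n_outgroup: int = 2
    split_time_wild_cult: float = 0.5
    bottleneck_strength: float = 0.1  # bottleneck size / wild size, in (0, 1]
    bottleneck_duration: float = 0.18
    outgroup_divergence: float = 5.0
    region_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    layout: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYOUT)
    )
    indel_rate: float = 0.0  # per-locus expected gap events (exercises core logic)

    def __post_init__(self) -> None:
        if not (0 < self.bottleneck_strength <= 1):
            raise ValueError("bottleneck strength must be in (0, 1]")
        if self.bottleneck_duration >= self.split_time_wild_cult:
            raise ValueError("bottleneck duration must be shorter than the split time")
        if self.outgroup_divergence <= self.split_time_wild_cult:
            raise ValueError("outgroup divergence must predate the cultivated split")
        if self.theta_site < 0 or self.length <= 0:
            raise ValueError("rates and lengths must be positive")
        if not (0 <= self.n_reference <= self.n_loci):
            raise ValueError("n_reference must be within n_loci")


@dataclass
class SimulatedDataset:
    loci: list[AlignedLocus]
    annotations: list[LocusAnnotation]
    panel: PopulationPanel
    truth: pd.DataFrame
    config: SimulationConfig

    def locus(self, locus_id: str) -> AlignedLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def annotation(self, locus_id: str) -> LocusAnnotation:
        for a in self.annotations:
            if a.locus_id == locus_id:
                return a
        raise KeyError(locus_id)

    @property
    def candidate_ids(self) -> list[str]:
        return [
            a.locus_id for a in self.annotations
            if a.locus_class != "neutral_reference"
        ]

    @property
    def reference_ids(self) -> list[str]:
        return [
            a.locus_id for a in self.annotations
            if a.locus_class == "neutral_reference"
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        loci_dir = outdir / "loci"
        loci_dir.mkdir(parents=True, exist_ok=True)
        for locus in self.loci:
            write_alignment_fasta(locus, loci_dir / f"{locus.locus_id}.fasta")
        write_panel_table(self.panel, outdir / "panel.tsv")
        write_locus_annotations(self.annotations, outdir / "annotations.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _demography(config: SimulationConfig) -> msprime.Demography:
    d = msprime.Demography()
    for name in ("indica", "japonica", "wild", "outgroup"):
        d.add_population(name=name, initial_size=1.0)
    t_bn = config.split_time_wild_cult - config.bottleneck_duration
    for pop in ("indica", "japonica"):
        d.add_population_parameters_change(
            time=t_bn, population=pop, initial_size=config.bottleneck_strength
        )
        d.add_mass_migration(
            time=config.split_time_wild_cult, source=pop, dest="wild", proportion=1.0
        )
    d.add_mass_migration(
        time=config.outgroup_divergence, source="outgroup", dest="wild", proportion=1.0
    )
    d.sort_events()
    return d


def _accession_names(config: SimulationConfig) -> tuple[list[str], PopulationPanel]:
    names: list[str] = []
    entries: dict[str, PanelEntry] = {}
    for prefix, count, pop, sub in (
        ("IND", config.n_indica, "cultivated", "indica"),
        ("JAP", config.n_japonica, "cultivated", "japonica"),
        ("WLD", config.n_wild, "wild", "none"),
        ("OUT", config.n_outgroup, "outgroup", "none"),
    ):
        for i in range(count):
            name = f"{prefix}{i + 1:02d}"
            names.append(name)
            entries[name] = PanelEntry(pop, sub)
    return names, PopulationPanel(entries)


def _rate_map(config: SimulationConfig, reference: bool) -> msprime.RateMap:
    base = 0.5 * config.theta_site  # mutations per lineage per 2N generations
    if reference:
        return msprime.RateMap(
            position=[0, config.length], rate=[base]
        )
    rates = np.full(config.length, base)
    order = ("upstream", "downstream", "precursor", "mature")  # nested last
    for label in order:
        if label not in config.layout:
            continue
        lo, hi = config.layout[label]
        rates[lo:hi] = base * config.region_multipliers.get(label, 1.0)
    edges = np.flatnonzero(np.diff(rates) != 0) + 1
    position = np.concatenate([[0], edges, [config.length]])
    rate = rates[position[:-1].astype(int)]
    return msprime.RateMap(position=position, rate=rate)


def _per_site_rates(config: SimulationConfig, reference: bool) -> np.ndarray:
    rm = _rate_map(config, reference)
    idx = np.minimum(
        np.searchsorted(rm.position, np.arange(config.length), side="right") - 1,
        len(rm.rate) - 1,
    )
    return np.asarray(rm.rate)[idx]


def simulate_domestication_panel(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full multi-locus panel (FASTA/TSV bundle in memory)."""
    names, panel = _accession_names(config)
    demography = _demography(config)
    samples = [
        msprime.SampleSet(config.n_indica, population="indica", ploidy=1),
        msprime.SampleSet(config.n_japonica, population="japonica", ploidy=1),
        msprime.SampleSet(config.n_wild, population="wild", ploidy=1),
        msprime.SampleSet(config.n_outgroup, population="outgroup", ploidy=1),
    ]
    master = derive_rng(config.seed, "panel")
    loci: list[AlignedLocus] = []
    annotations: list[LocusAnnotation] = []
    truth_rows = []
    for idx in range(config.n_loci):
        reference = idx < config.n_reference
        locus_id = (f"REF{idx + 1:03d}" if reference
                    else f"SIM{idx - config.n_reference + 1:03d}")
        seed_anc = int(master.integers(1, 2**31 - 1))
        seed_mut = int(master.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=config.length,
            ploidy=1,
            random_seed=seed_anc,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=_rate_map(config, reference),
            model=msprime.JC69(),
            random_seed=seed_mut,
            discrete_genome=True,
        )
        rng = derive_rng(config.seed, "emit", locus_id)
        mat = np.tile(rng.choice(_BASES, size=config.length), (len(names), 1))
        for var in mts.variants():
            pos = int(var.site.position)
            alleles = np.array(var.alleles, dtype="U1")
            mat[:, pos] = alleles[var.genotypes]
        if config.indel_rate > 0:
            _add_indels(mat, config, rng)
        loci.append(
            AlignedLocus(
                locus_id,
                tuple((a, "".join(row)) for a, row in zip(names, mat)),
            )
        )
        if reference:
            annotations.append(
                LocusAnnotation(locus_id, "neutral_reference", "not_applicable")
            )
        else:
            cons = "conserved" if (idx - config.n_reference) % 2 == 0 else "species_specific"
            regions = tuple(
                Region(label, lo, hi) for label, (lo, hi) in config.layout.items()
            )
            annotations.append(LocusAnnotation(locus_id, "MIRNA", cons, regions))
        truth_rows.append(
            {"locus_id": locus_id,
             "class": annotations[-1].locus_class,
             "theta_site": config.theta_site,
             "swept": False}
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(loci, annotations, panel, truth, config)


def _add_indels(mat: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> None:
    """Optional gap events so downstream core-alignment logic is exercised."""
    n_events = rng.poisson(config.indel_rate)
    n_seqs, L = mat.shape
    for _ in range(n_events):
        width = int(rng.integers(1, 4))
        start = int(rng.integers(0, L - width))
        carriers = rng.choice(n_seqs, size=max(1, int(rng.integers(1, n_seqs // 3 + 2))),
                              replace=False)
        mat[carriers, start:start + width] = "-"


def inject_sweep_locus(
    dataset: SimulatedDataset,
    locus_id: str,
    sweep_age: float | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """Replace the cultivated genealogy at one locus with a post-sweep star.

    All cultivated sequences become copies of one wild haplotype (the sweep
    founder) plus private mutations accumulated over ``sweep_age`` (default:
    the wild/cultivated split time, i.e. a sweep at domestication), placed
    with the locus's per-region rate profile.  Wild and outgroup sequences
    are untouched.
    """
    config = dataset.config
    if sweep_age is None:
        sweep_age = config.split_time_wild_cult
    locus = dataset.locus(locus_id)
    annotation = dataset.annotation(locus_id)
    reference = annotation.locus_class == "neutral_reference"
    rng = derive_rng(seed if seed is not None else config.seed, "sweep", locus_id)

    seqs = dict(locus.sequences)
    wild_ids = dataset.panel.accessions("wild", within=locus.accession_ids)
    cult_ids = dataset.panel.accessions("cultivated", within=locus.accession_ids)
    founder = np.array(list(seqs[wild_ids[int(rng.integers(len(wild_ids)))]]), dtype="U1")

    site_rates = _per_site_rates(config, reference)  # theta/2 per site
    weights = site_rates / site_rates.sum()
    lam = float(site_rates.sum() * sweep_age)  # E[mutations per lineage]
    new_seqs = dict(seqs)
    for acc in cult_ids:
        seq = founder.copy()
        n_mut = rng.poisson(lam)
        if n_mut:
            pos = rng.choice(config.length, size=min(n_mut, config.length),
                             replace=False, p=weights)
            for p in pos:
                seq[p] = rng.choice(_BASES[_BASES != seq[p]])
        new_seqs[acc] = "".join(seq)
    new_locus = AlignedLocus(
        locus_id, tuple((a, new_seqs[a]) for a in locus.accession_ids)
    )
    loci = [new_locus if l.locus_id == locus_id else l for l in dataset.loci]
    truth = dataset.truth.copy()
    truth.loc[truth["locus_id"] == locus_id, "swept"] = True
    return SimulatedDataset(loci, dataset.annotations, dataset.panel, truth, config)


# ---------------------------------------------------------------------------
# thin wrappers over the null engines (single-population study conditions)


def simulate_neutral_locus(
    n: int, theta_locus: float, seed: int, reps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(S, k-hat) replicates under the standard neutral coalescent."""
    rng = derive_rng(seed, "neutral-locus", n)
    return coalescent.neutral_replicates(n, theta_locus, reps, rng)


def simulate_fixed_s(
    n: int, S: int, seed: int, reps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(S, k-hat) replicates conditional on exactly S segregating sites."""
    rng = derive_rng(seed, "fixed-s", n, S)
    return coalescent.fixed_s_replicates(n, S, reps, rng)
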