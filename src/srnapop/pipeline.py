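"""End-to-end orchestration of the two-step survey design.

Step 1 (``run_survey``): per-locus and per-region diversity, Tajima's D
with fixed-S significance, aggregate tables and the functional-region
mutation catalogue, for the cultivated panel and its two subgroups.

Step 2 (``run_selection_screen``): for each candidate locus, per-subgroup
and wild-population Tajima and HKA tests against the neutral reference
loci, the wild/cultivated fold-reduction screen, and the final candidate
classification.

Every output table carries a provenance header (config hash, seed,
version); reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import (
    AlignedLocus,
    LocusAnnotation,
    PopulationPanel,
    extract_core_alignment,
    read_alignment_fasta,
    read_locus_annotations,
    read_panel_table,
)
from .diversity import (
    aggregate,
    diversity_stats,
    find_segregating_sites,
    region_diversity,
)
from .neutrality import d_distribution, tajimas_d, tajima_significance
from .hka import HKALocusInput, hka_candidate_test
from .selection import (
    GroupTests,
    classify_candidate,
    fold_reduction,
    neutral_baseline,
)
from .mutations import catalog_region_mutations

log = logging.getLogger(__name__)

SURVEY_GROUPS = ("cultivated", "indica", "japonica")
SCREEN_GROUPS = ("indica", "japonica", "wild")


@dataclass(frozen=True)
class PipelineConfig:
    loci_dir: str
    panel_path: str
    annotations_path: str
    out_dir: str
    seed: int
    alpha: float = 0.05
    tajima_reps: int = 10_000
    hka_sims: int = 10_000
    reference_loci: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["reference_loci"] = tuple(raw.get("reference_loci", ()))
        cfg = cls(**raw)
        for p in (cfg.loci_dir, cfg.panel_path, cfg.annotations_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class LocusBundle:
    loci: dict[str, AlignedLocus]
    annotations: dict[str, LocusAnnotation]
    panel: PopulationPanel


def load_bundle(
    loci_dir: str | Path, panel_path: str | Path, annotations_path: str | Path
) -> LocusBundle:
    """Read and cross-validate the FASTA directory and the two tables."""
    loci_dir = Path(loci_dir)
    paths = sorted(loci_dir.glob("*.fasta")) + sorted(loci_dir.glob("*.fa"))
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {loci_dir}")
    panel = read_panel_table(panel_path)
    annotations = {a.locus_id: a for a in read_locus_annotations(annotations_path)}
    loci = {}
    for p in paths:
        locus = read_alignment_fasta(p)
        panel.validate_locus(locus)
        if locus.locus_id in annotations:
            annotations[locus.locus_id].validate_against(locus)
        loci[locus.locus_id] = locus
    return LocusBundle(loci, annotations, panel)


def bundle_from_dataset(dataset) -> LocusBundle:
    """Wrap an in-memory :class:`SimulatedDataset` for the pipeline."""
    return LocusBundle(
        {l.locus_id: l for l in dataset.loci},
        {a.locus_id: a for a in dataset.annotations},
        dataset.panel,
    )


def _group_ids(panel: PopulationPanel, locus: AlignedLocus, group: str):
    return panel.accessions(subgroup=group, within=locus.accession_ids)


def _tajima_row(locus_id, group, core, config: PipelineConfig) -> dict:
    stats = diversity_stats(core)
    d = tajimas_d(stats.S, stats.pi_locus, core.n) if core.n >= 3 else math.nan
    if math.isnan(d):
        p, sig = math.nan, False
    else:
        p = tajima_significance(
            d, core.n, stats.S, n_reps=config.tajima_reps, seed=config.seed
        )
        sig = p < config.alpha
    return {
        "locus_id": locus_id, "group": group, "N": core.n, "L": stats.L,
        "S": stats.S, "pi_locus": stats.pi_locus, "D": d, "p_value": p,
        "significant": sig,
    }


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = (
        f"# srnapop v{__version__} seed={config.seed} alpha={config.alpha} "
        f"config={config.digest()} (no multiple-testing correction applied)\n"
        "# internal coordinates are 0-based half-open; printed positions 1-based\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_survey(config: PipelineConfig, bundle: LocusBundle | None = None) -> dict:
    """Step 1: diversity + neutrality reports for the cultivated panel."""
    if bundle is None:
        bundle = load_bundle(config.loci_dir, config.panel_path, config.annotations_path)
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    div_rows, region_rows, tajima_rows, mutation_rows = [], [], [], []
    for locus_id in sorted(bundle.loci):
        locus = bundle.loci[locus_id]
        ann = bundle.annotations.get(locus_id)
        for group in SURVEY_GROUPS:
            ids = _group_ids(bundle.panel, locus, group)
            if len(ids) < 2:
                log.warning("%s: <2 sequences for group %s, skipped", locus_id, group)
                continue
            core = extract_core_alignment(locus, ids)
            stats = diversity_stats(core)
            div_rows.append(
                {"locus_id": locus_id, "group": group, "N": stats.n, "L": stats.L,
                 "S": stats.S, "theta_site": stats.theta_w_site,
                 "pi_site": stats.pi_site, "theta_locus": stats.theta_w_locus,
                 "pi_locus": stats.pi_locus, "snp_per_kb": stats.snp_per_kb}
            )
            if core.n >= 3:
                tajima_rows.append(_tajima_row(locus_id, group, core, config))
            if ann is not None and ann.regions:
                for key, rstats in region_diversity(core, ann).items():
                    region_rows.append(
                        {"locus_id": locus_id, "group": group, "region": key,
                         "conservation": ann.conservation, "N": rstats.n,
                         "L": rstats.L, "S": rstats.S,
                         "snp_per_site": (rstats.S / rstats.L if rstats.L else math.nan),
                         "pi_site": rstats.pi_site}
                    )
        if ann is not None and ann.regions:
            ids = bundle.panel.accessions(within=locus.accession_ids)
            core_all = extract_core_alignment(locus, ids)
            catalog = find_segregating_sites(core_all)
            for rec in catalog_region_mutations(catalog, ann, locus, bundle.panel, ids):
                mutation_rows.append(
                    {"locus_id": rec.locus_id, "region": rec.region_label,
                     "name": rec.region_name, "position": rec.position_in_region,
                     "type": rec.mutation_type,
                     "alleles": json.dumps(rec.alleles, sort_keys=True)}
                )

    diversity_df = pd.DataFrame(div_rows)
    region_df = pd.DataFrame(region_rows)
    tajima_df = pd.DataFrame(tajima_rows)
    mutations_df = pd.DataFrame(mutation_rows)

    agg_rows = []
    if not region_df.empty:
        for stat in ("snp_per_site", "pi_site"):
            groupers = [
                ("all", region_df[region_df.group == "cultivated"], ["region"]),
                ("conservation", region_df[region_df.group == "cultivated"],
                 ["conservation", "region"]),
                ("subgroup", region_df[region_df.group.isin(("indica", "japonica"))],
                 ["group", "region"]),
            ]
            for stratum, sub, keys in groupers:
                if sub.empty:
                    continue
                for key_vals, chunk in sub.groupby(keys):
                    vals = chunk[stat].dropna()
                    if vals.empty:
                        continue
                    agg = aggregate("|".join(map(str, np.atleast_1d(key_vals))), vals)
                    agg_rows.append(
                        {"statistic": stat, "stratum": stratum, "group": agg.group,
                         "mean": agg.mean, "sem": agg.sem, "n_loci": agg.n_loci}
                    )
    aggregates_df = pd.DataFrame(agg_rows)

    if not tajima_df.empty and tajima_df["D"].notna().any():
        hist, mean_d, skew_d = d_distribution(
            tajima_df.loc[tajima_df.group == "cultivated", "D"].dropna()
            if (tajima_df.group == "cultivated").any()
            else tajima_df["D"].dropna()
        )
        hist["mean_D"] = mean_d
        hist["skewness"] = skew_d
    else:
        hist = pd.DataFrame(columns=["bin_left", "bin_right", "count"])

    tables = {
        "diversity": diversity_df,
        "region_diversity": region_df,
        "aggregates": aggregates_df,
        "tajima": tajima_df,
        "d_histogram": hist,
        "mutations": mutations_df,
    }
    if config.out_dir:
        for name, df in tables.items():
            _write_tsv(df, out_dir / f"{name}.tsv", config)
    return tables


def _divergence_input(
    locus: AlignedLocus,
    panel: PopulationPanel,
    ingroup_ids: Sequence[str],
    outgroup_ids: Sequence[str],
    locus_id: str,
    is_reference: bool,
) -> HKALocusInput | None:
    """Build one locus's HKA observation, or None when no outgroup data."""
    if len(ingroup_ids) < 2 or not outgroup_ids:
        return None
    core_in = extract_core_alignment(locus, ingroup_ids)
    if core_in.empty:
        return None
    S = find_segregating_sites(core_in).S
    core_all = extract_core_alignment(locus, tuple(ingroup_ids) + tuple(outgroup_ids))
    if core_all.empty:
        return None
    ni = len(ingroup_ids)
    mat_in = core_all.matrix[:ni]
    mat_out = core_all.matrix[ni:]
    diffs = (mat_in[:, None, :] != mat_out[None, :, :]).sum(axis=2)
    return HKALocusInput(
        locus_id=locus_id,
        n_ingroup=ni,
        L_poly=core_in.L,
        S_obs=S,
        L_div=core_all.L,
        D_obs=float(diffs.mean()),
        is_reference=is_reference,
    )


def run_selection_screen(config: PipelineConfig, bundle: LocusBundle | None = None) -> dict:
    """Step 2: Tajima + HKA per group, fold screen, candidate classification."""
    if bundle is None:
        bundle = load_bundle(config.loci_dir, config.panel_path, config.annotations_path)
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    panel = bundle.panel

    reference_ids = list(config.reference_loci) or [
        lid for lid, a in bundle.annotations.items()
        if a.locus_class == "neutral_reference"
    ]
    candidate_ids = [lid for lid in sorted(bundle.loci) if lid not in reference_ids]
    missing = [r for r in reference_ids if r not in bundle.loci]
    if missing:
        raise FileNotFoundError(f"reference loci without alignments: {missing}")

    outgroup_ids = panel.accessions("outgroup")

    # HKA reference observations, per screening group
    hka_refs: dict[str, list[HKALocusInput]] = {}
    for group in SCREEN_GROUPS:
        refs = []
        for rid in reference_ids:
            locus = bundle.loci[rid]
            ids = _group_ids(panel, locus, group)
            out_in_locus = [a for a in outgroup_ids if a in locus.accession_ids]
            obs = _divergence_input(locus, panel, ids, out_in_locus, rid, True)
            if obs is not None:
                refs.append(obs)
        hka_refs[group] = refs

    screen_rows, fold_inputs = [], []
    for locus_id in candidate_ids:
        locus = bundle.loci[locus_id]
        out_in_locus = [a for a in outgroup_ids if a in locus.accession_ids]
        row: dict = {"locus_id": locus_id}
        pi_by_group: dict[str, float] = {}
        for group in SCREEN_GROUPS:
            ids = _group_ids(panel, locus, group)
            sub: dict = {}
            if len(ids) >= 2:
                core = extract_core_alignment(locus, ids)
                stats = diversity_stats(core)
                pi_by_group[group] = stats.pi_site
                t = _tajima_row(locus_id, group, core, config)
                sub.update(
                    n=stats.n,
                    D=t["D"],
                    tajima_p=t["p_value"],
                    tajima_significant=t["significant"],
                )
                cand = _divergence_input(locus, panel, ids, out_in_locus, locus_id, False)
                if cand is not None and hka_refs[group]:
                    try:
                        res = hka_candidate_test(
                            cand, hka_refs[group],
                            n_sim=config.hka_sims,
                            seed=config.seed,
                            alpha=config.alpha,
                        )
                        sub["hka_p"] = res.p_value
                        sub["hka_x2"] = res.X2
                    except ValueError as exc:
                        log.warning("%s/%s: HKA unavailable (%s)", locus_id, group, exc)
                else:
                    log.warning("%s/%s: HKA NA (no outgroup or reference data)",
                                locus_id, group)
            else:
                log.warning("%s: <2 sequences for group %s", locus_id, group)
            row[group] = sub
        ann = bundle.annotations.get(locus_id)
        row["target"] = ann.locus_class if ann else ""
        screen_rows.append(row)

        for sg in ("indica", "japonica"):
            if sg in pi_by_group and "wild" in pi_by_group:
                fold_inputs.append(
                    {"locus_id": locus_id, "subgroup": sg,
                     "pi_wild": pi_by_group["wild"], "pi_cult": pi_by_group[sg]}
                )

    # neutral baseline from reference-locus fold reductions
    ref_folds = []
    for rid in reference_ids:
        locus = bundle.loci[rid]
        pis = {}
        for group in SCREEN_GROUPS:
            ids = _group_ids(panel, locus, group)
            if len(ids) >= 2:
                pis[group] = diversity_stats(extract_core_alignment(locus, ids)).pi_site
        for sg in ("indica", "japonica"):
            if sg in pis and "wild" in pis and pis[sg] > 0:
                ref_folds.append(pis["wild"] / pis[sg])
    baseline = neutral_baseline(ref_folds) if ref_folds else math.nan

    fold_rows = []
    for fi in fold_inputs:
        fr = fold_reduction(fi["locus_id"], fi["subgroup"], fi["pi_wild"],
                            fi["pi_cult"], baseline)
        fold_rows.append(
            {"locus_id": fr.locus_id, "subgroup": fr.subgroup,
             "pi_wild_site": fr.pi_wild_site, "pi_cult_site": fr.pi_cult_site,
             "fold": fr.fold, "baseline": baseline,
             "exceeds_baseline": fr.exceeds_baseline}
        )

    table_rows = []
    for row in screen_rows:
        tests = {}
        for g in SCREEN_GROUPS:
            sub = row[g]
            tests[g] = GroupTests(
                tajima_d=sub.get("D"),
                tajima_significant=bool(sub.get("tajima_significant", False)),
                hka_p=sub.get("hka_p"),
            )
        call = classify_candidate(row["locus_id"], tests["indica"],
                                  tests["japonica"], tests["wild"],
                                  alpha=config.alpha)
        status = call.status
        if not row["wild"]:
            # the domestication rule needs a wild contrast
            status = "NA"
            log.warning("%s: no wild data, candidate status NA", row["locus_id"])
        rec = {"locus_id": row["locus_id"]}
        for g in SCREEN_GROUPS:
            sub = row[g]
            d = sub.get("D")
            rec[f"{g}_N"] = sub.get("n")
            rec[f"{g}_D"] = (round(d, 2) if d is not None and not math.isnan(d)
                             else math.nan)
            rec[f"{g}_D_p"] = sub.get("tajima_p")
            rec[f"{g}_D_significant"] = bool(sub.get("tajima_significant", False))
            rec[f"{g}_hka_p"] = sub.get("hka_p")
        rec["target"] = row["target"]
        rec["candidate_status"] = status
        table_rows.append(rec)

    selection_df = pd.DataFrame(table_rows)
    fold_df = pd.DataFrame(fold_rows)
    if config.out_dir:
        _write_tsv(selection_df, out_dir / "selection_table.tsv", config)
        _write_tsv(fold_df, out_dir / "fold_screen.tsv", config)
    return {"selection": selection_df, "fold": fold_df, "baseline": baseline}
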