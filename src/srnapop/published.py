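"""Published statistics from the rice small-RNA resequencing survey.

Two kinds of reference data are bundled:

* the printed per-locus screening statistics of the 20-locus
  domestication-selection survey (sample sizes, Tajima's D with its
  significance star, HKA p-values, target family, and the published
  candidate status) — used as classifier input to check that
  :func:`srnapop.selection.classify_candidate` reproduces the published
  calls exactly;
* headline summary values that can only be recomputed from the full
  deposited sequence panel (GenBank GQ418390-GQ420345 and
  HM138917-HM140183).  These are *download-gated*: they require fetching
  and regrouping ~2 Mb of GenBank records, so they are recorded here with
  ``desk_scale=False`` rather than recomputed by the test suite.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import pandas as pd

# Printed screening statistics.  D_star marks values published as
# significant; hka_p is NaN where the survey reported NA (the clustered
# multi-copy miR395a/b locus was excluded from the HKA analysis).
_SCREEN_TSV = """\
locus_id	locus_type	indica_N	indica_D	indica_star	indica_hka_p	japonica_N	japonica_D	japonica_star	japonica_hka_p	wild_N	wild_D	wild_star	wild_hka_p	target	status
MIR164e	MIRNA	21	-1.90	1	0.101	21	1.18	0	0.285	10	-1.04	0	0.447	NAC	Putative
MIR390	MIRNA	25	-1.21	0	0.106	20	-0.09	0	0.014	11	-1.23	0	0.257	TAS3	Putative
MIR395a-b	MIRNA	27	-1.56	0	NA	21	-1.94	1	NA	11	-1.49	0	NA	APS/AST	Putative
TAS3a2	siRNA	28	-1.86	1	0.029	24	-0.85	0	0.158	10	-1.35	0	0.503	ARF	Putative
AK120922	siRNA	25	0.26	0	0.003	18	-1.77	0	0.055	11	-2.05	1	0.250	Unknown	ND
MIR164a	MIRNA	25	1.54	0	0.129	22	-1.31	0	0.215	11	-0.84	0	0.433	Unknown	ND
MIR164c	MIRNA	23	-0.51	0	0.167	23	-0.63	0	0.297	8	0.47	0	0.294	NAC	ND
MIR164d	MIRNA	25	-0.48	0	0.147	21	-1.29	0	0.260	12	-1.54	0	0.464	NAC	ND
MIR166f	MIRNA	29	-1.02	0	0.161	23	-0.81	0	0.342	10	-0.20	0	0.419	HD-ZIP	ND
MIR395i-k	MIRNA	25	0.98	0	0.106	18	-0.52	0	0.248	9	-0.60	0	0.245	APS/AST	ND
MIR396f	MIRNA	21	-0.54	0	0.089	20	0.76	0	0.288	10	-0.68	0	0.470	GRL	ND
MIR399a	MIRNA	27	0.35	0	0.099	24	-0.68	0	0.278	14	1.21	0	0.403	PT	ND
MIR399d	MIRNA	23	-2.37	1	0.107	22	-0.87	0	0.002	12	-2.04	1	0.255	PT	ND
MIR399i	MIRNA	22	-0.95	0	0.102	22	-1.08	0	0.196	11	-1.03	0	0.442	PT	ND
MIR440	MIRNA	25	0.04	0	0.097	20	-0.57	0	0.137	14	-1.58	0	0.339	Unknown	ND
MIR443	MIRNA	29	0.15	0	0.148	21	-1.57	0	0.274	9	-0.39	0	0.301	Unknown	ND
MIR1318	MIRNA	22	0.34	0	0.078	21	-0.65	0	0.227	12	-0.45	0	0.439	Unknown	ND
MIR1432	MIRNA	26	0.20	0	0.081	22	-1.30	0	0.176	10	0.57	0	0.382	EF	ND
MIR1862d	MIRNA	21	0.71	0	0.113	20	-0.14	0	0.270	9	-1.88	1	0.394	NAC	ND
MIR1867	MIRNA	24	-1.21	0	0.094	24	-1.11	0	0.280	10	-0.94	0	0.493	Unknown	ND
"""


def published_screen_table() -> pd.DataFrame:
    """The published 20-locus screening statistics as a DataFrame."""
    df = pd.read_csv(io.StringIO(_SCREEN_TSV), sep="\t", na_values=["NA"])
    for g in ("indica", "japonica", "wild"):
        df[f"{g}_star"] = df[f"{g}_star"].astype(bool)
    return df


def screen_table_as_classifier_rows(df: pd.DataFrame | None = None) -> list[dict]:
    """Reshape the published table into :func:`build_selection_table` rows."""
    if df is None:
        df = published_screen_table()
    rows = []
    for _, r in df.iterrows():
        row = {"locus_id": r["locus_id"], "target": r["target"]}
        for g in ("indica", "japonica", "wild"):
            hka = r[f"{g}_hka_p"]
            row[g] = {
                "n": int(r[f"{g}_N"]),
                "D": float(r[f"{g}_D"]),
                "tajima_significant": bool(r[f"{g}_star"]),
                "hka_p": None if (isinstance(hka, float) and math.isnan(hka)) else float(hka),
            }
        rows.append(row)
    return rows


@dataclass(frozen=True)
class ReferenceValue:
    """A published summary value and what it takes to recompute it."""

    name: str
    value: float
    units: str
    description: str
    desk_scale: bool  # False: needs the deposited GenBank sequence panel
    requires: str = ""


DOWNLOAD_GATED_BENCHMARKS: tuple[ReferenceValue, ...] = (
    ReferenceValue(
        name="mature_mirna_pi_site",
        value=0.00169,
        units="per site",
        description="mean pairwise diversity in mature miRNA sequences, "
        "cultivated panel (± 0.00067 SEM)",
        desk_scale=False,
        requires="GenBank GQ418390-GQ420345, HM138917-HM140183",
    ),
    ReferenceValue(
        name="mature_mirna_snp_per_kb",
        value=1.52,
        units="SNPs per 1000 sites",
        description="mean SNP density in mature miRNA sequences (± 0.51 SEM)",
        desk_scale=False,
        requires="GenBank GQ418390-GQ420345, HM138917-HM140183",
    ),
    ReferenceValue(
        name="mature_variant_mirna_fraction",
        value=12.5,
        units="percent",
        description="fraction of surveyed MIRNA loci with a SNP or indel in "
        "the mature sequence (11 of 88)",
        desk_scale=False,
        requires="GenBank GQ418390-GQ420345, HM138917-HM140183",
    ),
    ReferenceValue(
        name="mir399d_indica_tajima_d",
        value=-2.37,
        units="dimensionless",
        description="Tajima's D of MIR399d in the indica subgroup (n=23)",
        desk_scale=False,
        requires="GenBank GQ418390-GQ420345, HM138917-HM140183",
    ),
    ReferenceValue(
        name="mir390_fold_reduction_indica",
        value=7.0,
        units="fold",
        description="wild/cultivated diversity ratio at MIR390, indica "
        "subgroup (japonica: 6.3)",
        desk_scale=False,
        requires="GenBank GQ418390-GQ420345, HM138917-HM140183",
    ),
)
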