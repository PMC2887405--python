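"""Fold-reduction screening and domestication-candidate classification.

Two independent lines of evidence are reported:

* **fold screen** — the ratio of wild to cultivated per-site diversity at a
  locus, compared with the largest reduction observed at neutral reference
  genes (the baseline); a locus exceeding the baseline is a diversity-loss
  outlier.
* **candidate status** — a locus is a *Putative* domestication-selection
  candidate when a positive-selection signal (significantly *negative*
  Tajima's D, or HKA p below alpha) is present in at least one cultivated
  subgroup and absent from the wild population; otherwise *ND* (not
  detected), or *NA* when both cultivated subgroups lack usable tests.

A significantly positive D (balancing selection) is never counted as a
positive-selection signal.  The two screens are reported side by side with
no conjunction enforced between them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldReduction:
    locus_id: str
    subgroup: str
    pi_wild_site: float
    pi_cult_site: float
    fold: float  # inf when cultivated diversity is 0 and wild > 0; NaN when both 0
    exceeds_baseline: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fold)


@dataclass(frozen=True)
class GroupTests:
    """The two per-group test outcomes feeding the classifier.

    ``tajima_d``/``tajima_significant`` come from the fixed-S test,
    ``hka_p`` from the per-candidate HKA test; any field may be None/NaN
    when the corresponding test could not be run (missing outgroup, S = 0).
    """

    tajima_d: Optional[float] = None
    tajima_significant: bool = False
    hka_p: Optional[float] = None

    def has_any_test(self) -> bool:
        d_ok = self.tajima_d is not None and not math.isnan(self.tajima_d)
        return d_ok or self.hka_p is not None

    def positive_selection_signal(self, alpha: float = 0.05) -> bool:
        """Significant negative D, or HKA rejection.  Missing tests are
        treated as no-signal for that test only."""
        d_sig = (
            self.tajima_d is not None
            and not math.isnan(self.tajima_d)
            and self.tajima_significant
            and self.tajima_d < 0
        )
        hka_sig = self.hka_p is not None and self.hka_p < alpha
        return d_sig or hka_sig


@dataclass(frozen=True)
class SelectionCall:
    locus_id: str
    signal_indica: bool
    signal_japonica: bool
    signal_wild: bool
    status: str  # Putative / ND / NA


def neutral_baseline(neutral_folds: Iterable[float]) -> float:
    """Max fold reduction across neutral reference loci.

    Undefined entries (NaN) are skipped with a warning; an all-undefined or
    empty list is an error.
    """
    folds = list(neutral_folds)
    if not folds:
        raise ValueError("neutral_baseline needs >=1 fold value")
    defined = [f for f in folds if not math.isnan(f)]
    if len(defined) < len(folds):
        log.warning(
            "neutral_baseline: skipped %d undefined fold value(s)",
            len(folds) - len(defined),
        )
    if not defined:
        raise ValueError("all neutral fold values are undefined")
    return max(defined)


def fold_reduction(
    locus_id: str,
    subgroup: str,
    pi_wild_site: float,
    pi_cult_site: float,
    baseline: float,
) -> FoldReduction:
    if pi_wild_site < 0 or pi_cult_site < 0:
        raise ValueError("per-site diversities must be >= 0")
    if pi_wild_site == 0 and pi_cult_site == 0:
        fold = math.nan
        exceeds = False
    elif pi_cult_site == 0:
        fold = math.inf
        exceeds = True
        log.warning("%s/%s: zero cultivated diversity, fold is infinite",
                    locus_id, subgroup)
    else:
        fold = pi_wild_site / pi_cult_site
        exceeds = fold > baseline
    return FoldReduction(locus_id, subgroup, pi_wild_site, pi_cult_site,
                         fold, exceeds)


def classify_candidate(
    locus_id: str,
    indica: Optional[GroupTests],
    japonica: Optional[GroupTests],
    wild: Optional[GroupTests],
    alpha: float = 0.05,
) -> SelectionCall:
    """Apply the domestication-candidate rule to one locus."""
    ind = indica or GroupTests()
    jap = japonica or GroupTests()
    wld = wild or GroupTests()
    if not ind.has_any_test() and not jap.has_any_test():
        return SelectionCall(locus_id, False, False,
                             wld.positive_selection_signal(alpha), "NA")
    s_ind = ind.positive_selection_signal(alpha)
    s_jap = jap.positive_selection_signal(alpha)
    s_wld = wld.positive_selection_signal(alpha)
    status = "Putative" if (s_ind or s_jap) and not s_wld else "ND"
    return SelectionCall(locus_id, s_ind, s_jap, s_wld, status)


def build_selection_table(
    rows: Sequence[Mapping],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-locus screening report.

    Each input row is a mapping with ``locus_id``, optional ``target``
    (pass-through annotation string), and per-group sub-mappings ``indica``,
    ``japonica``, ``wild`` each holding n / D / tajima_significant / hka_p
    (any of which may be absent).  Returns one report row per locus with the
    per-population statistics and the Candidate Status column.
    """
    out = []
    for row in rows:
        groups = {}
        tests = {}
        for g in ("indica", "japonica", "wild"):
            sub = row.get(g) or {}
            d = sub.get("D")
            tests[g] = GroupTests(
                tajima_d=d,
                tajima_significant=bool(sub.get("tajima_significant", False)),
                hka_p=sub.get("hka_p"),
            )
            groups[g] = sub
        call = classify_candidate(
            row["locus_id"], tests["indica"], tests["japonica"], tests["wild"],
            alpha=alpha,
        )
        rec = {"locus_id": row["locus_id"]}
        for g in ("indica", "japonica", "wild"):
            sub = groups[g]
            rec[f"{g}_N"] = sub.get("n")
            d = sub.get("D")
            rec[f"{g}_D"] = round(d, 2) if d is not None and not math.isnan(d) else math.nan
            rec[f"{g}_D_significant"] = tests[g].tajima_significant
            rec[f"{g}_hka_p"] = sub.get("hka_p")
        rec["target"] = row.get("target", "")
        rec["candidate_status"] = call.status
        out.append(rec)
    return pd.DataFrame(out)
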