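"""Stratified co-occurrence accounting and species-tree annotation tables.

Each genome is reduced to a three-state category per gene system
(complete / incomplete / absent), then counted overall or stratified by
habitat or morphological subsection. Percentages are kept at full
precision in the tables and rounded half-up to integers for display,
matching the granularity the survey figures print.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .clusters import ArrangementLabel
from .families import CapabilityCall, FamilyPresence, system_state
from .genome_io import GenomeIOError, GenomeMetadata, tree_leaf_names

logger = logging.getLogger(__name__)

STATE_SYMBOL = {"complete": "+", "incomplete": "i", "absent": "-"}

AXES = ("overall", "habitat", "subsection")


@dataclass(frozen=True)
class GenomeCategory:
    genome_id: str
    hox_state: str
    hup_state: str
    nif_state: str

    @property
    def combination(self) -> str:
        return (f"hox{STATE_SYMBOL[self.hox_state]}/"
                f"hup{STATE_SYMBOL[self.hup_state]}/"
                f"nif{STATE_SYMBOL[self.nif_state]}")

    @property
    def h2ase_free(self) -> bool:
        return self.hox_state == "absent" and self.hup_state == "absent"


def round_half_up(value: float) -> int:
    """Round to nearest integer with exact halves going up (display rule)."""
    return int(math.floor(value + 0.5))


def categorize(presence_by_genome: Mapping[str, Sequence[FamilyPresence] | Mapping]
               ) -> list[GenomeCategory]:
    """Assign every genome exactly one (hox, hup, nif) state combination."""
    out: list[GenomeCategory] = []
    for gid in sorted(presence_by_genome):
        entry = presence_by_genome[gid]
        pmap = entry if isinstance(entry, Mapping) else {p.family_name: p for p in entry}
        out.append(GenomeCategory(
            genome_id=gid,
            hox_state=system_state(pmap, "hox"),
            hup_state=system_state(pmap, "hup"),
            nif_state=system_state(pmap, "nif"),
        ))
    return out


def summarize(categories: Sequence[GenomeCategory],
              metadata: Mapping[str, GenomeMetadata],
              axis: str = "overall") -> pd.DataFrame:
    """Count category combinations per stratum with percentages.

    Columns: stratum, combination, count, percentage (full precision),
    percentage_display (rounded half-up), denominator. Rows are ordered
    deterministically by (stratum, combination); empty strata are simply
    not present. Per-stratum percentages sum to 100 up to rounding and
    counts sum to the stratum size.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    rows = []
    for cat in categories:
        if axis == "overall":
            stratum = "all"
        else:
            meta = metadata.get(cat.genome_id)
            if meta is None:
                raise GenomeIOError(f"no metadata for genome {cat.genome_id!r}")
            stratum = getattr(meta, axis)
        rows.append({"stratum": stratum, "combination": cat.combination})
    df = pd.DataFrame(rows)
    counts = (df.groupby(["stratum", "combination"]).size()
              .rename("count").reset_index())
    denominators = df.groupby("stratum").size().rename("denominator")
    counts = counts.merge(denominators, left_on="stratum", right_index=True)
    counts["percentage"] = 100.0 * counts["count"] / counts["denominator"]
    counts["percentage_display"] = counts["percentage"].map(round_half_up)
    counts = counts.sort_values(["stratum", "combination"]).reset_index(drop=True)
    return counts[["stratum", "combination", "count", "denominator",
                   "percentage", "percentage_display"]]


def annotate_tree(tree: dendropy.Tree,
                  presence_by_genome: Mapping[str, Sequence[FamilyPresence] | Mapping],
                  capabilities: Mapping[str, CapabilityCall],
                  arrangements: Optional[Mapping[str, Mapping[str, ArrangementLabel]]] = None,
                  ) -> pd.DataFrame:
    """Per-leaf gene-content marks for rendering next to a species tree.

    One row per tree leaf, in tree (preorder leaf) order: a three-state
    mark per system (complete / incomplete / absent), a degenerate flag
    when a present gene carries degenerate catalytic residues, functional
    verdicts, and arrangement labels where classified. Leaves without a
    matching genome are marked ``missing`` with a logged warning.
    """
    leaves = tree_leaf_names(tree)
    if not leaves:
        raise GenomeIOError("tree has no named leaves")
    arrangements = arrangements or {}
    rows = []
    for leaf in leaves:
        if leaf not in presence_by_genome:
            logger.warning("tree leaf %r has no matching genome; marked missing", leaf)
            rows.append({"leaf": leaf, "hox": "missing", "hup": "missing",
                         "hyp": "missing", "nif": "missing", "degenerate_in": "",
                         "hox_functional": "", "hup_functional": "",
                         "nitrogen_fixing": "", "hox_arrangement": "",
                         "hup_arrangement": "", "hyp_arrangement": ""})
            continue
        entry = presence_by_genome[leaf]
        pmap = entry if isinstance(entry, Mapping) else {p.family_name: p for p in entry}
        degenerate = sorted(f for f, p in pmap.items()
                            if p.status == "present_degenerate")
        cap = capabilities.get(leaf)
        arr = arrangements.get(leaf, {})
        rows.append({
            "leaf": leaf,
            "hox": system_state(pmap, "hox"),
            "hup": system_state(pmap, "hup"),
            "hyp": system_state(pmap, "hyp"),
            "nif": system_state(pmap, "nif"),
            "degenerate_in": ";".join(degenerate),
            "hox_functional": "" if cap is None else str(cap.hox_functional),
            "hup_functional": "" if cap is None else str(cap.hup_functional),
            "nitrogen_fixing": "" if cap is None else str(cap.nitrogen_fixing),
            "hox_arrangement": arr["hox"].label if "hox" in arr else "",
            "hup_arrangement": arr["hup"].label if "hup" in arr else "",
            "hyp_arrangement": arr["hyp"].label if "hyp" in arr else "",
        })
    return pd.DataFrame(rows)
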