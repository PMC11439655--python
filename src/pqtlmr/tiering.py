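"""Evidence tiering: combining stage outcomes into a three-level ranking.

A protein is only considered at all when it passes the SMR screen
(P_FDR < 0.05) *and* colocalizes with the outcome (PP.H4 > 0.80); within
those, the validation MR stages decide the tier:

* tier 1 — SMR, colocalization, discovery MR and replication MR all pass;
* tier 2 — SMR, colocalization and discovery MR pass;
* tier 3 — SMR and colocalization pass.

Direction consistency between the SMR and MR estimates is computed and
reported but by default does not enter the tier rule; ``strict=True``
additionally requires it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["StageFlags", "TierAssignment", "assign_tier", "tier_report"]

SMR_FDR_THRESHOLD = 0.05
COLOC_PPH4_THRESHOLD = 0.80
MR_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class StageFlags:
    """Boolean stage outcomes for one protein."""

    protein: str
    smr_pass: bool
    coloc_pass: bool
    discovery_pass: bool
    replication_pass: bool
    directions_consistent: bool = True


@dataclass(frozen=True)
class TierAssignment:
    protein: str
    tier: str  # "1" | "2" | "3" | "none"


def assign_tier(flags: StageFlags, strict: bool = False) -> TierAssignment:
    """Highest tier whose requirements the flags meet."""
    if strict and not flags.directions_consistent:
        return TierAssignment(flags.protein, "none")
    if not (flags.smr_pass and flags.coloc_pass):
        return TierAssignment(flags.protein, "none")
    if flags.discovery_pass and flags.replication_pass:
        return TierAssignment(flags.protein, "1")
    if flags.discovery_pass:
        return TierAssignment(flags.protein, "2")
    return TierAssignment(flags.protein, "3")


def tier_report(all_flags: list[StageFlags], strict: bool = False) -> pd.DataFrame:
    """One row per protein with all flags and the assigned tier."""
    rows = []
    for f in all_flags:
        t = assign_tier(f, strict=strict)
        rows.append(
            {
                "protein": f.protein,
                "smr_pass": f.smr_pass,
                "coloc_pass": f.coloc_pass,
                "discovery_pass": f.discovery_pass,
                "replication_pass": f.replication_pass,
                "directions_consistent": f.directions_consistent,
                "tier": t.tier,
            }
        )
    return pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)
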