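"""Three-way overlap of prioritized proteins with body-fluid proteomes.

Candidates found both in cerebrospinal fluid and in plasma are accessible in
routinely sampled fluids and are therefore nominated as putative biochemical
biomarkers.  All identifiers are normalized gene symbols; a protein-id to
symbol mapping may be applied upstream (see iotables.apply_symbol_mapping).
"""

from __future__ import annotations

import dataclasses
import warnings

import pandas as pd

__all__ = ["VennResult", "overlap3"]

REGION_KEYS = (
    "candidates_only",
    "csf_only",
    "plasma_only",
    "candidates_csf",
    "candidates_plasma",
    "csf_plasma",
    "triple",
)


@dataclasses.dataclass
class VennResult:
    """The 7 exclusive Venn region counts plus the triple-overlap members."""

    counts: dict  # region key -> count
    triple_members: list  # sorted

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "count": self.counts[k]} for k in REGION_KEYS]
        rows.append({"region": "triple_members", "count": ",".join(self.triple_members)})
        return pd.DataFrame(rows, columns=["region", "count"])


def overlap3(candidates, csf, plasma) -> VennResult:
    """Exclusive Venn region cardinalities for candidates x CSF x plasma.

    Region counts sum to the size of the union; the triple intersection's
    membership is returned sorted.  Empty input sets produce a warning, not
    an error.
    """
    candidates, csf, plasma = set(candidates), set(csf), set(plasma)
    for name, s in (("candidates", candidates), ("csf", csf), ("plasma", plasma)):
        if not s:
            warnings.warn(f"empty {name} set in three-way overlap")
    triple = candidates & csf & plasma
    counts = {
        "candidates_only": len(candidates - csf - plasma),
        "csf_only": len(csf - candidates - plasma),
        "plasma_only": len(plasma - candidates - csf),
        "candidates_csf": len((candidates & csf) - plasma),
        "candidates_plasma": len((candidates & plasma) - csf),
        "csf_plasma": len((csf & plasma) - candidates),
        "triple": len(triple),
    }
    return VennResult(counts=counts, triple_members=sorted(triple))
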