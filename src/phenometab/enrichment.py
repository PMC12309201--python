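"""Over-representation analysis of metabolite sets against a pathway map.

A transparent hypergeometric ORA over a user-supplied feature -> pathway
annotation table. This is a deliberate, clearly-labelled substitute for
KEGG network-diffusion enrichment tools: it needs no external database and
its null model is exact, at the price of ignoring pathway topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PathwayMap:
    """pathway ID -> member feature IDs, with an explicit background."""

    pathways: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pathways = {k: set(v) for k, v in self.pathways.items()}
        self.universe = set(self.universe)
        for pid, members in self.pathways.items():
            if not members <= self.universe:
                raise ValueError(f"pathway {pid!r} has members outside the universe")

    @classmethod
    def from_table(cls, table: pd.DataFrame, universe=None) -> "PathwayMap":
        """Two-column (feature_id, pathway_id) annotation table."""
        need = {"feature_id", "pathway_id"}
        if not need <= set(table.columns):
            raise ValueError(f"annotation table needs columns {sorted(need)}")
        pathways: dict[str, set] = {}
        for _, row in table.iterrows():
            pathways.setdefault(row["pathway_id"], set()).add(row["feature_id"])
        if universe is None:
            universe = set(table["feature_id"])
        return cls(pathways, set(universe))


def ora_hypergeometric(dam_set, pmap: PathwayMap, alpha: float = 0.05
                       ) -> pd.DataFrame:
    """One-sided hypergeometric tail test per pathway, BH FDR across pathways.

    With universe size N, pathway size K, selection size n and overlap k the
    p-value is P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    dam_set = set(dam_set)
    if not pmap.universe:
        raise ValueError("empty universe")
    if not dam_set <= pmap.universe:
        extra = sorted(dam_set - pmap.universe)[:5]
        raise ValueError(f"selection contains features outside the universe: {extra}")
    N = len(pmap.universe)
    n = len(dam_set)
    rows = []
    for pid, members in sorted(pmap.pathways.items()):
        K = len(members)
        k = len(members & dam_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"pathway": pid, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["enriched"] = out["fdr"] < alpha
    return out
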