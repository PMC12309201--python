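"""Genotype tolerance ranking by per-trait ranks and their product.

Each trait ranks the genotypes (1 = best, average ranks on ties); the rank
product multiplies a genotype's ranks across traits and the total rank is
the rank of the products ascending. Product aggregation rewards
consistently strong performance more than mean-rank aggregation: one very
good trait rank (e.g. a 1) pulls the product down multiplicatively.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats


def rank_traits(values: pd.DataFrame, higher_is_better: dict | bool = True
                ) -> pd.DataFrame:
    """Per-trait genotype ranks (index = genotype, columns = traits).

    ``higher_is_better`` may be a single flag or a per-trait mapping.
    Missing values are an error: every genotype needs a value per trait.
    """
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing genotype values for traits: {bad}")
    ranks = {}
    for trait in values.columns:
        hib = higher_is_better.get(trait, True) if isinstance(higher_is_better, dict) \
            else bool(higher_is_better)
        ranks[trait] = values[trait].rank(ascending=not hib, method="average")
    return pd.DataFrame(ranks, index=values.index)


def rank_product_total(ranks: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trait ranks into rank products and total ranks.

    Total rank orders the products ascending; ties share the average total
    rank. Output is sorted by total rank.
    """
    if ranks.isna().any().any():
        raise ValueError("rank matrix must be complete")
    out = ranks.copy()
    out["rank_product"] = ranks.prod(axis=1)
    out["total_rank"] = stats.rankdata(out["rank_product"], method="average")
    return out.sort_values("total_rank")
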