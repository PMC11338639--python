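"""Count/proportion tables summarizing a pipeline run.

Percentages are rounded half-up (not banker's) at the requested number of
decimals, matching how discovery ratios such as 1302/30691 -> 4.2 % or
526/667 -> 79 % print.  Genome-level proportions count multi-copy genomes
once; gene-level tables count per gene.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd


def proportion_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_counts(
    records: Sequence[Mapping[str, object]], group_keys: Sequence[str]
) -> pd.DataFrame:
    """One count row per key combination plus a totals row, sorted by key."""
    for key in group_keys:
        for rec in records:
            if key not in rec:
                raise KeyError(f"record missing group key {key!r}")
    if records:
        df = pd.DataFrame(records)
        grouped = (
            df.groupby(list(group_keys)).size().reset_index(name="count")
            if group_keys
            else pd.DataFrame({"count": [len(df)]})
        )
        grouped = grouped.sort_values(list(group_keys)).reset_index(drop=True)
    else:
        grouped = pd.DataFrame(columns=[*group_keys, "count"])
    total = {key: "__total__" for key in group_keys}
    total["count"] = int(grouped["count"].sum()) if len(grouped) else 0
    return pd.concat([grouped, pd.DataFrame([total])], ignore_index=True)


def histogram(values: Sequence[int]) -> dict[int, int]:
    """Value -> frequency (e.g. pCODH copies per genome -> genome count)."""
    out: dict[int, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def proportion_table(
    pairs: Mapping[str, tuple[int, int]], decimals: int = 1
) -> pd.DataFrame:
    """Labelled numerator/denominator pairs -> tidy percentage table."""
    rows = []
    for label, (num, den) in pairs.items():
        rows.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "fraction_pct": proportion_pct(num, den, decimals),
            }
        )
    return pd.DataFrame(rows)
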