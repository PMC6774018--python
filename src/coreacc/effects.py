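"""Pooled-treatment effect arithmetic on treatment-mean tables.

With a balanced 2x2 design (control, W, N, NW; equal replication), the
marginal effect of a factor is summarized by pooling the two treatment
means with the factor present against the two without it:

    N pooling:  plus = mean(N, NW),  minus = mean(control, W)
    W pooling:  plus = mean(W, NW),  minus = mean(control, N)

and reporting percent change 100*(plus - minus)/minus, absolute difference
and fold change. These are unweighted means of the printed treatment means,
which equal the marginal means under balanced replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "TreatmentMeansTable",
    "EffectSummary",
    "pooled_effect",
    "effect_report",
    "round_half_up",
]

TREATMENTS = ("control", "W", "N", "NW")


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (matches how printed tables round .5 up).

    An intermediate 9-decimal half-up pass absorbs binary floating-point
    residue (0.66499999999999991 is treated as the 0.665 it arithmetically
    is) before rounding to the requested precision.
    """
    guard = Decimal(repr(x)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-decimals)
    return float(guard.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TreatmentMeansTable:
    """One measured index with mean (SE) for each of the four treatments."""

    index_name: str
    units: str
    means: dict
    ses: dict | None = None

    def __post_init__(self) -> None:
        missing = [t for t in TREATMENTS if t not in self.means]
        if missing:
            raise ValueError(f"{self.index_name}: missing treatment means {missing}")
        if self.ses is not None and any(v < 0 for v in self.ses.values()):
            raise ValueError(f"{self.index_name}: negative standard error")


@dataclass
class EffectSummary:
    index_name: str
    factor: str
    pooled_mean_plus: float
    pooled_mean_minus: float
    percent_change: float
    absolute_difference: float
    fold_change: float


def pooled_effect(row: TreatmentMeansTable, factor: str) -> EffectSummary:
    """Pool the four treatment means into a +factor vs -factor contrast."""
    if factor not in ("N", "W"):
        raise ValueError("factor must be 'N' or 'W'")
    m = row.means
    if factor == "N":
        plus = (m["N"] + m["NW"]) / 2.0
        minus = (m["control"] + m["W"]) / 2.0
    else:
        plus = (m["W"] + m["NW"]) / 2.0
        minus = (m["control"] + m["N"]) / 2.0
    diff = plus - minus
    if minus == 0:
        raise ZeroDivisionError(
            f"{row.index_name}: zero -{factor} pooled mean; percent and fold "
            "changes are undefined"
        )
    return EffectSummary(
        index_name=row.index_name,
        factor=factor,
        pooled_mean_plus=plus,
        pooled_mean_minus=minus,
        percent_change=100.0 * diff / minus,
        absolute_difference=diff,
        fold_change=plus / minus,
    )


def effect_report(rows, rounding: int | None = None) -> pd.DataFrame:
    """One pooled-effect summary per row per factor, as a DataFrame.

    ``rounding`` applies half-up decimal rounding to the numeric columns,
    matching how printed tables round.
    """
    records = []
    for row in rows:
        for factor in ("N", "W"):
            s = pooled_effect(row, factor)
            records.append(
                {
                    "index": s.index_name,
                    "factor": factor,
                    "pooled_mean_plus": s.pooled_mean_plus,
                    "pooled_mean_minus": s.pooled_mean_minus,
                    "percent_change": s.percent_change,
                    "absolute_difference": s.absolute_difference,
                    "fold_change": s.fold_change,
                }
            )
    df = pd.DataFrame.from_records(records)
    if rounding is not None:
        num = df.columns.drop(["index", "factor"])
        df[num] = df[num].map(lambda x: round_half_up(x, rounding))
    return df
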