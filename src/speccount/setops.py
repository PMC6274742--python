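"""Venn arithmetic over the two conditions' identified-protein sets."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["VennSummary", "venn_compare", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VennSummary:
    """Shared/unique identification counts and their percentages of the union."""

    n_a: int
    n_b: int
    shared: int
    unique_a: int
    unique_b: int
    total: int
    pct_shared: float
    pct_unique_a: float
    pct_unique_b: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def venn_compare(set_a: Iterable[str], set_b: Iterable[str]) -> VennSummary:
    """Compare two identification sets.

    total = |A ∪ B|; each percentage is count/total·100 rounded half-up to
    one decimal. An empty union yields zero percentages.
    """
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    total = len(a | b)

    def pct(count: int) -> float:
        return round_half_up(100.0 * count / total, 1) if total else 0.0

    return VennSummary(
        n_a=len(a),
        n_b=len(b),
        shared=shared,
        unique_a=len(a) - shared,
        unique_b=len(b) - shared,
        total=total,
        pct_shared=pct(shared),
        pct_unique_a=pct(len(a) - shared),
        pct_unique_b=pct(len(b) - shared),
    )


def venn_from_sizes(n_a: int, n_b: int, shared: int) -> VennSummary:
    """Venn summary from set sizes alone (when only the counts are known)."""
    if shared > min(n_a, n_b) or min(n_a, n_b, shared) < 0:
        raise ValueError("invalid set sizes: need 0 ≤ shared ≤ min(n_a, n_b)")
    set_a = {f"A{i}" for i in range(n_a - shared)} | {f"S{i}" for i in range(shared)}
    set_b = {f"B{i}" for i in range(n_b - shared)} | {f"S{i}" for i in range(shared)}
    return venn_compare(set_a, set_b)
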