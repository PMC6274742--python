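"""The spectral-counting quantitation core: Rsc, NSAF, and DE classification.

Rsc is the log2 ratio of spectral counts between two conditions with an
additive pseudo-count correction factor ``f`` and a complement term over the
total spectra of each run:

    Rsc = log2((n_s + f) / (n_n + f)) + log2((t_n - n_n + f) / (t_s - n_s + f))

where n_n, n_s are a protein's spectral counts in the two conditions and
t_n, t_s are the total spectra over all proteins in each run. The pseudo-count
(default 1.25) keeps the ratio defined when a protein is absent from one
condition; the complement term corrects for unequal sampling depth. Positive
Rsc means higher abundance in the second ("case") condition.

NSAF (normalized spectral abundance factor) is a within-sample relative
abundance: each protein's count divided by its length, normalized to sum to 1
over all proteins in the sample.

A protein is differentially expressed when Rsc > +1 or Rsc < −1, i.e. an
estimated fold change above 2 or below 0.5; boundary values are unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .errors import ConfigurationError, DataError, DomainError

__all__ = [
    "QuantConfig",
    "compute_rsc",
    "compute_nsaf",
    "classify",
    "quantify",
    "UP",
    "DOWN",
    "UNCHANGED",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class QuantConfig:
    """Tunables of the quantitation stage.

    f : additive pseudo-count in the Rsc ratio (must be > 0).
    up_threshold / down_threshold : strict Rsc cutoffs for the up/down calls;
    ±1 corresponds to a 2-fold change.
    """

    f: float = 1.25
    up_threshold: float = 1.0
    down_threshold: float = -1.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ConfigurationError("correction factor f must be positive")
        if not self.down_threshold < self.up_threshold:
            raise ConfigurationError("down_threshold must be below up_threshold")


def compute_rsc(n_s: float, n_n: float, t_s: float, t_n: float, f: float = 1.25) -> float:
    """Pseudo-count-corrected log2 spectral-count ratio for one protein.

    Parameters are the case count ``n_s``, control count ``n_n``, and the
    corresponding run totals ``t_s`` and ``t_n``. Preconditions (counts
    nonnegative, count ≤ its total, f > 0) are enforced, never clamped.
    """
    if f <= 0:
        raise DomainError("correction factor f must be positive")
    if n_s < 0 or n_n < 0:
        raise DomainError("spectral counts must be nonnegative")
    if t_s < n_s or t_n < n_n:
        raise DomainError("a protein's count cannot exceed its run total")
    return math.log2((n_s + f) / (n_n + f)) + math.log2((t_n - n_n + f) / (t_s - n_s + f))


def _rsc_vector(
    n_s: np.ndarray, n_n: np.ndarray, t_s: float, t_n: float, f: float
) -> np.ndarray:
    """Vectorized Rsc over all proteins of a matrix; same contract as compute_rsc."""
    if np.any(n_s < 0) or np.any(n_n < 0):
        raise DomainError("spectral counts must be nonnegative")
    if np.any(n_s > t_s) or np.any(n_n > t_n):
        raise DomainError("a protein's count cannot exceed its run total")
    return np.log2((n_s + f) / (n_n + f)) + np.log2((t_n - n_n + f) / (t_s - n_s + f))


def compute_nsaf(cm: CountMatrix, condition: str) -> dict[str, float]:
    """Normalized spectral abundance factors for one condition.

    The denominator runs over every protein in the matrix (both conditions
    share one protein universe); zero-count proteins contribute 0 and get
    NSAF 0. Values sum to 1.
    """
    if cm.lengths is None:
        raise DataError("count matrix carries no protein lengths; NSAF needs them")
    if condition not in cm.counts.columns:
        raise ConfigurationError(f"unknown condition {condition!r}")
    missing = [acc for acc in cm.counts.index if acc not in cm.lengths]
    if missing:
        raise DataError(f"no length for accession(s): {missing[:5]}")
    counts = cm.counts[condition].to_numpy(dtype=float)
    lengths = np.array([cm.lengths[acc] for acc in cm.counts.index], dtype=float)
    saf = counts / lengths
    denom = saf.sum()
    if denom == 0:
        raise DomainError(f"all spectral counts are zero in condition {condition!r}")
    nsaf = saf / denom
    return dict(zip(cm.counts.index, nsaf))


def classify(rsc: float, cfg: QuantConfig = QuantConfig()) -> str:
    """Differential-expression call from one Rsc value.

    Strict inequalities: a value exactly on a threshold is unchanged.
    """
    if rsc > cfg.up_threshold:
        return UP
    if rsc < cfg.down_threshold:
        return DOWN
    return UNCHANGED


def quantify(cm: CountMatrix, cfg: QuantConfig = QuantConfig()) -> pd.DataFrame:
    """Per-protein quantitation table for a two-condition count matrix.

    Columns: accession, n_a, n_b (counts in the first and second condition),
    rsc (log2, positive = up in the second condition), nsaf_a, nsaf_b,
    de_class. Rows are sorted by rsc descending, ties broken by accession.
    """
    cond_a, cond_b = cm.conditions
    t_a, t_b = cm.totals
    n_a = cm.counts[cond_a].to_numpy(dtype=float)
    n_b = cm.counts[cond_b].to_numpy(dtype=float)
    rsc = _rsc_vector(n_b, n_a, float(t_b), float(t_a), cfg.f)
    nsaf_a = compute_nsaf(cm, cond_a)
    nsaf_b = compute_nsaf(cm, cond_b)
    accs = list(cm.counts.index)
    table = pd.DataFrame(
        {
            "accession": accs,
            "n_a": n_a.astype(int),
            "n_b": n_b.astype(int),
            "rsc": rsc,
            "nsaf_a": [nsaf_a[a] for a in accs],
            "nsaf_b": [nsaf_b[a] for a in accs],
        }
    )
    table["de_class"] = [classify(v, cfg) for v in table["rsc"]]
    table = table.sort_values(
        ["rsc", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def de_counts(quant: pd.DataFrame) -> dict[str, int]:
    """Tally of up/down/unchanged calls in a quantitation table."""
    counts = quant["de_class"].value_counts().to_dict()
    return {cls: int(counts.get(cls, 0)) for cls in (UP, DOWN, UNCHANGED)}
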