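"""Aggregation of PSM rows into a protein × condition spectral-count matrix.

A spectral count is the number of MS/MS spectra (PSM rows) attributed to a
protein in one sample; it is the abundance proxy the whole pipeline rests
on. Each PSM row counts once toward exactly the accession it carries — no
shared-peptide apportionment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io import PsmTable

__all__ = ["CountMatrix", "count_spectra", "identified_sets"]


@dataclass
class CountMatrix:
    """Spectral counts per protein for two conditions.

    ``counts`` is indexed by accession with one integer column per
    condition. Totals are always recomputed from the matrix, never stored,
    so they cannot drift out of sync. ``lengths`` (residues per protein) is
    optional until NSAF is requested.
    """

    counts: pd.DataFrame
    lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[1] != 2:
            raise ConfigurationError("CountMatrix requires exactly two condition columns")
        if self.counts.index.has_duplicates:
            raise DataError("duplicate accessions in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative spectral counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def conditions(self) -> tuple[str, str]:
        return tuple(self.counts.columns)  # type: ignore[return-value]

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def total(self, condition: str) -> int:
        """Total spectra over all proteins in one condition (t_n or t_s)."""
        if condition not in self.counts.columns:
            raise ConfigurationError(f"unknown condition {condition!r}")
        return int(self.counts[condition].sum())

    @property
    def totals(self) -> tuple[int, int]:
        a, b = self.conditions
        return self.total(a), self.total(b)

    def count(self, protein: str, condition: str) -> int:
        return int(self.counts.at[protein, condition])

    def with_lengths(self, lengths: Mapping[str, int]) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), lengths=dict(lengths))

    def to_frame(self) -> pd.DataFrame:
        """Long-lived TSV layout: accession, per-condition counts, length."""
        out = self.counts.reset_index().rename(columns={"index": "accession"})
        if out.columns[0] != "accession":
            out = out.rename(columns={out.columns[0]: "accession"})
        if self.lengths is not None:
            out["length"] = [self.lengths.get(acc) for acc in out["accession"]]
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_spectra(
    psm: PsmTable,
    conditions: tuple[str, str],
    condition_of: Mapping[str, str] | None = None,
    allow_empty_condition: bool = False,
) -> CountMatrix:
    """Tally PSM rows into per-protein, per-condition spectral counts.

    Parameters
    ----------
    psm
        The parsed PSM table.
    conditions
        Ordered pair of condition labels; the order fixes the matrix's
        column order (and hence the sign convention downstream).
    condition_of
        Optional map from sample_id to condition, used to pool several
        samples per condition by summation. By default each sample_id is
        taken to be a condition label itself.
    allow_empty_condition
        Permit a condition with zero PSM rows (the matrix column is all
        zeros). Without the flag this is a configuration error, since it
        usually signals a mislabeled input.

    Proteins with zero counts in both conditions never enter the matrix.
    """
    cond_a, cond_b = conditions
    if cond_a == cond_b:
        raise ConfigurationError("condition labels must be distinct")

    samples = psm.frame["sample_id"]
    if condition_of is not None:
        unknown = set(samples.unique()) - set(condition_of)
        if unknown:
            raise ConfigurationError(f"sample_id(s) {sorted(unknown)} missing from condition map")
        mapped = samples.map(condition_of)
    else:
        mapped = samples
    bad = set(mapped.unique()) - {cond_a, cond_b}
    if bad:
        raise ConfigurationError(
            f"sample label(s) {sorted(bad)} do not match conditions {conditions}"
        )
    for cond in conditions:
        if cond not in set(mapped.unique()) and not allow_empty_condition:
            raise ConfigurationError(
                f"condition {cond!r} has no PSM rows (pass allow_empty_condition to permit)"
            )

    tally = (
        pd.DataFrame({"accession": psm.frame["protein_accession"], "condition": mapped})
        .groupby(["accession", "condition"], sort=False)
        .size()
        .unstack(fill_value=0)
    )
    for cond in conditions:
        if cond not in tally.columns:
            tally[cond] = 0
    tally = tally[list(conditions)]
    tally = tally.sort_index()
    tally.columns.name = None
    tally.index.name = "accession"
    return CountMatrix(tally)


def empty_count_matrix(conditions: tuple[str, str]) -> CountMatrix:
    """A valid matrix with no proteins and totals (0, 0)."""
    frame = pd.DataFrame(columns=list(conditions), index=pd.Index([], name="accession"))
    return CountMatrix(frame)


def identified_sets(cm: CountMatrix, min_count: int = 1) -> tuple[set[str], set[str]]:
    """Identified-protein sets per condition: count ≥ min_count.

    Spectral count ≥ 1 is the default identification criterion, matching
    the convention that any protein with at least one attributed spectrum
    counts as identified in that sample.
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be ≥ 1")
    a, b = cm.conditions
    set_a = set(cm.counts.index[cm.counts[a] >= min_count])
    set_b = set(cm.counts.index[cm.counts[b] >= min_count])
    return set_a, set_b
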