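"""Synthetic two-condition spectral-counting experiments with known truth.

The generator emulates the statistical structure a spectral-counting
comparison assumes: each condition is a single pooled sample whose total
spectrum count is Poisson-distributed around a target depth, and the spectra
fall on proteins multinomially according to the condition's true relative
abundances. A planted subset of proteins carries a fold change (up or down
with equal probability) between conditions; everything else is null. The
multinomial-conditional-on-Poisson-total model keeps abundances summing to
exactly 1 per condition; independent per-protein Poissons are available as a
switch.

Defaults approximate the scale of a small-animal corneal proteome run:
500 proteins, ~5,000 spectra per condition, 10% of proteins planted with a
4-fold shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .errors import ConfigurationError, DataError
from .io import PsmTable
from .quant import DOWN, UNCHANGED, UP

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate",
    "simulate_counts",
    "evaluate_recovery",
    "RecoveryStats",
]

NULL = "null"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic experiment.

    n_proteins : size of the protein universe.
    length_range : (min, max) protein length in residues, drawn uniformly.
    de_fraction : fraction of proteins planted with a fold change.
    fold_change : multiplicative abundance shift (> 1), applied up or down
        with equal probability.
    depth : expected total spectra per condition.
    seed : RNG seed; all randomness derives from it.
    baseline : relative-abundance distribution; "log_uniform" spans
        ``abundance_span`` orders of magnitude, "uniform" is flat.
    count_model : "multinomial" (total ~ Poisson(depth), counts multinomial)
        or "poisson" (independent per-protein Poissons).
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 1000)
    de_fraction: float = 0.1
    fold_change: float = 4.0
    depth: float = 5000.0
    seed: int = 0
    baseline: Literal["log_uniform", "uniform"] = "log_uniform"
    abundance_span: float = 100.0
    count_model: Literal["multinomial", "poisson"] = "multinomial"
    conditions: tuple[str, str] = ("normal", "stz")

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be ≥ 1")
        if self.depth < 1:
            raise ConfigurationError("depth must be ≥ 1")
        if not 0 <= self.de_fraction < 1:
            raise ConfigurationError("de_fraction must be in [0, 1)")
        if self.fold_change <= 1:
            raise ConfigurationError("fold_change must exceed 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("length_range must satisfy 1 ≤ min ≤ max")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-condition abundances and DE labels.

    ``frame`` columns: accession, abundance_a, abundance_b (true relative
    abundances, each summing to 1), de_label in {up, down, null}. "up" means
    more abundant in the second condition.
    """

    frame: pd.DataFrame

    def labels(self) -> dict[str, str]:
        return dict(zip(self.frame["accession"], self.frame["de_label"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _abundances(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.baseline == "log_uniform":
        w = np.exp(rng.uniform(0.0, np.log(cfg.abundance_span), cfg.n_proteins))
    elif cfg.baseline == "uniform":
        w = rng.uniform(0.5, 1.5, cfg.n_proteins)
    else:
        raise ConfigurationError(f"unknown baseline {cfg.baseline!r}")
    return w / w.sum()


def simulate_counts(cfg: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix plus its ground truth (no PSM expansion)."""
    rng = np.random.default_rng(cfg.seed)
    accs = [f"SYN{i:04d}" for i in range(cfg.n_proteins)]
    lengths = {
        acc: int(L)
        for acc, L in zip(
            accs, rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, cfg.n_proteins)
        )
    }

    base = _abundances(cfg, rng)
    n_de = int(round(cfg.de_fraction * cfg.n_proteins))
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    up_mask = rng.random(n_de) < 0.5

    weights_b = base.copy()
    labels = np.full(cfg.n_proteins, NULL, dtype=object)
    for j, idx in enumerate(de_idx):
        if up_mask[j]:
            weights_b[idx] *= cfg.fold_change
            labels[idx] = UP
        else:
            weights_b[idx] /= cfg.fold_change
            labels[idx] = DOWN
    abund_a = base
    abund_b = weights_b / weights_b.sum()

    counts = np.empty((cfg.n_proteins, 2), dtype=np.int64)
    for col, abund in enumerate((abund_a, abund_b)):
        if cfg.count_model == "multinomial":
            total = rng.poisson(cfg.depth)
            counts[:, col] = rng.multinomial(total, abund)
        else:
            counts[:, col] = rng.poisson(cfg.depth * abund)

    frame = pd.DataFrame(
        counts, index=pd.Index(accs, name="accession"), columns=list(cfg.conditions)
    )
    # drop proteins never observed — they would not appear in a real report
    observed = frame.sum(axis=1) > 0
    cm = CountMatrix(frame[observed], lengths=lengths)
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "accession": accs,
                "abundance_a": abund_a,
                "abundance_b": abund_b,
                "de_label": labels,
            }
        )
    )
    return cm, truth


def simulate(cfg: SyntheticConfig) -> tuple[PsmTable, dict[str, int], SyntheticTruth]:
    """Full synthetic experiment: PSM rows, protein lengths, and truth.

    Each spectral count is expanded to one PSM row with a synthetic
    spectrum id; the result round-trips through the counting stage to the
    matrix it was drawn from. Deterministic for a fixed seed.
    """
    cm, truth = simulate_counts(cfg)
    cond_a, cond_b = cfg.conditions
    rows: list[tuple[str, str, str]] = []
    spec_no = 0
    for acc in cm.proteins:
        for cond in (cond_a, cond_b):
            for _ in range(cm.count(acc, cond)):
                rows.append((cond, acc, f"scan{spec_no:06d}"))
                spec_no += 1
    frame = pd.DataFrame(rows, columns=["sample_id", "protein_accession", "spectrum_id"])
    assert cm.lengths is not None
    return PsmTable(frame, conditions=cfg.conditions), cm.lengths, truth


@dataclass(frozen=True)
class RecoveryStats:
    """How well the DE classification recovered the planted truth.

    sensitivity : planted proteins called DE with the correct sign / planted.
    false_positive_rate : null proteins called DE / null.
    sign_accuracy : correct-sign fraction among planted proteins called DE
        (NaN when none were recovered).
    n_planted, n_null : denominators after any expected-count filter.
    """

    sensitivity: float
    false_positive_rate: float
    sign_accuracy: float
    n_planted: int
    n_null: int


def evaluate_recovery(
    quant: pd.DataFrame,
    truth: SyntheticTruth,
    min_expected: float = 0.0,
    depth: float | None = None,
) -> RecoveryStats:
    """Score a quantitation table against the planted truth.

    Proteins absent from the quantitation table (never observed) count as
    classified "unchanged". With ``min_expected`` > 0 and a ``depth``, only
    proteins whose expected count (depth × true abundance) reaches the
    threshold in at least one condition enter the tally — low-abundance
    proteins carry too few spectra for any count-based call.
    """
    calls = dict(zip(quant["accession"], quant["de_class"]))
    unknown = set(calls) - set(truth.frame["accession"])
    if unknown:
        raise DataError(f"quantified accession(s) not in truth: {sorted(unknown)[:3]}")

    tf = truth.frame
    if min_expected > 0:
        if depth is None:
            raise ConfigurationError("min_expected filtering needs the experiment depth")
        keep = (tf["abundance_a"] * depth >= min_expected) | (
            tf["abundance_b"] * depth >= min_expected
        )
        tf = tf[keep]

    planted = tf[tf["de_label"].isin([UP, DOWN])]
    null = tf[tf["de_label"] == NULL]

    correct_sign = sum(
        1
        for acc, label in zip(planted["accession"], planted["de_label"])
        if calls.get(acc, UNCHANGED) == label
    )
    recovered = sum(
        1
        for acc in planted["accession"]
        if calls.get(acc, UNCHANGED) in (UP, DOWN)
    )
    false_pos = sum(
        1 for acc in null["accession"] if calls.get(acc, UNCHANGED) in (UP, DOWN)
    )

    sensitivity = correct_sign / len(planted) if len(planted) else float("nan")
    fpr = false_pos / len(null) if len(null) else float("nan")
    sign_acc = correct_sign / recovered if recovered else float("nan")
    return RecoveryStats(sensitivity, fpr, sign_acc, len(planted), len(null))
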