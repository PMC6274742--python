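"""End-to-end orchestration: counts → quantitation → set comparison → enrichment.

The sign convention is fixed by the order of the condition labels: the first
condition is the reference (denominator of the count ratio), the second is
the case, so positive Rsc means up in the case condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .counting import count_spectra, identified_sets
from .enrichment import enrich
from .errors import SpeccountError
from .io import (
    read_annotation_table,
    read_lengths_fasta,
    read_lengths_table,
    read_psm_table,
)
from .quant import QuantConfig, de_counts, quantify
from .setops import venn_compare

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(SpeccountError):
    """An error wrapped with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``conditions`` is (reference, case); positive Rsc = up in the case.
    Lengths come from ``fasta`` or ``lengths`` (two-column TSV), one of which
    is required. ``annotation`` enables the enrichment stage.
    """

    psm: str | Path
    conditions: tuple[str, str]
    out_dir: str | Path
    dialect: str = "tsv"
    column_map: Mapping[str, str] | None = None
    fasta: str | Path | None = None
    lengths: str | Path | None = None
    annotation: str | Path | None = None
    quant: QuantConfig = field(default_factory=QuantConfig)
    min_count: int = 1
    min_k: int = 2
    ease: bool = False

    def __post_init__(self) -> None:
        if self.conditions[0] == self.conditions[1]:
            raise SpeccountError("condition labels must be distinct")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SpeccountError as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the result tables under ``cfg.out_dir``.

    Writes counts.tsv, quant.tsv (Rsc-ranked), venn.tsv, enrichment.tsv
    (when an annotation is supplied) and run.log. Deterministic: rerunning
    on the same inputs reproduces the files byte for byte. Returns the
    paths written, keyed by stage name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log_lines = [
        f"speccount {__version__}",
        f"psm={cfg.psm} dialect={cfg.dialect}",
        f"conditions={cfg.conditions[0]},{cfg.conditions[1]} (positive rsc = up in {cfg.conditions[1]})",
        f"f={cfg.quant.f} up_threshold={cfg.quant.up_threshold} "
        f"down_threshold={cfg.quant.down_threshold} min_count={cfg.min_count}",
    ]

    psm = _stage("io_psm")(read_psm_table)(
        cfg.psm, dialect=cfg.dialect, column_map=cfg.column_map, conditions=cfg.conditions
    )
    log_lines.append(f"psm_rows={len(psm)}")

    if cfg.fasta is not None:
        lengths = _stage("io_psm")(read_lengths_fasta)(cfg.fasta)
    elif cfg.lengths is not None:
        lengths = _stage("io_psm")(read_lengths_table)(cfg.lengths)
    else:
        lengths = None

    cm = _stage("counting")(count_spectra)(psm, cfg.conditions)
    if lengths is not None:
        cm = cm.with_lengths(lengths)
    counts_path = out_dir / "counts.tsv"
    cm.to_tsv(counts_path)
    artifacts["counts"] = counts_path
    log_lines.append(f"proteins={len(cm.proteins)} totals={cm.totals}")

    if lengths is None:
        raise StageError("quant", SpeccountError("NSAF requires protein lengths (--fasta or --lengths)"))
    table = _stage("quant")(quantify)(cm, cfg.quant)
    quant_path = out_dir / "quant.tsv"
    table.to_csv(quant_path, sep="\t", index=False, float_format="%.6g")
    artifacts["quant"] = quant_path
    tallies = de_counts(table)
    log_lines.append(
        f"de_up={tallies['up']} de_down={tallies['down']} unchanged={tallies['unchanged']}"
    )

    set_a, set_b = _stage("setops")(identified_sets)(cm, cfg.min_count)
    venn = venn_compare(set_a, set_b)
    venn_path = out_dir / "venn.tsv"
    venn.to_tsv(venn_path)
    artifacts["venn"] = venn_path
    log_lines.append(f"venn_total={venn.total} shared={venn.shared}")

    if cfg.annotation is not None:
        ann = _stage("enrichment")(read_annotation_table)(cfg.annotation)
        de_set = set(table.loc[table["de_class"] != "unchanged", "accession"])
        background = set(cm.proteins)
        result = _stage("enrichment")(enrich)(de_set, background, ann, min_k=cfg.min_k, ease=cfg.ease)
        enrich_path = out_dir / "enrichment.tsv"
        result.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
        artifacts["enrichment"] = enrich_path
        log_lines.append(f"enriched_categories={len(result)} (min_k={cfg.min_k} ease={cfg.ease})")

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = log_path
    for line in log_lines:
        logger.info(line)
    return artifacts
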