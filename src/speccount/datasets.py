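"""Bundled reference data for tests, examples, and the acceptance checks.

The extracellular-matrix (ECM) reference table lists the 15 proteins reported
as differentially expressed (|Rsc| > 1) in the cornea of the
streptozotocin-induced diabetic rat versus the normal rat and annotated with
the Gene Ontology cellular-component term "extracellular matrix": SwissProt
accession, protein name, and published Rsc value (positive = up in the
diabetic cornea).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ecm_reference_table", "ecm_annotation"]

ECM_CATEGORY = "extracellular matrix"

_ECM_ROWS = [
    ("P30427", "Plectin", -2.277),
    ("P69897", "Tubulin beta-5 chain", -2.154),
    ("Q6P9T8", "Tubulin beta-4B chain", -2.062),
    ("P05197", "Elongation factor 2", -2.062),
    ("P61980", "Heterogeneous nuclear ribonucleoprotein K", -1.505),
    ("P61751", "ADP-ribosylation factor 4", -1.505),
    ("P62271", "40S ribosomal protein S18", -1.117),
    ("P45592", "Cofilin-1", -1.117),
    ("P49744", "Thrombospondin-4", 1.111),
    ("P02466", "Collagen alpha-2(I) chain", 1.111),
    ("Q8CJD3", "Zymogen granule membrane protein 16", 1.111),
    ("P51886", "Lumican", 1.459),
    ("Q9EQP5", "Prolargin", 1.488),
    ("P47853", "Biglycan", 1.740),
    ("Q01129", "Decorin", 2.0601),
]


def ecm_reference_table() -> pd.DataFrame:
    """The 15 published ECM differential-expression rows.

    Columns: accession, description, rsc.
    """
    return pd.DataFrame(_ECM_ROWS, columns=["accession", "description", "rsc"])


def ecm_annotation() -> dict[str, set[str]]:
    """Annotation map assigning each ECM reference accession its category."""
    return {acc: {ECM_CATEGORY} for acc, _, _ in _ECM_ROWS}
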