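import pandas as pd
import pytest

from speccount import PsmTable, SyntheticConfig, simulate


@pytest.fixture
def small_psm() -> PsmTable:
    """Hand-built six-row PSM table: P1 3×normal, P2 1×normal + 2×stz."""
    rows = [
        ("normal", "P1"),
        ("normal", "P1"),
        ("normal", "P1"),
        ("normal", "P2"),
        ("stz", "P2"),
        ("stz", "P2"),
    ]
    frame = pd.DataFrame(rows, columns=["sample_id", "protein_accession"])
    return PsmTable(frame, conditions=("normal", "stz"))


@pytest.fixture(scope="session")
def synthetic_experiment():
    """One fixed-seed synthetic experiment shared across tests."""
    cfg = SyntheticConfig(n_proteins=60, depth=800.0, de_fraction=0.1, fold_change=4.0, seed=7)
    psm, lengths, truth = simulate(cfg)
    return cfg, psm, lengths, truth


def write_psm_tsv(psm: PsmTable, path) -> None:
    from speccount.io import write_psm_table

    write_psm_table(psm, path)
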