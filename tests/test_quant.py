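"""Rsc statistic, NSAF normalization, and DE classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccount import (
    CountMatrix,
    DataError,
    DomainError,
    QuantConfig,
    classify,
    compute_nsaf,
    compute_rsc,
    quantify,
)
from speccount.datasets import ecm_reference_table
from speccount.quant import DOWN, UNCHANGED, UP, de_counts

TOL = 1e-12


def rsc_oracle(n_s, n_n, t_s, t_n, f=1.25):
    """Independent scalar evaluation via natural logs, term by term."""
    ln2 = math.log(2.0)
    return (
        math.log((n_s + f) / (n_n + f)) / ln2
        + math.log((t_n - n_n + f) / (t_s - n_s + f)) / ln2
    )


def _matrix(counts, lengths=None, conditions=("normal", "stz")):
    accs = [f"P{i}" for i in range(len(counts))]
    frame = pd.DataFrame(counts, columns=list(conditions), index=pd.Index(accs, name="accession"))
    return CountMatrix(frame, lengths=dict(zip(accs, lengths)) if lengths else None)


class TestComputeRsc:
    def test_symmetric_counts_give_zero(self):
        assert compute_rsc(5, 5, 100, 100) == pytest.approx(0.0, abs=TOL)

    def test_two_fold_example(self):
        # log2(11.25/6.25) + log2(96.25/91.25), frozen from the scalar oracle
        assert compute_rsc(10, 5, 100, 100) == pytest.approx(0.9249588883698342, abs=TOL)

    def test_matches_scalar_oracle_on_random_tuples(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            t_s, t_n = rng.integers(10, 100000, 2)
            n_s = int(rng.integers(0, t_s + 1))
            n_n = int(rng.integers(0, t_n + 1))
            assert compute_rsc(n_s, n_n, t_s, t_n) == pytest.approx(
                rsc_oracle(n_s, n_n, t_s, t_n), abs=TOL
            )

    @pytest.mark.parametrize(
        "args",
        [(-1, 5, 100, 100), (5, -1, 100, 100), (101, 5, 100, 100), (5, 101, 100, 100)],
    )
    def test_precondition_violations_raise(self, args):
        with pytest.raises(DomainError):
            compute_rsc(*args)

    def test_nonpositive_f_rejected(self):
        with pytest.raises(DomainError):
            compute_rsc(1, 1, 10, 10, f=0.0)

    def test_large_count_limit_approaches_log2_fold(self):
        """With counts small relative to totals, Rsc converges to log2 of the
        count ratio — the sense in which |Rsc| > 1 means a 2-fold change."""
        rsc = compute_rsc(1000, 500, 10**6, 10**6)
        assert abs(rsc - math.log2(2.0)) < 0.05


class TestClassify:
    @pytest.mark.parametrize(
        "rsc,expected",
        [
            (2.0601, UP),
            (1.459, UP),
            (1.111, UP),
            (-2.277, DOWN),
            (-1.117, DOWN),
            (1.0, UNCHANGED),
            (-1.0, UNCHANGED),
            (0.0, UNCHANGED),
        ],
    )
    def test_threshold_rule(self, rsc, expected):
        assert classify(rsc) == expected

    def test_published_ecm_table_splits_eight_down_seven_up(self):
        table = ecm_reference_table()
        calls = table["rsc"].map(classify)
        assert (calls == DOWN).sum() == 8
        assert (calls == UP).sum() == 7
        assert calls[table["accession"] == "P51886"].item() == UP  # lumican

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            QuantConfig(f=-1.0)
        with pytest.raises(Exception):
            QuantConfig(up_threshold=-1.0, down_threshold=1.0)


class TestNsaf:
    def test_single_protein_is_one(self):
        cm = _matrix([[7, 3]], lengths=[100])
        assert compute_nsaf(cm, "normal") == {"P0": 1.0}

    def test_hand_oracle_two_proteins(self):
        # counts 4,2 with lengths 100,200 → SAF 0.04, 0.01 → NSAF 0.8, 0.2
        cm = _matrix([[4, 1], [2, 1]], lengths=[100, 200])
        nsaf = compute_nsaf(cm, "normal")
        assert nsaf["P0"] == pytest.approx(0.8, abs=TOL)
        assert nsaf["P1"] == pytest.approx(0.2, abs=TOL)

    def test_equal_counts_equal_lengths_uniform(self):
        n = 8
        cm = _matrix([[5, 5]] * n, lengths=[300] * n)
        nsaf = compute_nsaf(cm, "stz")
        for v in nsaf.values():
            assert v == pytest.approx(1 / n, abs=TOL)

    def test_zero_count_protein_has_zero_nsaf_and_sum_is_one(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 20, size=(30, 2))
        counts[3] = [0, 0]
        cm = _matrix(counts.tolist(), lengths=list(rng.integers(50, 900, 30)))
        for cond in cm.conditions:
            nsaf = compute_nsaf(cm, cond)
            assert sum(nsaf.values()) == pytest.approx(1.0, abs=TOL)
            assert nsaf["P3"] == 0.0

    def test_missing_length_names_accession(self):
        cm = _matrix([[1, 1], [1, 1]], lengths=[100, 100])
        assert cm.lengths is not None
        del cm.lengths["P1"]
        with pytest.raises(DataError, match="P1"):
            compute_nsaf(cm, "normal")

    def test_all_zero_condition_is_domain_error(self):
        cm = _matrix([[3, 0], [2, 0]], lengths=[100, 100])
        with pytest.raises(DomainError):
            compute_nsaf(cm, "stz")


class TestQuantify:
    def test_symmetric_matrix_all_unchanged(self):
        cm = _matrix([[5, 5], [9, 9]], lengths=[100, 200])
        table = quantify(cm)
        assert (table["de_class"] == UNCHANGED).all()
        assert table["rsc"].abs().max() < TOL

    def test_planted_eightfold_protein_is_called_up(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(5, 30, size=(50, 2)).tolist()
        counts[0] = [20, 160]  # 8-fold up in the case condition
        cm = _matrix(counts, lengths=[200] * 50)
        table = quantify(cm)
        row = table[table["accession"] == "P0"].iloc[0]
        assert row["de_class"] == UP
        assert row["rsc"] == pytest.approx(
            rsc_oracle(160, 20, cm.total("stz"), cm.total("normal")), abs=TOL
        )

    def test_classes_partition_the_proteins(self):
        rng = np.random.default_rng(2)
        cm = _matrix(
            rng.integers(0, 40, size=(80, 2)).tolist(),
            lengths=list(rng.integers(50, 500, 80)),
        )
        table = quantify(cm)
        tallies = de_counts(table)
        assert sum(tallies.values()) == len(cm.proteins)

    def test_vectorized_equals_scalar_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            counts = rng.integers(0, 50, size=(n, 2))
            if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
                continue
            cm = _matrix(counts.tolist(), lengths=list(rng.integers(50, 900, n)))
            table = quantify(cm)
            t_n, t_s = cm.totals
            for _, row in table.iterrows():
                assert row["rsc"] == pytest.approx(
                    rsc_oracle(row["n_b"], row["n_a"], t_s, t_n), abs=TOL
                )

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(40, 2))
        counts[0] = [0, 12]  # one protein absent from the reference
        lengths = list(rng.integers(50, 500, 40))
        cm = _matrix(counts.tolist(), lengths=lengths)
        swapped = CountMatrix(cm.counts[["stz", "normal"]], lengths=cm.lengths)
        fwd = quantify(cm).set_index("accession")["rsc"]
        rev = quantify(swapped).set_index("accession")["rsc"]
        assert (fwd + rev).abs().max() < TOL

    def test_sorted_by_rsc_descending_ties_by_accession(self):
        cm = _matrix([[5, 5], [5, 5], [1, 20]], lengths=[100, 100, 100])
        table = quantify(cm)
        assert list(table["rsc"]) == sorted(table["rsc"], reverse=True)
        ties = table[table["rsc"].abs() < TOL]
        assert list(ties["accession"]) == sorted(ties["accession"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.integers(0, 500),
    st.integers(0, 500),
    st.integers(0, 5000),
    st.integers(0, 5000),
    st.floats(0.1, 10.0),
)
def test_rsc_antisymmetry_property(n_s, n_n, extra_s, extra_n, f):
    """Swapping conditions negates the statistic for any admissible tuple."""
    t_s, t_n = n_s + extra_s, n_n + extra_n
    fwd = compute_rsc(n_s, n_n, t_s, t_n, f)
    rev = compute_rsc(n_n, n_s, t_n, t_s, f)
    assert fwd == pytest.approx(-rev, abs=TOL)
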