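"""Category over-representation among differentially expressed proteins.

A local, reproducible stand-in for web-based functional-annotation services:
given an accession→categories map, each category is tested for enrichment in
the DE set against a background (by default all identified proteins) with a
one-sided hypergeometric tail P(X ≥ k), optionally the conservative EASE-style
variant that scores k−1 successes. Raw p-values are adjusted across the
reported categories by Benjamini–Hochberg.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

__all__ = ["enrich", "category_counts"]

AnnotationMap = Mapping[str, set[str]]


def category_counts(proteins: Iterable[str], ann: AnnotationMap) -> dict[str, int]:
    """Number of proteins from ``proteins`` annotated with each category."""
    counts: dict[str, int] = {}
    for acc in set(proteins):
        for cat in ann.get(acc, ()):  # unannotated proteins contribute nothing
            counts[cat] = counts.get(cat, 0) + 1
    return counts


def enrich(
    de: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    min_k: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """Test each annotation category for over-representation in the DE set.

    Parameters
    ----------
    de, background
        DE accessions and the background universe; ``de`` must be a subset.
    ann
        accession → set of category labels.
    min_k
        Categories with fewer than this many DE members are not reported.
    ease
        If true, score k−1 successes instead of k (the conservative variant
        popularized by the EASE tool); p-values become larger.

    Returns a DataFrame with columns category, k, K, n, N, p_value,
    adjusted_p (Benjamini–Hochberg across the reported categories), sorted
    by p_value ascending then category.
    """
    de_set, bg_set = set(de), set(background)
    if not bg_set:
        raise DataError("background set is empty")
    if not de_set <= bg_set:
        raise DataError(
            f"DE set is not a subset of the background "
            f"(e.g. {sorted(de_set - bg_set)[:3]})"
        )
    if min_k < 1:
        raise ConfigurationError("min_k must be ≥ 1")

    n, N = len(de_set), len(bg_set)
    de_cat = category_counts(de_set, ann)
    bg_cat = category_counts(bg_set, ann)

    rows = []
    for cat in sorted(de_cat):
        k = de_cat[cat]
        if k < min_k:
            continue
        K = bg_cat[cat]
        successes = k - 1 if ease else k
        # tail P(X ≥ successes) under Hypergeom(N, K, n)
        p = float(hypergeom.sf(successes - 1, N, K, n))
        p = min(p, 1.0)
        rows.append({"category": cat, "k": k, "K": K, "n": n, "N": N, "p_value": p})

    result = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p_value"])
    if len(result):
        result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(["p_value", "category"]).reset_index(drop=True)
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result
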