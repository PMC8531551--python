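"""Hypergeometric over-representation analysis of differentially methylated genes.

Gene sets come from user-supplied GMT files; the background is the set of
genes represented on the array (the only defensible universe for a promoter
array design). For a query of n genes and a set of K genes in a background
of N, the raw p-value is the hypergeometric upper tail P(X ≥ k) of the
overlap k, and fold enrichment is (k/n)/(K/N).

Two significance schemes mirror the dual thresholds commonly used for
pathway and ontology collections: a set is significant iff it has ≥ 2 query
genes and — pathway: BH-FDR P < 0.05 and fold ≥ 1.50; ontology: raw
P < 0.01 and fold ≥ 1.10. The FDR column is always computed and reported,
whichever rule applies.

An EASE-style conservative variant (scoring k−1 successes) is available via
``ease=True``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

KIND_RULES = {
    "pathway": {"max_p": 0.05, "use_fdr": True, "min_fold": 1.50},
    "ontology": {"max_p": 0.01, "use_fdr": False, "min_fold": 1.10},
}
MIN_GENES = 2


@dataclass
class GeneSetCollection:
    name: str
    kind: str  # "pathway" | "ontology"
    sets: dict[str, tuple[str, frozenset[str]]]  # id -> (term name, members)
    background: frozenset[str]

    def __post_init__(self):
        if self.kind not in KIND_RULES:
            raise ValueError(f"kind must be one of {sorted(KIND_RULES)}")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into {set id: (description, members)}."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return sets


def make_collection(
    sets: dict[str, tuple[str, frozenset[str]]],
    background: set[str],
    kind: str,
    name: str = "collection",
) -> GeneSetCollection:
    """Restrict sets to the background and drop sets left empty."""
    restricted = {}
    bg = frozenset(background)
    for sid, (desc, members) in sets.items():
        kept = frozenset(members) & bg
        if kept:
            restricted[sid] = (desc, kept)
    return GeneSetCollection(name=name, kind=kind, sets=restricted, background=bg)


def test_set(
    query: set[str], members: set[str], background: set[str], ease: bool = False
) -> tuple[int, float, float, list[str]]:
    """Hypergeometric upper-tail test of one gene set.

    Returns (k, fold_enrichment, p_raw, overlap genes). With ``ease`` the
    tail is evaluated at k−1 (the EASE score), a conservative variant.
    """
    N = len(background)
    n = len(query)
    if N == 0 or n == 0:
        raise ValueError("background and query must be non-empty")
    if not set(query) <= set(background):
        raise ValueError("query genes must be contained in the background")
    members = set(members) & set(background)
    K = len(members)
    overlap = sorted(set(query) & members)
    k = len(overlap)
    fold = (k / n) / (K / N) if K > 0 else 0.0
    score_k = max(k - 1, 0) if ease else k
    p = float(hypergeom.sf(score_k - 1, N, K, n))  # P(X >= score_k)
    return k, fold, min(p, 1.0), overlap


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


RESULT_COLUMNS = [
    "TERM_ID",
    "TERM_NAME",
    "GENE_COUNT",
    "FOLD_ENRICHMENT",
    "P_VALUE",
    "FDR",
    "SIGNIFICANT",
    "GENES",
]


def run_enrichment(
    query: set[str], collection: GeneSetCollection, ease: bool = False
) -> pd.DataFrame:
    """Test every set of a collection and apply its significance rule.

    Results are sorted by raw p-value; the SIGNIFICANT flag follows the
    collection kind's dual threshold plus the ≥ 2 query-gene floor.
    """
    rule = KIND_RULES[collection.kind]
    rows = []
    for sid, (desc, members) in collection.sets.items():
        k, fold, p, overlap = test_set(query, members, collection.background, ease=ease)
        rows.append((sid, desc, k, fold, p, overlap))
    df = pd.DataFrame(
        rows, columns=["TERM_ID", "TERM_NAME", "GENE_COUNT", "FOLD_ENRICHMENT", "P_VALUE", "_OV"]
    )
    df["FDR"] = bh_fdr(df["P_VALUE"]) if len(df) else []
    p_for_rule = df["FDR"] if rule["use_fdr"] else df["P_VALUE"]
    df["SIGNIFICANT"] = (
        (df["GENE_COUNT"] >= MIN_GENES)
        & (p_for_rule < rule["max_p"])
        & (df["FOLD_ENRICHMENT"] >= rule["min_fold"])
    )
    df["GENES"] = df["_OV"].map(lambda ov: ",".join(ov))
    df = df.drop(columns="_OV").sort_values(
        ["P_VALUE", "TERM_ID"], kind="mergesort"
    ).reset_index(drop=True)
    return df[RESULT_COLUMNS]


def write_enrichment_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
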