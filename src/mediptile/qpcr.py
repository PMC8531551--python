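"""qPCR quantification: 2^-ΔΔCt expression, MeDIP-qPCR percent input, 2×2 ANOVA.

Relative expression by the comparative-Ct method: per sample,
ΔCt = Ct(target) − Ct(reference gene); ΔΔCt subtracts the mean ΔCt of the
reference group (default the untreated control cell), and the fold change
is 2^−ΔΔCt, so the reference group has geometric-mean fold 1.

MeDIP-qPCR enrichment is expressed as percent of input, with the input
Ct corrected for its dilution:

    %input = 100 × 2^((Ct_input − log2(dilution)) − Ct_IP)

Group comparisons use a two-factor ANOVA (maternal diet × offspring diet)
with type-II sums of squares, which coincides with the classical balanced
decomposition when cell sizes are equal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

REQUIRED_QPCR_COLUMNS = [
    "sample",
    "maternal_diet",
    "offspring_diet",
    "gene",
    "ct_target",
    "ct_reference",
]


def _check_ct(values: pd.Series, label: str) -> None:
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError(f"non-finite {label} Ct value")
    if ((v < 10) | (v > 40)).any():
        warnings.warn(f"{label} Ct values outside the typical 10-40 cycle range")


def relative_expression(
    records: pd.DataFrame, reference_group: tuple[str, str] = ("NC", "CD")
) -> pd.DataFrame:
    """Per-sample 2^-ΔΔCt fold changes versus a reference group.

    ``reference_group`` is the (maternal_diet, offspring_diet) cell whose
    mean ΔCt anchors ΔΔCt. Returns the input with DELTA_CT, DELTA_DELTA_CT
    and FOLD columns appended.
    """
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s) {missing}")
    _check_ct(records["ct_target"], "target")
    _check_ct(records["ct_reference"], "reference")
    out = records.copy()
    out["DELTA_CT"] = out["ct_target"] - out["ct_reference"]
    ref = out[
        (out["maternal_diet"] == reference_group[0])
        & (out["offspring_diet"] == reference_group[1])
    ]
    if ref.empty:
        raise ValueError(f"reference group {reference_group} has no samples")
    out["DELTA_DELTA_CT"] = out["DELTA_CT"] - ref["DELTA_CT"].mean()
    out["FOLD"] = np.power(2.0, -out["DELTA_DELTA_CT"])
    return out


def percent_input(ct_ip: float, ct_input: float, dilution_factor: float = 1.0):
    """MeDIP-qPCR percent of (dilution-corrected) input."""
    if np.any(np.asarray(dilution_factor) <= 0):
        raise ValueError("dilution factor must be positive")
    adj_input = np.asarray(ct_input, dtype=float) - np.log2(dilution_factor)
    return 100.0 * np.power(2.0, adj_input - np.asarray(ct_ip, dtype=float))


def two_way_anova(
    values, factor_a, factor_b, names: tuple[str, str] = ("A", "B")
) -> dict:
    """Two-factor ANOVA with type-II sums of squares.

    Returns {'anova': DataFrame indexed by effect (A, B, A:B, Residual) with
    sum_sq/df/F/PR(>F), 'cells': per-cell mean ± SEM and n}. Requires ≥ 2
    observations in every factor combination.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "A": list(factor_a), "B": list(factor_b)}
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["A", "B"]).size()
    expected = df["A"].nunique() * df["B"].nunique()
    if len(counts) < expected or (counts < 2).any():
        raise ValueError("every factor-level combination needs >= 2 observations")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 F ratios on degenerate fixtures
        table = sm.stats.anova_lm(model, typ=2)
    table.index = [names[0], names[1], f"{names[0]}:{names[1]}", "Residual"]
    # an effect with zero sum of squares explains nothing: F = 0, P = 1
    # (avoids 0/0 = NaN when the residual variance is also zero)
    zero = table["sum_sq"] < 1e-12
    effect_rows = table.index != "Residual"
    table.loc[zero & effect_rows, "F"] = 0.0
    table.loc[zero & effect_rows, "PR(>F)"] = 1.0
    cells = (
        df.groupby(["A", "B"])["y"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
        .reset_index()
        .rename(columns={"A": names[0], "B": names[1]})
    )
    return {"anova": table, "cells": cells}


def expression_report(
    records: pd.DataFrame, reference_group: tuple[str, str] = ("NC", "CD")
) -> dict:
    """2^-ΔΔCt folds plus the 2×2 ANOVA of ΔCt per gene."""
    out = {}
    for gene, sub in records.groupby("gene"):
        folds = relative_expression(sub, reference_group=reference_group)
        anova = two_way_anova(
            folds["DELTA_CT"],
            folds["maternal_diet"],
            folds["offspring_diet"],
            names=("maternal_diet", "offspring_diet"),
        )
        out[gene] = {"folds": folds, **anova}
    return out
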