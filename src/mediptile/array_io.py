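"""Reading, validation and normalization of two-channel probe tables.

A MeDIP-chip array reports two fluorescence channels per probe: the
immunoprecipitated (MeDIP, Cy5) channel and the total-input (Cy3) channel.
The working quantity downstream is the per-probe log2(MeDIP/Input)
enrichment ratio; probe affinity cancels in the ratio, which is why
two-channel designs use it.

Probe tables are tab-delimited with header
``PROBE_ID  CHR  POSITION  GENE_ID  MEDIP_SIGNAL  INPUT_SIGNAL``,
one file per array. Positions are 1-based; all BED emitted elsewhere in the
package is 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROBE_TABLE_COLUMNS = [
    "PROBE_ID",
    "CHR",
    "POSITION",
    "GENE_ID",
    "MEDIP_SIGNAL",
    "INPUT_SIGNAL",
]


@dataclass(frozen=True)
class ProbeMeasurement:
    """One probe on one array: location, promoter link, two intensities."""

    probe_id: str
    chrom: str
    position: int  # 1-based bp
    gene_id: str
    medip: float  # arbitrary fluorescence units, > 0
    input: float  # > 0


@dataclass
class LogRatioArray:
    """Per-probe log2(MeDIP/Input) for one array.

    ``probes`` is a DataFrame indexed by PROBE_ID with columns CHR, POSITION,
    GENE_ID and LOG2_RATIO, canonically sorted by (CHR, POSITION, PROBE_ID).
    """

    array_id: str
    group: str  # e.g. "control"/"treated" or "NC-CD"/"DIO-CD"
    replicate: int
    probes: pd.DataFrame

    @property
    def log2_ratio(self) -> np.ndarray:
        return self.probes["LOG2_RATIO"].to_numpy()


def compute_log2_ratio(medip: float, input: float) -> float:
    """log2(MeDIP/Input) for one probe; both intensities must be positive."""
    if medip <= 0 or input <= 0:
        raise ValueError(
            f"channel intensities must be positive (medip={medip}, input={input})"
        )
    return float(np.log2(medip / input))


def read_probe_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate one array's probe table.

    Returns a DataFrame with the canonical columns, sorted by
    (CHR, POSITION, PROBE_ID). Raises ``ValueError`` naming the offending
    row for missing columns, non-positive intensities or duplicated probe
    ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"PROBE_ID": str, "CHR": str, "GENE_ID": str})
    missing = [c for c in PROBE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("MEDIP_SIGNAL", "INPUT_SIGNAL"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"{path}: non-positive {col} for probe {row['PROBE_ID']} "
                f"(row {bad[0] + 2})"
            )
    dup = df["PROBE_ID"][df["PROBE_ID"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe id {dup.iloc[0]!r}")
    return df.sort_values(["CHR", "POSITION", "PROBE_ID"], kind="mergesort").reset_index(
        drop=True
    )


def write_probe_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PROBE_TABLE_COLUMNS)


def log_ratio_array(
    df: pd.DataFrame, array_id: str, group: str, replicate: int
) -> LogRatioArray:
    """Turn a validated probe table into a LogRatioArray."""
    probes = df.set_index("PROBE_ID")[["CHR", "POSITION", "GENE_ID"]].copy()
    probes["LOG2_RATIO"] = np.log2(
        df["MEDIP_SIGNAL"].to_numpy() / df["INPUT_SIGNAL"].to_numpy()
    )
    return LogRatioArray(array_id=array_id, group=group, replicate=replicate, probes=probes)


NORMALIZATION_METHODS = ("none", "median")


def normalize_array(arr: LogRatioArray, method: str = "median") -> LogRatioArray:
    """Normalize one array's log ratios.

    ``median`` subtracts the per-array median so the median log-ratio is 0
    (the usual centering for two-channel ratio data when no external
    calibration exists); ``none`` passes values through — the default for
    synthetic data, whose ratios are already on a common scale.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}; use one of {NORMALIZATION_METHODS}")
    probes = arr.probes.copy()
    if method == "median":
        probes["LOG2_RATIO"] = probes["LOG2_RATIO"] - probes["LOG2_RATIO"].median()
    return LogRatioArray(arr.array_id, arr.group, arr.replicate, probes)


def load_arrays(
    paths_groups: list[tuple[str, str, int]], method: str = "none"
) -> list[LogRatioArray]:
    """Read several (path, group, replicate) probe tables and normalize.

    All arrays must share an identical probe set.
    """
    arrays = []
    for path, group, rep in paths_groups:
        df = read_probe_table(path)
        arr = log_ratio_array(df, array_id=os.path.basename(str(path)), group=group, replicate=rep)
        arrays.append(normalize_array(arr, method=method))
    ref = arrays[0].probes.index
    for arr in arrays[1:]:
        if not ref.equals(arr.probes.index):
            raise ValueError(
                f"probe set of {arr.array_id} does not match {arrays[0].array_id}"
            )
    return arrays
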