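"""Differential-enrichment calling on promoter tiling arrays.

The pipeline statistic is M′ — the per-probe difference between
group-averaged log2(MeDIP/Input) enrichment of the treated and control
groups:

    M′ = mean_treated[log2(MeDIP/Input)] − mean_control[log2(MeDIP/Input)]

Peaks are found by a sliding-window scan within each promoter: every probe
receives a one-sided enrichment p-value from a Kolmogorov–Smirnov
comparison of its window's replicate-pair differences against the
experiment-wide difference pool, runs of significant probes become
candidate peaks, nearby runs are merged, and the differentially enriched
peak (DEP) filter cascade — within-peak median enrichment, replicate
consistency (CV), PeakScore and combined P — yields the final
hyper-/hypomethylated DMR table.

No multiple-testing correction is applied across peaks; the filter cascade
is reported as-is and the output header says so.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .array_io import LogRatioArray

HYPER = "hyper"
HYPO = "hypo"


@dataclass
class ProbeStats:
    """Per-probe group statistics plus the replicate-pair differences.

    ``table`` is indexed by PROBE_ID, sorted by (CHR, POSITION, PROBE_ID),
    with columns CHR, POSITION, GENE_ID, mean/median log2 ratio per group,
    MPRIME, CV_CONTROL and CV_TREATED (CVs on linear-scale ratios).
    ``diffs`` holds treated−control log2-ratio differences per replicate
    pair, one row per probe, aligned with ``table``.
    """

    table: pd.DataFrame
    diffs: np.ndarray


@dataclass
class Peak:
    """A contiguous probe run passing the sliding-window scan.

    Coordinates are 0-based half-open. ``cv_control``/``cv_treated`` carry
    the member probes' coefficients of variation so the DEP filter can
    apply its replicate-consistency criterion.
    """

    chrom: str
    start: int
    end: int
    gene_id: str
    probe_ids: list[str]
    median_ratio_control: float
    median_ratio_treated: float
    median_mprime: float
    peak_p: float
    peak_score: float
    cv_control: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_treated: np.ndarray = field(default_factory=lambda: np.array([]))
    direction: str | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def compute_probe_stats(
    control: list[LogRatioArray], treated: list[LogRatioArray]
) -> ProbeStats:
    """Group means/medians, M′ and per-group CV for every probe.

    Requires ≥2 replicates per group with identical probe sets; replicate
    pairing for the difference pool is by replicate index, so both groups
    must have the same number of arrays. CVs are sd/mean across replicates
    of the linear-scale ratio 2**log2ratio (CV of a log ratio near zero is
    ill-defined).
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least 2 replicate arrays per group")
    if len(control) != len(treated):
        raise ValueError(
            "replicate-pair differences require equal group sizes "
            f"(control={len(control)}, treated={len(treated)})"
        )
    ref = control[0].probes.index
    for arr in control[1:] + treated:
        if not ref.equals(arr.probes.index):
            raise ValueError(f"probe set mismatch in array {arr.array_id}")

    ctl = np.column_stack([a.log2_ratio for a in control])
    trt = np.column_stack([a.log2_ratio for a in treated])

    def cv_linear(x: np.ndarray) -> np.ndarray:
        lin = np.power(2.0, x)
        m = lin.mean(axis=1)
        s = lin.std(axis=1, ddof=1)
        return s / m

    table = control[0].probes[["CHR", "POSITION", "GENE_ID"]].copy()
    table["MEAN_CONTROL"] = ctl.mean(axis=1)
    table["MEAN_TREATED"] = trt.mean(axis=1)
    table["MEDIAN_CONTROL"] = np.median(ctl, axis=1)
    table["MEDIAN_TREATED"] = np.median(trt, axis=1)
    table["MPRIME"] = table["MEAN_TREATED"] - table["MEAN_CONTROL"]
    table["CV_CONTROL"] = cv_linear(ctl)
    table["CV_TREATED"] = cv_linear(trt)
    return ProbeStats(table=table, diffs=trt - ctl)


def _ks_one_sided(window: np.ndarray, pool_sorted: np.ndarray, larger: bool) -> float:
    """One-sided KS p-value of ``window`` against the (much larger) pool.

    ``larger=True`` tests whether the window distribution is stochastically
    larger than the pool. The direction is chosen by the caller from the
    window mean, i.e. selected from the data, so the returned p doubles the
    exact one-sided tail (Birnbaum–Tingey, pool treated as the reference
    distribution since it dwarfs any window) — without the doubling the
    probe-level p would be anti-conservative by a factor ~2 under the null.
    """
    w = np.sort(window)
    n = len(w)
    m = len(pool_sorted)
    i = np.arange(n)
    if larger:
        # sup of F_pool − F_window, attained just below window jump points
        d = np.searchsorted(pool_sorted, w, side="left") / m - i / n
    else:
        d = (i + 1) / n - np.searchsorted(pool_sorted, w, side="right") / m
    D = max(float(d.max()), 0.0)
    return float(min(1.0, 2.0 * sps.ksone.sf(D, n)))


def probe_pvalues(
    stats: ProbeStats, window_bp: float = 750.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window enrichment p-value and direction per probe.

    For each probe, the window is every probe of the same promoter within
    window_bp/2 of it; the window's replicate-pair differences are KS-tested
    one-sidedly (in the direction of their mean) against the experiment-wide
    pool of differences. Returns (p, direction) with direction in
    {+1, −1, 0}; direction 0 (exactly zero mean difference) gets p = 1.
    """
    table = stats.table
    diffs = stats.diffs
    pool = np.sort(diffs.ravel())
    p = np.ones(len(table))
    direction = np.zeros(len(table), dtype=int)
    half = window_bp / 2.0

    pos_all = table["POSITION"].to_numpy()
    for _, idx in table.groupby("GENE_ID", sort=False).indices.items():
        idx = np.sort(idx)  # positional indices; table is position-sorted
        pos = pos_all[idx]
        for j, pj in enumerate(pos):
            sel = idx[(pos >= pj - half) & (pos <= pj + half)]
            w = diffs[sel].ravel()
            mu = w.mean()
            if mu == 0.0:
                continue
            d = 1 if mu > 0 else -1
            direction[idx[j]] = d
            p[idx[j]] = _ks_one_sided(w, pool, larger=(d > 0))
    return p, direction


def _runs(
    passing: np.ndarray, direction: np.ndarray, pos: np.ndarray, max_gap: float
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive passing probes sharing a direction.

    A run also breaks where adjacent probes lie more than max_gap bp apart —
    probes that far separated are distinct enrichment events. Returns
    [start, end] index pairs (inclusive) into the promoter's probes.
    """
    runs = []
    i, n = 0, len(passing)
    while i < n:
        if passing[i]:
            j = i
            while (
                j + 1 < n
                and passing[j + 1]
                and direction[j + 1] == direction[i]
                and pos[j + 1] - pos[j] <= max_gap
            ):
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def find_peaks(
    stats: ProbeStats,
    window_bp: float = 750.0,
    min_probes: int = 2,
    probe_p_cutoff: float = 0.1,
    merge_gap: float = 500.0,
) -> list[Peak]:
    """Sliding-window peak finding within each promoter.

    A candidate peak is a maximal run of ≥ min_probes consecutive
    same-direction probes with p ≤ probe_p_cutoff; candidate runs separated
    by ≤ merge_gap bp are merged, and every probe spanned by the merged
    interval becomes a member. peak_p is Fisher's combination of member
    probe p-values and peak_score the mean of −log10(probe p) over members.
    """
    table = stats.table
    if not table["POSITION"].groupby(table["GENE_ID"], sort=False).is_monotonic_increasing.all():
        raise ValueError("probes must be sorted by position within each promoter")
    p, direction = probe_pvalues(stats, window_bp=window_bp)

    peaks: list[Peak] = []
    pos_all = table["POSITION"].to_numpy()
    ctl_med = table["MEDIAN_CONTROL"].to_numpy()
    trt_med = table["MEDIAN_TREATED"].to_numpy()
    mprime = table["MPRIME"].to_numpy()
    cv_c = table["CV_CONTROL"].to_numpy()
    cv_t = table["CV_TREATED"].to_numpy()
    probe_ids = table.index.to_numpy()
    chroms = table["CHR"].to_numpy()

    for gene, idx in table.groupby("GENE_ID", sort=False).indices.items():
        idx = np.sort(idx)
        passing = p[idx] <= probe_p_cutoff
        runs = [
            r
            for r in _runs(passing, direction[idx], pos_all[idx], merge_gap)
            if r[1] - r[0] + 1 >= min_probes
        ]
        if not runs:
            continue
        # merge same-direction runs whose genomic gap is <= merge_gap
        merged: list[list[tuple[int, int]]] = [[runs[0]]]
        for r in runs[1:]:
            prev = merged[-1][-1]
            gap = pos_all[idx[r[0]]] - pos_all[idx[prev[1]]]
            if gap <= merge_gap and direction[idx[r[0]]] == direction[idx[prev[0]]]:
                merged[-1].append(r)
            else:
                merged.append([r])
        for group_runs in merged:
            lo, hi = group_runs[0][0], group_runs[-1][1]
            members = idx[lo : hi + 1]
            member_p = p[members]
            stat = -2.0 * np.sum(np.log(member_p))
            peak_p = float(sps.chi2.sf(stat, 2 * len(members)))
            peak_score = float(np.mean(-np.log10(member_p)))
            med_m = float(np.median(mprime[members]))
            peaks.append(
                Peak(
                    chrom=str(chroms[members[0]]),
                    start=int(pos_all[members[0]]) - 1,
                    end=int(pos_all[members[-1]]),
                    gene_id=str(gene),
                    probe_ids=[str(x) for x in probe_ids[members]],
                    median_ratio_control=float(np.median(ctl_med[members])),
                    median_ratio_treated=float(np.median(trt_med[members])),
                    median_mprime=med_m,
                    peak_p=peak_p,
                    peak_score=peak_score,
                    cv_control=cv_c[members].copy(),
                    cv_treated=cv_t[members].copy(),
                    direction=HYPER if med_m > 0 else (HYPO if med_m < 0 else None),
                )
            )
    return peaks


def filter_deps(
    peaks: list[Peak],
    min_median_ratio: float = 0.3,
    max_cv: float = 0.8,
    min_cv_fraction: float = 0.5,
    min_peakscore: float = 2.0,
    max_p: float = 0.01,
) -> list[Peak]:
    """The DEP filter cascade producing the final DMR list.

    A peak is kept iff
      (i)  max over groups of its within-peak median log2(MeDIP/Input)
           ≥ min_median_ratio, and its median M′ is nonzero (the sign
           assigns the hyper/hypo direction);
      (ii) at least min_cv_fraction of its member probes have CV ≤ max_cv
           in BOTH groups;
      and PeakScore ≥ min_peakscore and combined P ≤ max_p.
    """
    out = []
    for pk in peaks:
        if max(pk.median_ratio_control, pk.median_ratio_treated) < min_median_ratio:
            continue
        if pk.median_mprime == 0.0:
            continue
        cv_pass = (np.asarray(pk.cv_control) <= max_cv) & (
            np.asarray(pk.cv_treated) <= max_cv
        )
        if cv_pass.mean() < min_cv_fraction:
            continue
        if pk.peak_score < min_peakscore or pk.peak_p > max_p:
            continue
        out.append(replace(pk, direction=HYPER if pk.median_mprime > 0 else HYPO))
    return out


DMR_COLUMNS = [
    "CHR",
    "START",
    "END",
    "GENE_ID",
    "DIRECTION",
    "MEDIAN_RATIO_CONTROL",
    "MEDIAN_RATIO_TREATED",
    "MEDIAN_MPRIME",
    "PEAK_SCORE",
    "PEAK_P",
    "N_PROBES",
]


def dmr_frame(dmrs: list[Peak]) -> pd.DataFrame:
    rows = [
        (
            d.chrom,
            d.start,
            d.end,
            d.gene_id,
            d.direction,
            d.median_ratio_control,
            d.median_ratio_treated,
            d.median_mprime,
            d.peak_score,
            d.peak_p,
            d.n_probes,
        )
        for d in dmrs
    ]
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def write_dmr_table(
    dmrs: list[Peak], tsv_path: str | os.PathLike, bed_path: str | os.PathLike | None = None
) -> pd.DataFrame:
    """Write the DMR table as TSV (and optionally BED6).

    BED score is min(1000, round(100×PeakScore)); strand is '.'. The TSV
    header records that no peak-level multiple-testing correction applies.
    """
    df = dmr_frame(dmrs)
    with open(tsv_path, "w") as fh:
        fh.write("# DMR table; peak P values are Fisher-combined probe p-values, "
                 "uncorrected across peaks\n")
        df.to_csv(fh, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for d in dmrs:
                score = min(1000, round(100 * d.peak_score))
                fh.write(
                    f"{d.chrom}\t{d.start}\t{d.end}\t{d.gene_id}|{d.direction}\t{score}\t.\n"
                )
    return df


def read_dmr_table(tsv_path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"CHR": str, "GENE_ID": str})
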