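import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mediptile as mt
from mediptile.dmr import probe_pvalues

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def arrays_from_tables(tables: dict[str, pd.DataFrame]) -> list[mt.LogRatioArray]:
    """Turn simulate_intensities output into LogRatioArrays (no normalization)."""
    return [
        mt.log_ratio_array(df, array_id=key, group=key.split("_")[0], replicate=int(key[-1]))
        for key, df in tables.items()
    ]


def split_groups(arrays):
    return (
        [a for a in arrays if a.group == "control"],
        [a for a in arrays if a.group == "treated"],
    )


def run_experiment(cfg: mt.SimConfig):
    """Simulate and call one experiment; returns (dmrs, truth, stats)."""
    layout = mt.generate_annotation(cfg)
    tables, truth = mt.simulate_intensities(cfg, layout)
    control, treated = split_groups(arrays_from_tables(tables))
    stats = mt.compute_probe_stats(control, treated)
    peaks = mt.find_peaks(stats)
    return mt.filter_deps(peaks), truth, stats


def stats_from_ratios(ratio_sets: dict[str, np.ndarray], positions, gene_ids):
    """Build ProbeStats directly from per-array log2-ratio vectors.

    ``ratio_sets`` maps array ids like control_rep1 to vectors aligned with
    ``positions``/``gene_ids``; handy for hand-built noiseless fixtures.
    """
    n = len(positions)
    arrays = []
    for key, vals in ratio_sets.items():
        probes = pd.DataFrame(
            {
                "CHR": "chr1",
                "POSITION": positions,
                "GENE_ID": gene_ids,
                "LOG2_RATIO": np.asarray(vals, dtype=float),
            },
            index=pd.Index([f"P{i:03d}" for i in range(n)], name="PROBE_ID"),
        )
        arrays.append(
            mt.LogRatioArray(key, key.split("_")[0], int(key[-1]), probes)
        )
    return mt.compute_probe_stats(*split_groups(arrays))


def brute_force_peaks(stats, window_bp=750.0, min_probes=2, cutoff=0.1, merge_gap=500.0):
    """Independent enumeration oracle for the sliding-window run logic.

    Checks every contiguous probe interval of each promoter for the
    qualifying property (all probes pass, one direction, >= min_probes),
    keeps the maximal ones, then merges across small gaps — returning
    member probe-id lists for comparison with find_peaks.
    """
    p, direction = probe_pvalues(stats, window_bp=window_bp)
    table = stats.table
    out = []
    for gene, idx in table.groupby("GENE_ID", sort=False).indices.items():
        idx = np.sort(idx)
        pos = table["POSITION"].to_numpy()[idx]
        ids = table.index.to_numpy()[idx]
        k = len(idx)

        def qualifies(i, j):
            sel = idx[i : j + 1]
            return bool(
                np.all(p[sel] <= cutoff)
                and len(set(direction[sel])) == 1
                and direction[sel[0]] != 0
                and (j - i + 1) >= min_probes
                and (j == i or np.all(np.diff(pos[i : j + 1]) <= merge_gap))
            )

        intervals = [(i, j) for i in range(k) for j in range(i, k) if qualifies(i, j)]
        maximal = [
            (i, j)
            for (i, j) in intervals
            if not any(
                (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in intervals
            )
        ]
        maximal.sort()
        merged: list[list[int]] = []
        for i, j in maximal:
            if (
                merged
                and pos[i] - pos[merged[-1][-1]] <= merge_gap
                and direction[idx[i]] == direction[idx[merged[-1][0]]]
            ):
                merged[-1].extend(range(i, j + 1))
            else:
                merged.append(list(range(i, j + 1)))
        for block in merged:
            lo, hi = min(block), max(block)
            out.append((gene, [str(x) for x in ids[lo : hi + 1]]))
    return out


@pytest.fixture(scope="session")
def small_experiment():
    """One modest experiment with spikes, shared across read-only tests."""
    cfg = mt.SimConfig(n_promoters=300, seed=11)
    layout = mt.generate_annotation(cfg)
    tables, truth = mt.simulate_intensities(cfg, layout)
    control, treated = split_groups(arrays_from_tables(tables))
    stats = mt.compute_probe_stats(control, treated)
    return cfg, layout, tables, truth, stats
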