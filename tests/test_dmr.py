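import numpy as np
import pandas as pd
import pytest

import mediptile as mt
from mediptile.dmr import HYPER, HYPO, Peak, dmr_frame

from .conftest import (
    arrays_from_tables,
    brute_force_peaks,
    run_experiment,
    split_groups,
    stats_from_ratios,
)


def constant_ratio_stats(treated_vals, control_vals, n_probes=4):
    """One promoter, n probes, constant per-replicate ratios for all probes."""
    positions = 1000 + 100 * np.arange(n_probes)
    genes = ["gX"] * n_probes
    sets = {}
    for i, v in enumerate(control_vals, 1):
        sets[f"control_rep{i}"] = np.full(n_probes, float(v))
    for i, v in enumerate(treated_vals, 1):
        sets[f"treated_rep{i}"] = np.full(n_probes, float(v))
    return stats_from_ratios(sets, positions, genes)


class TestProbeStats:
    def test_constant_replicates(self):
        stats = constant_ratio_stats((1.2, 1.2, 1.2), (0.4, 0.4, 0.4))
        assert stats.table["MPRIME"].to_numpy() == pytest.approx(0.8)
        assert stats.table["CV_CONTROL"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert stats.table["CV_TREATED"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_give_zero_mprime(self):
        stats = constant_ratio_stats((0.7, 0.9, 1.1), (0.7, 0.9, 1.1))
        assert stats.table["MPRIME"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_linear_scale_cv(self):
        # treated log2 ratios (1.0, 1.5, 2.0) -> linear {2, 2.83, 4};
        # control (0.0, 0.5, 1.0) -> {1, 1.41, 2}; sd/mean = 0.3414745 both
        stats = constant_ratio_stats((1.0, 1.5, 2.0), (0.0, 0.5, 1.0))
        assert stats.table["MPRIME"].to_numpy() == pytest.approx(1.0)
        assert stats.table["CV_TREATED"].to_numpy() == pytest.approx(0.3414745, abs=1e-6)
        assert stats.table["CV_CONTROL"].to_numpy() == pytest.approx(0.3414745, abs=1e-6)

    def test_probe_set_mismatch_rejected(self, small_experiment):
        *_, stats = small_experiment
        cfg = mt.SimConfig(n_promoters=10, seed=3)
        tables, _ = mt.simulate_intensities(cfg, mt.generate_annotation(cfg))
        arrays = arrays_from_tables(tables)
        control, treated = split_groups(arrays)
        control2 = [control[0], control[1], treated[0]]
        bad = control2[0].probes.iloc[:-1]
        control2[0] = mt.LogRatioArray("x", "control", 1, bad)
        with pytest.raises(ValueError, match="mismatch"):
            mt.compute_probe_stats(control2, treated)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicate"):
            constant_ratio_stats((1.0,), (0.0,))


def spiked_fixture(spiked_probe_idx, gap_positions=None, n_null=20):
    """Noiseless multi-promoter fixture: promoter gX with chosen probes
    spiked (treated ratio 1, others 0) among n_null flat promoters."""
    positions, genes, spike = [], [], []
    if gap_positions is None:
        gap_positions = 1000 + 225 * np.arange(8)
    for j, p in enumerate(gap_positions):
        positions.append(p)
        genes.append("gX")
        spike.append(j in spiked_probe_idx)
    for g in range(n_null):
        for j in range(8):
            positions.append(1_000_000 + 10_000 * g + 225 * j)
            genes.append(f"n{g}")
            spike.append(False)
    spike = np.array(spike, dtype=float)
    sets = {}
    for i in (1, 2, 3):
        sets[f"control_rep{i}"] = np.zeros(len(positions))
        sets[f"treated_rep{i}"] = spike.copy()
    return stats_from_ratios(sets, np.array(positions), genes)


class TestFindPeaks:
    def test_flat_profile_no_peaks(self):
        stats = spiked_fixture(set())
        assert mt.find_peaks(stats) == []

    def test_middle_spike_recovers_exact_run(self):
        stats = spiked_fixture({2, 3, 4, 5})
        peaks = mt.find_peaks(stats)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.gene_id == "gX"
        member_idx = sorted(int(p[-3:]) for p in pk.probe_ids)
        assert member_idx == [2, 3, 4, 5]
        assert pk.direction == HYPER
        assert pk.median_mprime == pytest.approx(1.0)

    @pytest.mark.parametrize("gap,expected_peaks", [(600, 2), (400, 1)])
    def test_merge_gap_controls_run_fusion(self, gap, expected_peaks):
        # two 2-probe spiked runs separated by `gap` bp with no probe between
        pos = np.array([1000, 1100, 1100 + gap, 1200 + gap])
        stats = spiked_fixture({0, 1, 2, 3}, gap_positions=pos)
        peaks = [p for p in mt.find_peaks(stats) if p.gene_id == "gX"]
        assert len(peaks) == expected_peaks

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n_prom = 4
            positions, genes = [], []
            for g in range(n_prom):
                k = rng.integers(2, 13)
                positions.extend(100_000 * g + 1000 + 150 * np.arange(k))
                genes.extend([f"g{g}"] * k)
            sets = {
                f"{grp}_rep{i}": rng.normal(0, 0.5, len(positions))
                for grp in ("control", "treated")
                for i in (1, 2, 3)
            }
            stats = stats_from_ratios(sets, np.array(positions), genes)
            got = sorted(
                (p.gene_id, sorted(p.probe_ids)) for p in mt.find_peaks(stats)
            )
            expected = sorted(
                (g, sorted(ids)) for g, ids in brute_force_peaks(stats)
            )
            assert got == expected

    def test_unsorted_input_rejected(self, small_experiment):
        *_, stats = small_experiment
        shuffled = mt.ProbeStats(table=stats.table.iloc[::-1], diffs=stats.diffs[::-1])
        with pytest.raises(ValueError, match="sorted"):
            mt.find_peaks(shuffled)


def make_peak(**overrides) -> Peak:
    base = dict(
        chrom="chr1",
        start=1000,
        end=2000,
        gene_id="gX",
        probe_ids=["a", "b", "c", "d"],
        median_ratio_control=0.1,
        median_ratio_treated=0.5,
        median_mprime=0.4,
        peak_p=0.001,
        peak_score=3.5,
        cv_control=np.full(4, 0.1),
        cv_treated=np.full(4, 0.1),
    )
    base.update(overrides)
    return Peak(**base)


class TestFilterDeps:
    def test_textbook_accept(self):
        out = mt.filter_deps([make_peak()])
        assert len(out) == 1 and out[0].direction == HYPER

    def test_median_ratio_threshold(self):
        low = make_peak(median_ratio_control=0.2, median_ratio_treated=0.2)
        assert mt.filter_deps([low]) == []

    def test_cv_fraction_threshold(self):
        # 3 of 4 probes fail CV in the control group -> only 25% pass
        bad = make_peak(cv_control=np.array([0.1, 0.9, 0.9, 0.9]))
        assert mt.filter_deps([bad]) == []

    def test_direction_follows_median_mprime_sign(self):
        hypo = make_peak(median_mprime=-0.4)
        out = mt.filter_deps([hypo])
        assert out[0].direction == HYPO

    def test_score_and_p_thresholds(self):
        assert mt.filter_deps([make_peak(peak_score=1.5)]) == []
        assert mt.filter_deps([make_peak(peak_p=0.02)]) == []

    def test_monotone_in_thresholds(self, small_experiment):
        *_, stats = small_experiment
        peaks = mt.find_peaks(stats)
        n_default = len(mt.filter_deps(peaks))
        assert len(mt.filter_deps(peaks, min_median_ratio=0.5)) <= n_default
        assert len(mt.filter_deps(peaks, min_peakscore=3.0)) <= n_default
        assert len(mt.filter_deps(peaks, max_p=0.001)) <= n_default
        assert len(mt.filter_deps(peaks, max_cv=0.1)) <= n_default


class TestAntisymmetry:
    def test_group_swap_negates_mprime_and_flips_directions(self):
        cfg = mt.SimConfig(n_promoters=150, seed=21)
        tables, _ = mt.simulate_intensities(cfg, mt.generate_annotation(cfg))
        control, treated = split_groups(arrays_from_tables(tables))
        fwd = mt.compute_probe_stats(control, treated)
        rev = mt.compute_probe_stats(treated, control)
        np.testing.assert_allclose(
            fwd.table["MPRIME"], -rev.table["MPRIME"], atol=1e-12
        )
        d_fwd = mt.filter_deps(mt.find_peaks(fwd))
        d_rev = mt.filter_deps(mt.find_peaks(rev))
        key = lambda d: (d.chrom, d.start, d.end)
        assert sorted(map(key, d_fwd)) == sorted(map(key, d_rev))
        by_key_rev = {key(d): d for d in d_rev}
        for d in d_fwd:
            r = by_key_rev[key(d)]
            assert {d.direction, r.direction} == {HYPER, HYPO}
            assert d.peak_score == pytest.approx(r.peak_score)
            assert abs(d.median_mprime) == pytest.approx(abs(r.median_mprime))


class TestDmrTable:
    def test_empty_call_set(self, tmp_path):
        tsv, bed = tmp_path / "d.tsv", tmp_path / "d.bed"
        mt.write_dmr_table([], tsv, bed)
        df = mt.read_dmr_table(tsv)
        assert len(df) == 0 and list(df.columns) == list(dmr_frame([]).columns)
        assert bed.read_text() == ""

    def test_round_trip_single_hyper(self, tmp_path):
        dmrs = mt.filter_deps([make_peak()])
        tsv, bed = tmp_path / "d.tsv", tmp_path / "d.bed"
        written = mt.write_dmr_table(dmrs, tsv, bed)
        df = mt.read_dmr_table(tsv)
        pd.testing.assert_frame_equal(df, written)
        fields = bed.read_text().strip().split("\t")
        assert fields[3] == "gX|hyper" and fields[5] == "."
        assert int(fields[4]) == min(1000, round(100 * dmrs[0].peak_score))

    def test_spike_recovery_end_to_end(self):
        dmrs, truth, _ = run_experiment(mt.SimConfig(n_promoters=400, seed=13))
        called = {d.gene_id: d.direction for d in dmrs}
        hits = sum(1 for g, d in called.items() if truth.dmr_promoters.get(g) == d)
        assert hits / len(truth.dmr_promoters) >= 0.85
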