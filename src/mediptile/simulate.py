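"""Synthetic MeDIP-chip experiments with known ground truth.

Emulates a two-channel promoter tiling design: each promoter spans a
strand-aware TSS window (default −1300..+500 bp), tiled with evenly spaced
probes, hybridized on replicate arrays for a control and a treated group.
A configurable fraction of promoters carries a spiked group-level
methylation difference (hyper or hypo in the treated group); the generator
records every spike, so downstream calls can be scored for sensitivity and
precision.

Intensity model: each probe has a fixed affinity baseline (drawn once per
probe) shared by both channels, so the log2(MeDIP/Input) ratio cancels it —
the reason ratio statistics are used on real two-channel arrays. Promoters
occupy one of two methylation states, as real promoters do: a majority are
unmethylated (log2 enrichment near 0) and a minority methylated (enrichment
near +1); the state is common to both groups. Spiked promoters shift their
enrichment by ±effect_size in the treated group only, in the direction the
starting state permits — methylation gain at unmethylated promoters,
loss at methylated ones (a promoter cannot lose methylation it never had).
Log-scale Gaussian noise is added independently per channel, probe and
array. Dye bias, spatial artifacts and GC-dependent affinity are not
modeled.

The default geometry (2,000 promoters × 8 probes) is a scaled-down version
of the 22,327-promoter / ~180k-probe array it emulates, so that a full
pipeline run stays under a minute; the full geometry is a config choice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cpg
from .array_io import PROBE_TABLE_COLUMNS

MOUSE_CHROMS = [f"chr{i}" for i in range(1, 20)] + ["chrX", "chrY"]

# Markov-style sequence composition per intended CpG class:
# (GC fraction of the iid draw, CpG retention factor rho)
_CLASS_PARAMS = {cpg.HCP: (0.65, 1.0), cpg.ICP: (0.50, 0.55), cpg.LCP: (0.30, 0.05)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_promoters: int = 2000
    probes_per_promoter: int = 8
    promoter_window: tuple[int, int] = (-1300, 500)  # signed offsets around TSS
    n_replicates_per_group: int = 3
    effect_size: float = 1.0  # log2 shift of the MeDIP channel in spiked promoters
    frac_dmr: float = 0.05
    noise_sd: float = 0.25  # log2-scale intensity noise sd
    cpg_class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # HCP, ICP, LCP
    seed: int = 0
    # secondary knobs of the intensity model
    baseline_log2_intensity: float = 10.0
    affinity_sd: float = 1.0
    frac_methylated: float = 0.4  # minority of promoters carry methylation
    methylated_level: float = 1.0  # log2 enrichment of the methylated state
    methylated_sd: float = 0.25
    unmethylated_sd: float = 0.1

    def validate(self) -> None:
        if self.n_promoters <= 0 or self.probes_per_promoter <= 0:
            raise ValueError("counts must be positive")
        if self.n_replicates_per_group <= 0:
            raise ValueError("need at least one replicate per group")
        if not (0.0 <= self.frac_dmr <= 1.0):
            raise ValueError("frac_dmr must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0 (direction is encoded separately)")
        if abs(sum(self.cpg_class_mix) - 1.0) > 1e-9:
            raise ValueError("cpg_class_mix must sum to 1")
        lo, hi = self.promoter_window
        if hi - lo < self.probes_per_promoter:
            raise ValueError(
                f"promoter window of {hi - lo} bp too small for "
                f"{self.probes_per_promoter} probes"
            )


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    dmr_promoters: dict[str, str] = field(default_factory=dict)  # id -> hyper|hypo
    cpg_class_truth: dict[str, str] = field(default_factory=dict)  # id -> HCP|ICP|LCP


@dataclass
class Layout:
    """Promoter annotation plus probe layout."""

    promoters: pd.DataFrame  # GENE_ID, CHR, TSS, STRAND, START, END (BED half-open)
    probes: pd.DataFrame  # PROBE_ID, CHR, POSITION (1-based), GENE_ID


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_annotation(config: SimConfig) -> Layout:
    """Promoter windows and evenly spaced probes, strand-aware.

    Plus-strand promoters span [TSS+lo, TSS+hi]; minus-strand windows are
    mirrored around the TSS, so both are upstream-heavy of their TSS.
    """
    config.validate()
    rng = _stage_rngs(config.seed, 5)[0]
    lo, hi = config.promoter_window
    length = hi - lo
    k = config.probes_per_promoter

    gene_ids, chroms, tss_list, strands = [], [], [], []
    probe_rows = []
    offsets = lo + (np.arange(k) + 0.5) * length / k  # window midpoint when k == 1
    for i in range(config.n_promoters):
        gid = f"G{i:05d}"
        chrom = MOUSE_CHROMS[i % len(MOUSE_CHROMS)]
        tss = 100_000 + (i // len(MOUSE_CHROMS)) * 50_000
        strand = "+" if rng.random() < 0.5 else "-"
        gene_ids.append(gid)
        chroms.append(chrom)
        tss_list.append(tss)
        strands.append(strand)
        sign = 1 if strand == "+" else -1
        pos = np.rint(tss + sign * offsets).astype(int)  # 1-based genomic bp
        pos = np.sort(pos)
        for j, pjs in enumerate(pos):
            probe_rows.append((f"{gid}_P{j:02d}", chrom, int(pjs), gid))

    promoters = pd.DataFrame(
        {
            "GENE_ID": gene_ids,
            "CHR": chroms,
            "TSS": tss_list,
            "STRAND": strands,
        }
    )
    sign = np.where(promoters["STRAND"] == "+", 1, -1)
    w_lo = promoters["TSS"] + np.where(sign > 0, lo, -hi)
    promoters["START"] = w_lo - 1  # BED 0-based
    promoters["END"] = promoters["START"] + length
    probes = pd.DataFrame(probe_rows, columns=["PROBE_ID", "CHR", "POSITION", "GENE_ID"])
    probes = probes.sort_values(["CHR", "POSITION", "PROBE_ID"], kind="mergesort").reset_index(
        drop=True
    )
    return Layout(promoters=promoters, probes=probes)


def _draw_sequence(rng: np.random.Generator, length: int, gc: float, rho: float) -> str:
    """IID draw at the target GC, then thin CpG dinucleotides to ~rho."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    s = rng.choice(bases, size=length, p=p)
    if rho < 1.0:
        is_cg = (s[:-1] == ord("C")) & (s[1:] == ord("G"))
        hit = np.flatnonzero(is_cg)
        kill = hit[rng.random(len(hit)) >= rho]
        # replace the G with A or T so no new CpG can arise
        s[kill + 1] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=len(kill))
    return s.tobytes().decode("ascii")


def generate_sequences(config: SimConfig, layout: Layout, truth: TruthSet | None = None):
    """Promoter sequences engineered per intended CpG class.

    Classes are assigned from cpg_class_mix; intent is recorded in the
    returned TruthSet. Yields a list of (promoter_id, sequence).
    """
    config.validate()
    rng = _stage_rngs(config.seed, 5)[1]
    if truth is None:
        truth = TruthSet()
    lo, hi = config.promoter_window
    length = hi - lo
    classes = rng.choice(
        [cpg.HCP, cpg.ICP, cpg.LCP], size=config.n_promoters, p=list(config.cpg_class_mix)
    )
    records = []
    for gid, cls in zip(layout.promoters["GENE_ID"], classes):
        gc, rho = _CLASS_PARAMS[cls]
        records.append((gid, _draw_sequence(rng, length, gc, rho)))
        truth.cpg_class_truth[gid] = cls
    return records, truth


def simulate_intensities(
    config: SimConfig, layout: Layout, truth: TruthSet | None = None
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Two-channel probe tables for every array, plus the spike truth.

    Returns {array_id: probe table} with array ids like ``control_rep1``;
    spiked promoters (fraction frac_dmr) shift every probe of the promoter
    by ±effect_size in the treated group's MeDIP channel. Hyper spikes are
    placed at unmethylated promoters (gain of methylation) and hypo spikes
    at methylated ones (loss), the only directions the starting states
    admit.
    """
    config.validate()
    rng = _stage_rngs(config.seed, 5)[2]
    if truth is None:
        truth = TruthSet()

    probes = layout.probes
    n_probes = len(probes)
    gene_ids = layout.promoters["GENE_ID"].to_numpy()

    methylated = rng.random(len(gene_ids)) < config.frac_methylated
    n_spike = int(round(config.frac_dmr * config.n_promoters))
    n_hypo = min(n_spike // 2, int(methylated.sum()))
    n_hyper = min(n_spike - n_hypo, int((~methylated).sum()))
    hypo = rng.choice(gene_ids[methylated], size=n_hypo, replace=False)
    hyper = rng.choice(gene_ids[~methylated], size=n_hyper, replace=False)
    truth.dmr_promoters.update({g: "hypo" for g in hypo})
    truth.dmr_promoters.update({g: "hyper" for g in hyper})

    affinity = config.baseline_log2_intensity + config.affinity_sd * rng.standard_normal(
        n_probes
    )
    level = np.where(methylated, config.methylated_level, 0.0)
    sd = np.where(methylated, config.methylated_sd, config.unmethylated_sd)
    meth = level + sd * rng.standard_normal(len(gene_ids))
    meth_by_gene = dict(zip(gene_ids, meth))
    probe_meth = probes["GENE_ID"].map(meth_by_gene).to_numpy()
    delta = probes["GENE_ID"].map(
        {g: (config.effect_size if d == "hyper" else -config.effect_size)
         for g, d in truth.dmr_promoters.items()}
    ).fillna(0.0).to_numpy()

    tables: dict[str, pd.DataFrame] = {}
    for group in ("control", "treated"):
        shift = delta if group == "treated" else 0.0
        for rep in range(1, config.n_replicates_per_group + 1):
            eps_in = config.noise_sd * rng.standard_normal(n_probes)
            eps_ip = config.noise_sd * rng.standard_normal(n_probes)
            table = probes.copy()
            table["MEDIP_SIGNAL"] = np.power(2.0, affinity + probe_meth + shift + eps_ip)
            table["INPUT_SIGNAL"] = np.power(2.0, affinity + eps_in)
            tables[f"{group}_rep{rep}"] = table[PROBE_TABLE_COLUMNS]
    return tables, truth


def generate_qpcr(
    delta_ct_means: dict[tuple[str, str], float],
    n_per_cell: int = 8,
    noise_sd: float = 0.25,
    ct_reference_mean: float = 18.0,
    gene: str = "Acaa2",
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Balanced 2×2 qPCR Ct table (maternal diet × offspring diet).

    ``delta_ct_means`` maps (maternal_diet, offspring_diet) cells — e.g.
    ("NC", "CD") — to the cell's mean ΔCt = Ct(target) − Ct(reference);
    per-sample ΔCt is Gaussian around the cell mean with sd ``noise_sd``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    i = 0
    for (mat, off), mu in delta_ct_means.items():
        for _ in range(n_per_cell):
            ct_ref = ct_reference_mean + noise_sd * rng.standard_normal()
            dct = mu + noise_sd * rng.standard_normal()
            rows.append((f"S{i:03d}", mat, off, gene, ct_ref + dct, ct_ref))
            i += 1
    return pd.DataFrame(
        rows,
        columns=["sample", "maternal_diet", "offspring_diet", "gene", "ct_target", "ct_reference"],
    )


def generate_gene_sets(
    layout: Layout,
    truth: TruthSet,
    n_sets: int = 20,
    set_size: int = 50,
    n_enriched: int = 2,
    enriched_frac: float = 0.5,
    rng: np.random.Generator | int | None = 0,
) -> dict[str, list[str]]:
    """Gene sets over the array's promoters, some enriched for spiked genes.

    The first ``n_enriched`` sets draw ``enriched_frac`` of their members
    from the spiked (true DMR) promoters; the rest are uniform draws.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genes = layout.promoters["GENE_ID"].to_numpy()
    dmr = np.array(sorted(truth.dmr_promoters))
    other = np.array(sorted(set(genes) - set(dmr)))
    set_size = min(set_size, len(genes))
    sets = {}
    for i in range(n_sets):
        if i < n_enriched and len(dmr) > 0:
            k_dmr = min(int(round(enriched_frac * set_size)), len(dmr))
            n_other = min(set_size - k_dmr, len(other))
            members = np.concatenate(
                [
                    rng.choice(dmr, size=k_dmr, replace=False),
                    rng.choice(other, size=n_other, replace=False),
                ]
            )
        else:
            members = rng.choice(genes, size=set_size, replace=False)
        sets[f"SET{i:02d}"] = sorted(members)
    return sets


# ---------------------------------------------------------------------------
# file writers (plain-text formats only)

def write_experiment(config: SimConfig, outdir: str | os.PathLike) -> TruthSet:
    """Generate and write a complete experiment to ``outdir``.

    Files: promoters.bed (BED6 windows), truth_dmrs.bed (direction in the
    name field), promoters.fa, per-array probe tables, gene_sets.gmt,
    qpcr.csv and truth_classes.tsv. Identical config (incl. seed) yields
    byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    layout = generate_annotation(config)
    records, truth = generate_sequences(config, layout)
    tables, truth = simulate_intensities(config, layout, truth)

    prom = layout.promoters
    with open(os.path.join(outdir, "promoters.bed"), "w") as fh:
        for r in prom.itertuples():
            fh.write(f"{r.CHR}\t{r.START}\t{r.END}\t{r.GENE_ID}\t0\t{r.STRAND}\n")
    with open(os.path.join(outdir, "truth_dmrs.bed"), "w") as fh:
        for r in prom.itertuples():
            if r.GENE_ID in truth.dmr_promoters:
                d = truth.dmr_promoters[r.GENE_ID]
                fh.write(f"{r.CHR}\t{r.START}\t{r.END}\t{r.GENE_ID}|{d}\t0\t{r.STRAND}\n")
    with open(os.path.join(outdir, "promoters.fa"), "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(os.path.join(outdir, "truth_classes.tsv"), "w") as fh:
        fh.write("PROMOTER_ID\tCLASS\n")
        for pid, cls in truth.cpg_class_truth.items():
            fh.write(f"{pid}\t{cls}\n")
    for array_id, table in tables.items():
        table.to_csv(os.path.join(outdir, f"{array_id}.probes.tsv"), sep="\t", index=False)

    qpcr_rng, gmt_rng = _stage_rngs(config.seed, 5)[3:5]
    sets = generate_gene_sets(layout, truth, rng=gmt_rng)
    with open(os.path.join(outdir, "gene_sets.gmt"), "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\tsynthetic set\t" + "\t".join(members) + "\n")
    qpcr = generate_qpcr(
        {("NC", "CD"): 6.0, ("NC", "HFD"): 6.3, ("DIO", "CD"): 7.0, ("DIO", "HFD"): 7.3},
        rng=qpcr_rng,
    )
    qpcr.to_csv(os.path.join(outdir, "qpcr.csv"), index=False)
    return truth
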