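"""One-command orchestration: simulate → normalize → call → classify →
summarize → enrich → qpcr, driven by a single YAML-serializable config.

Every stage writes plain-text outputs under the run directory and a JSON
manifest records the config hash and per-stage row counts, so identical
config + seed reproduces byte-identical results and an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import array_io, cpg, dmr, enrichment, qpcr, simulate

log = logging.getLogger("mediptile")

STAGES = ("simulate", "normalize", "call", "classify", "summarize", "enrich", "qpcr")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the published thresholds."""

    outdir: str = "medip_run"
    seed: int = 0
    # synthetic experiment
    n_promoters: int = 2000
    probes_per_promoter: int = 8
    n_replicates_per_group: int = 3
    effect_size: float = 1.0
    frac_dmr: float = 0.05
    noise_sd: float = 0.25
    # normalization
    normalization: str = "none"  # synthetic ratios are already on one scale
    # peak finding
    window_bp: float = 750.0
    min_probes: int = 2
    probe_p_cutoff: float = 0.1
    merge_gap: float = 500.0
    # DEP filter
    min_median_ratio: float = 0.3
    max_cv: float = 0.8
    min_cv_fraction: float = 0.5
    min_peakscore: float = 2.0
    max_p: float = 0.01
    # enrichment
    gmt_kind: str = "pathway"
    # qPCR
    qpcr_reference: tuple[str, str] = ("NC", "CD")
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "qpcr_reference" in d:
            d["qpcr_reference"] = tuple(d["qpcr_reference"])
        return cls(**d)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["qpcr_reference"] = list(self.qpcr_reference)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}': {msg}")
        self.stage = stage


def _need(stage: str, path: str) -> str:
    if not os.path.exists(path):
        raise StageError(
            stage, f"required input {path} is missing — was its producing stage disabled?"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    simdir = os.path.join(config.outdir, "sim")
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.as_dict(),
        "stages": {},
    }
    counts = manifest["stages"]

    sim_config = simulate.SimConfig(
        n_promoters=config.n_promoters,
        probes_per_promoter=config.probes_per_promoter,
        n_replicates_per_group=config.n_replicates_per_group,
        effect_size=config.effect_size,
        frac_dmr=config.frac_dmr,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )

    if config.stages.get("simulate", True):
        truth = simulate.write_experiment(sim_config, simdir)
        counts["simulate"] = {
            "promoters": config.n_promoters,
            "probes": config.n_promoters * config.probes_per_promoter,
            "arrays": 2 * config.n_replicates_per_group,
            "spiked": len(truth.dmr_promoters),
        }
        log.info("simulate: %s", counts["simulate"])

    arrays = None
    if config.stages.get("normalize", True):
        paths = []
        for group in ("control", "treated"):
            for rep in range(1, config.n_replicates_per_group + 1):
                p = _need("normalize", os.path.join(simdir, f"{group}_rep{rep}.probes.tsv"))
                paths.append((p, group, rep))
        arrays = array_io.load_arrays(paths, method=config.normalization)
        ratios = pd.concat(
            {a.array_id: a.probes["LOG2_RATIO"] for a in arrays}, axis=1
        )
        ratios.to_csv(os.path.join(config.outdir, "ratios.tsv"), sep="\t")
        counts["normalize"] = {"arrays": len(arrays), "probes": len(arrays[0].probes)}
        log.info("normalize: %s", counts["normalize"])

    dmrs_path = os.path.join(config.outdir, "dmrs.tsv")
    if config.stages.get("call", True):
        if arrays is None:
            raise StageError("call", "normalized arrays unavailable (normalize disabled?)")
        stats = dmr.compute_probe_stats(
            [a for a in arrays if a.group == "control"],
            [a for a in arrays if a.group == "treated"],
        )
        peaks = dmr.find_peaks(
            stats,
            window_bp=config.window_bp,
            min_probes=config.min_probes,
            probe_p_cutoff=config.probe_p_cutoff,
            merge_gap=config.merge_gap,
        )
        dmrs = dmr.filter_deps(
            peaks,
            min_median_ratio=config.min_median_ratio,
            max_cv=config.max_cv,
            min_cv_fraction=config.min_cv_fraction,
            min_peakscore=config.min_peakscore,
            max_p=config.max_p,
        )
        dmr.write_dmr_table(dmrs, dmrs_path, os.path.join(config.outdir, "dmrs.bed"))
        counts["call"] = {"peaks": len(peaks), "dmrs": len(dmrs)}
        log.info("call: %s", counts["call"])

    classes_path = os.path.join(config.outdir, "classes.tsv")
    if config.stages.get("classify", True):
        from Bio import SeqIO

        fasta = _need("classify", os.path.join(simdir, "promoters.fa"))
        classes = cpg.classify_fasta(SeqIO.parse(fasta, "fasta"))
        classes.to_csv(classes_path, sep="\t", index=False)
        counts["classify"] = classes["CLASS"].value_counts().to_dict()
        log.info("classify: %s", counts["classify"])

    if config.stages.get("summarize", True):
        dmrs_df = dmr.read_dmr_table(_need("summarize", dmrs_path))
        classes = pd.read_csv(_need("summarize", classes_path), sep="\t")
        report = cpg.summarize_dmrs(dmrs_df, classes)
        report.to_frame().to_csv(os.path.join(config.outdir, "composition.tsv"), sep="\t", index=False)
        counts["summarize"] = {"total_dmrs": report.total}
        log.info("summarize: %s", counts["summarize"])

    if config.stages.get("enrich", True):
        dmrs_df = dmr.read_dmr_table(_need("enrich", dmrs_path))
        gmt = enrichment.read_gmt(_need("enrich", os.path.join(simdir, "gene_sets.gmt")))
        prom = pd.read_csv(
            _need("enrich", os.path.join(simdir, "promoters.bed")),
            sep="\t",
            header=None,
            names=["CHR", "START", "END", "GENE_ID", "SCORE", "STRAND"],
        )
        coll = enrichment.make_collection(gmt, set(prom["GENE_ID"]), kind=config.gmt_kind)
        query = set(dmrs_df["GENE_ID"])
        results = enrichment.run_enrichment(query, coll)
        enrichment.write_enrichment_table(results, os.path.join(config.outdir, "enrichment.tsv"))
        counts["enrich"] = {
            "sets": len(results),
            "significant": int(results["SIGNIFICANT"].sum()),
            "query_genes": len(query),
        }
        log.info("enrich: %s", counts["enrich"])

    if config.stages.get("qpcr", True):
        table = pd.read_csv(_need("qpcr", os.path.join(simdir, "qpcr.csv")))
        reports = qpcr.expression_report(table, reference_group=config.qpcr_reference)
        rows = []
        for gene, rep in reports.items():
            a = rep["anova"]
            folds = rep["folds"]
            cellmeans = folds.groupby(["maternal_diet", "offspring_diet"])["FOLD"].mean()
            rows.append(
                {
                    "gene": gene,
                    **{f"fold_{m}_{o}": v for (m, o), v in cellmeans.items()},
                    **{
                        f"p_{eff}": a.loc[eff, "PR(>F)"]
                        for eff in a.index
                        if eff != "Residual"
                    },
                }
            )
        pd.DataFrame(rows).to_csv(os.path.join(config.outdir, "qpcr_report.tsv"), sep="\t", index=False)
        counts["qpcr"] = {"genes": len(reports), "samples": len(table)}
        log.info("qpcr: %s", counts["qpcr"])

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
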