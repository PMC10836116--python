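"""End-to-end orchestration: simulate -> preprocess -> call-pas -> annotate
-> rhythm (24 h and 12 h) -> diffexp -> ora, with a reproducibility manifest.

A single :class:`PipelineConfig` (YAML-serializable) carries every stage's
parameter block plus the global seed; the manifest records parameter hashes,
output checksums and row counts so two runs of the same config are
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, diffexp, enrichment, preprocess, rhythm, synthetic_data
from .pas_calling import (
    FilterParams,
    cluster_sites,
    counts_matrix,
    filter_pacs,
    normalize,
    read_sample_sheet,
    read_tags_bed,
    remove_mitochondrial,
    write_pac_bed,
    write_pac_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "apa_rhythm_out"
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    preprocess: preprocess.PreprocessParams = field(
        default_factory=preprocess.PreprocessParams
    )
    filters: FilterParams = field(default_factory=FilterParams)
    rhythm: rhythm.RhythmParams = field(default_factory=rhythm.RhythmParams)
    rhythm_on_normalized: bool = False  # raw counts feed the detectors by default
    de_p_threshold: float = 0.01
    de_lfc_threshold: float = 0.5
    ora_fdr_threshold: float = 0.05
    n_fastq_reads: int = 500

    def __post_init__(self) -> None:
        # fan the global seed out to per-stage seeds deterministically
        if isinstance(self.sim, dict):
            self.sim = synthetic_data.SimConfig(**self.sim)
        if isinstance(self.preprocess, dict):
            self.preprocess = preprocess.PreprocessParams(**self.preprocess)
        if isinstance(self.filters, dict):
            if "mito_chroms" in self.filters:
                self.filters["mito_chroms"] = frozenset(self.filters["mito_chroms"])
            self.filters = FilterParams(**self.filters)
        if isinstance(self.rhythm, dict):
            self.rhythm = rhythm.RhythmParams(**self.rhythm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"]["mito_chroms"] = sorted(d["filters"]["mito_chroms"])
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def param_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # io location must not affect the hash
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest (also written
    to ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path, rows: int | None = None) -> None:
        manifest["outputs"][path.name] = {
            "sha256": _sha256(path),
            **({"rows": rows} if rows is not None else {}),
        }
        manifest["stages"].setdefault(stage, []).append(path.name)

    def run_stage(stage: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- simulate ----------------------------------------------------------
    sim = dataclasses.replace(config.sim, seed=config.seed)
    genes, truth = run_stage("simulate", synthetic_data.simulate_genome, sim)
    samples = synthetic_data.full_design(seed=config.seed)
    counts = synthetic_data.simulate_counts(sim, samples, truth)
    tags = synthetic_data.simulate_tags(sim, truth, counts)

    gtf = out / "genes.gtf"
    synthetic_data.write_gtf(genes, str(gtf))
    truth_path = out / "truth.tsv"
    synthetic_data.write_truth(truth, str(truth_path))
    sheet = out / "samples.tsv"
    synthetic_data.write_sample_sheet(samples, str(sheet))
    bed = out / "tags.bed"
    synthetic_data.write_tags_bed(tags, str(bed))
    fastq = out / "reads.fastq"
    read_truth = synthetic_data.simulate_fastq(sim, str(fastq), config.n_fastq_reads)
    read_truth_path = out / "read_truth.tsv"
    read_truth.to_csv(read_truth_path, sep="\t", index=False)
    for p, n in (
        (gtf, len(genes)),
        (truth_path, len(truth)),
        (sheet, len(samples)),
        (bed, len(tags)),
        (fastq, config.n_fastq_reads),
        (read_truth_path, len(read_truth)),
    ):
        record("simulate", p, n)
    logger.info("simulate: %d genes, %d PASs, %d tags", len(genes), len(truth), len(tags))

    # ---- preprocess --------------------------------------------------------
    clean = out / "clean.fastq"
    summary = run_stage(
        "preprocess", preprocess.preprocess_fastq, str(fastq), str(clean), config.preprocess
    )
    summary_path = out / "preprocess_summary.tsv"
    preprocess.write_summary_tsv(summary, str(summary_path))
    record("preprocess", clean, summary.reads_out)
    record("preprocess", summary_path)
    logger.info("preprocess: %d -> %d reads", summary.reads_in, summary.reads_out)

    # ---- call-pas ----------------------------------------------------------
    samples = read_sample_sheet(str(sheet))
    tags_in = read_tags_bed(str(bed))
    pacs = run_stage("call-pas", cluster_sites, tags_in, config.filters)
    pacs = filter_pacs(pacs, samples, config.filters)
    pacs = remove_mitochondrial(pacs, config.filters)
    pacs = normalize(pacs, samples, config.filters)
    pac_path = out / "pacs.tsv"
    pac_df = write_pac_table(pacs, samples, str(pac_path))
    write_pac_bed(pacs, str(out / "pacs.bed"))
    record("call-pas", pac_path, len(pacs))
    record("call-pas", out / "pacs.bed", len(pacs))
    logger.info(
        "call-pas: %d PACs retained (window=%d, cutoff=%d)",
        len(pacs), config.filters.cluster_window_nt, config.filters.lib_size_cutoff,
    )

    # ---- annotate ----------------------------------------------------------
    genes_in = annotation.read_gtf(str(gtf))
    annots = run_stage("annotate", annotation.annotate_pacs, pacs, genes_in)
    annot_path = out / "annotations.tsv"
    annotation.write_annotation_tsv(annots, str(annot_path))
    record("annotate", annot_path, len(annots))
    stats_path = out / "apa_stats.json"
    st = annotation.apa_stats(annots)
    stats_path.write_text(
        json.dumps(
            {
                "mean_per_gene": st["mean_per_gene"],
                "histogram": {str(k): int(v) for k, v in st["histogram"].items()},
                "frac_genes_ge": {str(k): v for k, v in st["frac_genes_ge"].items()},
            },
            indent=2,
            sort_keys=True,
        )
    )
    record("annotate", stats_path)

    # ---- rhythm ------------------------------------------------------------
    kind = "norm" if config.rhythm_on_normalized else "count"
    matrix = counts_matrix(pac_df, kind)
    circ = [s for s in samples if s.condition in rhythm.CIRCADIAN_CONDITIONS]
    circ_ids = [s.sample_id for s in circ]
    rhythm_results = {}
    for period in (24.0, 12.0):
        res = run_stage(
            "rhythm", rhythm.consensus_rhythm, matrix[circ_ids], circ, period, config.rhythm
        )
        path = out / f"rhythm{int(period)}.tsv"
        rhythm.write_rhythm_tsv(res, str(path))
        record("rhythm", path, len(res))
        rhythm_results[period] = res
        logger.info(
            "rhythm %gh: %d consensus PACs (alpha=%g, scheme=%s)",
            period, int(res["consensus"].sum()), config.rhythm.alpha, config.rhythm.scheme,
        )
    bins = rhythm.phase_bin(rhythm_results[24.0])
    bins_path = out / "phase_bins.tsv"
    with open(bins_path, "w") as fh:
        fh.write("# 5-h sliding windows on the 24-h circle; centers in ZT hours\n")
        fh.write("center_h\tpac_id\n")
        for center, members in sorted(bins.items()):
            for pid in members:
                fh.write(f"{center:g}\t{pid}\n")
    record("rhythm", bins_path)

    # ---- diffexp -----------------------------------------------------------
    pac_gene = {a.pac_id: a.gene_id for a in annots if a.gene_id != annotation.INTERGENIC}
    multi = annotation.multi_apa_gene_set(annots)
    raw = counts_matrix(pac_df, "count")
    de = run_stage(
        "diffexp",
        diffexp.run_contrasts,
        raw,
        samples,
        diffexp.DEFAULT_CONTRASTS,
        config.de_p_threshold,
        config.de_lfc_threshold,
        multi,
        pac_gene,
    )
    de_path = out / "diffexp.tsv"
    with open(de_path, "w") as fh:
        fh.write("# log2fc on log2 scale; p two-sided NB Wald; lfdr empirical-null local FDR\n")
        de.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    record("diffexp", de_path, len(de))
    logger.info(
        "diffexp: %d significant PAC/contrast pairs (p<%g, |lfc|>%g)",
        int(de["significant"].sum()), config.de_p_threshold, config.de_lfc_threshold,
    )

    # ---- ora ---------------------------------------------------------------
    universe = set(pac_gene.values())
    query = {
        pac_gene[pid]
        for pid in rhythm_results[24.0].loc[rhythm_results[24.0]["consensus"], "pac_id"]
        if pid in pac_gene and pac_gene[pid] in multi
    }
    ora_path = out / "ora.tsv"
    if universe and query:
        rng = np.random.default_rng(config.seed + 1)
        uni = sorted(universe)
        sets = {
            f"SET{k:02d}": set(rng.choice(uni, size=max(3, len(uni) // 10), replace=False))
            for k in range(10)
        }
        collection = enrichment.GeneSetCollection(sets, universe)
        ora = run_stage(
            "ora", enrichment.hypergeom_ora, query, collection, config.ora_fdr_threshold
        )
        ora.to_csv(ora_path, sep="\t", index=False, float_format="%.6g")
    else:
        pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "enrichment_ratio", "p", "fdr", "passes"]
        ).to_csv(ora_path, sep="\t", index=False)
    record("ora", ora_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
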