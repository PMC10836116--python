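"""Ground-truthed synthetic inputs for every pipeline stage.

Simulates (a) a single-chromosome genome of non-overlapping multi-PAS genes
with region-classified cleavage sites, (b) NB-distributed count matrices
with planted 24 h / 12 h cosinor rhythms and multiplicative
sleep-deprivation effects, (c) per-read tag alignments with Gaussian
position jitter, and (d) FASTQ reads with 5' T-rich artifact prefixes and a
low-quality read class.  A truth table links every simulated PAS to its
generating parameters so downstream recovery can be scored exactly.

All outputs are a deterministic function of ``SimConfig`` (the seed is
fanned out to independent per-stage streams, so stages can be rerun
individually and still reproduce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, Transcript
from .pas_calling import AlignedTag, SampleInfo

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_counts",
    "simulate_tags",
    "simulate_fastq",
    "circadian_design",
    "full_design",
    "write_gtf",
    "write_tags_bed",
    "write_sample_sheet",
]

SD_CONDITIONS = frozenset({"R0", "R2", "R4", "R8"})

# gene template (local 1-based coordinates within an 1800-nt gene body):
# exon1 [1,200], exon2 [501,700], exon3 [1001,1800]; CDS ends at 1100, so the
# 3'UTR spans [1101,1800].  Planted PAS positions per region are fixed and
# pairwise > 25 nt apart so distinct PASs can never co-cluster.
_GENE_LEN = 1800
_EXONS_LOCAL = [(1, 200), (501, 700), (1001, 1800)]
_CDS_END_LOCAL = 1100
_PAS_LOCAL = {
    "utr3_terminal": 1800,
    "utr3_internal": 1600,
    "internal_exon": 600,
    "intron": 350,
    "utr3_distal": 2300,
}
_EXTRA_REGIONS = ("utr3_internal", "internal_exon", "intron", "utr3_distal")
_GENE_PITCH = 8000


@dataclass
class SimConfig:
    """Full parameterization of the simulator; the seed determines everything."""

    seed: int = 0
    n_genes: int = 100
    pas_per_gene_probs: tuple[float, float, float, float] = (0.55, 0.26, 0.12, 0.07)
    frac_cycling_24: float = 0.1
    frac_cycling_12: float = 0.05
    rel_amplitude_range: tuple[float, float] = (0.3, 0.8)
    phase_range_h: tuple[float, float] = (0.0, 24.0)
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (20.0, 500.0)  # expected reads per 1e7
    library_sizes: list[int] = field(default_factory=list)
    sd_effect_log2fc: float = 1.0
    frac_sd_affected: float = 0.0
    tag_jitter_sd_nt: float = 0.0
    t_prefix_prob: float = 0.5
    chrom: str = "chr1"
    chrom_length_nt: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(sum(self.pas_per_gene_probs) - 1.0) > 1e-9:
            raise ValueError("pas_per_gene_probs must sum to 1")
        if self.frac_cycling_24 + self.frac_cycling_12 > 1.0 + 1e-9:
            raise ValueError("cycling fractions exceed 1")
        for name in ("rel_amplitude_range", "phase_range_h", "base_mean_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        lo, hi = self.rel_amplitude_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("relative amplitudes must lie in (0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.tag_jitter_sd_nt < 0:
            raise ValueError("tag_jitter_sd_nt must be >= 0")
        if not 0.0 <= self.t_prefix_prob <= 1.0:
            raise ValueError("t_prefix_prob must be in [0, 1]")
        needed = 2000 + self.n_genes * _GENE_PITCH
        if self.chrom_length_nt is not None and self.chrom_length_nt < needed:
            raise ValueError(
                f"chrom_length_nt={self.chrom_length_nt} too small for "
                f"{self.n_genes} genes (need >= {needed})"
            )

    def rng_for(self, stage: str) -> np.random.Generator:
        order = ("genome", "counts", "tags", "fastq", "design")
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order.index(stage)])


# ---------------------------------------------------------------------------
# designs


def circadian_design(
    library_sizes: list[int] | None = None, seed: int = 0
) -> list[SampleInfo]:
    """6 timepoints (ZT2..ZT22) x 5 replicates."""
    return _design(("ZT2", "ZT6", "ZT10", "ZT14", "ZT18", "ZT22"), library_sizes, seed)


def full_design(
    library_sizes: list[int] | None = None, seed: int = 0
) -> list[SampleInfo]:
    """Circadian design plus the SD arm (ZT8 controls and R0/R2/R4/R8), 55 samples."""
    conds = (
        "ZT2", "ZT6", "ZT10", "ZT14", "ZT18", "ZT22",
        "ZT8", "R0", "R2", "R4", "R8",
    )
    return _design(conds, library_sizes, seed)


def _design(conditions, library_sizes, seed) -> list[SampleInfo]:
    n = len(conditions) * 5
    if library_sizes is None:
        # depths straddling the 1.7M adaptive-filter cutoff
        rng = np.random.default_rng(seed)
        library_sizes = rng.integers(900_000, 3_000_000, size=n).tolist()
    if len(library_sizes) != n:
        raise ValueError(f"need {n} library sizes, got {len(library_sizes)}")
    samples = []
    k = 0
    for cond in conditions:
        for rep in range(1, 6):
            samples.append(SampleInfo(f"{cond}_r{rep}", cond, rep, int(library_sizes[k])))
            k += 1
    return samples


# ---------------------------------------------------------------------------
# genome + truth


def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out non-overlapping genes and plant region-classified PASs.

    Returns gene models and the truth table (one row per PAS: identity,
    coordinates, region, rhythm parameters, SD effect and base mean).
    """
    rng = config.rng_for("genome")
    genes: list[GeneModel] = []
    rows = []
    n_pas_draw = rng.choice(
        np.arange(1, 5), size=config.n_genes, p=np.asarray(config.pas_per_gene_probs)
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    for g in range(config.n_genes):
        start = 1001 + g * _GENE_PITCH  # 1-based slot origin
        strand = strands[g]
        gene_id = f"G{g + 1:05d}"

        def glob(local: int) -> int:
            if strand == "+":
                return start + local - 1
            return start + _GENE_LEN - local  # mirror for - strand

        exons = sorted(
            (min(glob(a), glob(b)), max(glob(a), glob(b))) for a, b in _EXONS_LOCAL
        )
        gene = GeneModel(gene_id, config.chrom, strand)
        gene.transcripts.append(
            Transcript(f"{gene_id}.t1", exons, glob(_CDS_END_LOCAL))
        )
        genes.append(gene)

        regions = ["utr3_terminal"]
        extra = int(n_pas_draw[g]) - 1
        if extra:
            regions += list(
                rng.choice(np.array(_EXTRA_REGIONS), size=extra, replace=False)
            )
        for region in regions:
            u = rng.uniform()
            if u < config.frac_cycling_24:
                period = 24
            elif u < config.frac_cycling_24 + config.frac_cycling_12:
                period = 12
            else:
                period = 0
            amp = rng.uniform(*config.rel_amplitude_range) if period else 0.0
            phase = rng.uniform(*config.phase_range_h) if period else 0.0
            sd_lfc = (
                config.sd_effect_log2fc
                if rng.uniform() < config.frac_sd_affected
                else 0.0
            )
            base = float(
                np.exp(rng.uniform(*np.log(np.asarray(config.base_mean_range))))
            )
            rows.append(
                {
                    "pas_id": f"{gene_id}:{region}",
                    "gene_id": gene_id,
                    "chrom": config.chrom,
                    "strand": strand,
                    "coord": glob(_PAS_LOCAL[region]),
                    "region": region,
                    "period": period,
                    "rel_amplitude": amp,
                    "phase_h": phase,
                    "sd_log2fc": sd_lfc,
                    "base_mean": base,
                }
            )
    truth = pd.DataFrame(rows)
    return genes, truth


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimConfig, samples: list[SampleInfo], truth: pd.DataFrame
) -> pd.DataFrame:
    """NB count matrix (PAS x sample) from the planted cosinor model.

    Expected normalized abundance q(t) = m*(1 + a*cos(2*pi*(t - phi)/T));
    the NB mean for sample s is q(t_s)*L_s/1e7, times 2**sd_log2fc for
    SD-affected PASs in recovery conditions.
    """
    from .rhythm import condition_hours

    rng = config.rng_for("counts")
    amps = truth["rel_amplitude"].to_numpy(dtype=float)
    if np.any(amps > 1.0):
        raise ValueError("relative amplitude > 1 would give a negative NB mean")
    m = truth["base_mean"].to_numpy(dtype=float)
    period = truth["period"].to_numpy(dtype=float)
    phase = truth["phase_h"].to_numpy(dtype=float)
    sd_lfc = truth["sd_log2fc"].to_numpy(dtype=float)

    mat = np.empty((len(truth), len(samples)), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, s in enumerate(samples):
        t = condition_hours(s.condition)
        with np.errstate(invalid="ignore"):
            q = np.where(
                period > 0,
                m * (1.0 + amps * np.cos(2.0 * np.pi * (t - phase) / np.where(period > 0, period, 24.0))),
                m,
            )
        if s.condition in SD_CONDITIONS:
            q = q * np.exp2(sd_lfc)
        mu = np.maximum(q * s.library_size / 1e7, 0.0)
        if alpha > 0:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            mat[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            mat[:, j] = rng.poisson(mu)
    return pd.DataFrame(mat, index=truth["pas_id"].values,
                        columns=[s.sample_id for s in samples])


# ---------------------------------------------------------------------------
# tags


def simulate_tags(
    config: SimConfig, truth: pd.DataFrame, counts: pd.DataFrame
) -> list[AlignedTag]:
    """Emit one tag per counted read, jittered around the true cleavage site.

    Jitter is rounded Gaussian (sd = ``tag_jitter_sd_nt``) truncated to
    |jitter| <= 12 nt, so planted PASs (> 25 nt apart) can never merge.
    """
    rng = config.rng_for("tags")
    tags: list[AlignedTag] = []
    coords = truth.set_index("pas_id")
    for pas_id in counts.index:
        row = coords.loc[pas_id]
        for sample_id, c in counts.loc[pas_id].items():
            c = int(c)
            if c == 0:
                continue
            if config.tag_jitter_sd_nt > 0:
                jitter = np.clip(
                    np.rint(rng.normal(0.0, config.tag_jitter_sd_nt, size=c)), -12, 12
                ).astype(int)
            else:
                jitter = np.zeros(c, dtype=int)
            for jt in jitter:
                tags.append(
                    AlignedTag(row["chrom"], row["strand"], int(row["coord"]) + int(jt), sample_id)
                )
    return tags


# ---------------------------------------------------------------------------
# FASTQ


def simulate_fastq(
    config: SimConfig,
    out_path: str,
    n_reads: int = 1000,
    low_quality_frac: float = 0.1,
) -> pd.DataFrame:
    """Write synthetic reads exercising the quality filter and T-trimmer.

    Clean read bodies are 30-120 nt, never start with T and have < 3 T in
    their first 4 bases, so the trimmer's stop condition holds exactly at
    the recorded clean start.  A ``t_prefix_prob`` fraction get a 5-20 nt 5'
    prefix that is >= 80% T (pure T runs, or runs with one embedded non-T
    followed by >= 3 T so the window rule removes it).  A
    ``low_quality_frac`` fraction get mostly ~Q8 bases (the rest ~Q30).
    Returns the per-read truth table.
    """
    rng = config.rng_for("fastq")
    bases = np.array(list("ACGT"))
    no_t = np.array(list("ACG"))
    rows = []
    with open(out_path, "w") as fh:
        for i in range(n_reads):
            clean_len = int(rng.integers(30, 121))
            head = rng.choice(no_t, size=min(4, clean_len))
            tail = rng.choice(bases, size=max(clean_len - 4, 0))
            clean = "".join(head) + "".join(tail)

            has_prefix = rng.uniform() < config.t_prefix_prob
            prefix = ""
            if has_prefix:
                plen = int(rng.integers(5, 21))
                if rng.uniform() < 0.5 or plen < 5:
                    prefix = "T" * plen
                else:
                    pos = int(rng.integers(1, plen - 3))  # >= 3 trailing T
                    prefix = "T" * pos + str(rng.choice(no_t)) + "T" * (plen - pos - 1)
            seq = prefix + clean

            low_q = rng.uniform() < low_quality_frac
            if low_q:
                quals = np.clip(rng.normal(8, 2, size=len(seq)), 2, 9).astype(int)
            else:
                quals = np.clip(rng.normal(33, 3, size=len(seq)), 15, 40).astype(int)
            read_id = f"read{i:06d}"
            fh.write(
                f"@{read_id}\n{seq}\n+\n"
                + "".join(chr(q + 33) for q in quals)
                + "\n"
            )
            rows.append(
                {
                    "read_id": read_id,
                    "has_prefix": has_prefix,
                    "prefix_len": len(prefix),
                    "clean_len": clean_len,
                    "low_quality": low_q,
                    "clean_bases": clean,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def write_gtf(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                for s, e in t.exons:
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )
                # CDS spans from the first coding base to cds_end; emit the
                # portions of exons on the coding side
                if gene.strand == "+":
                    lo, hi = t.tx_start, t.cds_end
                else:
                    lo, hi = t.cds_end, t.tx_end
                for s, e in t.exons:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs <= ce:
                        fh.write(
                            f"{gene.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{gene.strand}\t.\t{attrs}\n"
                        )


def write_tags_bed(tags: list[AlignedTag], path: str) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.site - 1}\t{t.site}\t{t.sample_id}\t1\t{t.strand}\n")


def write_sample_sheet(samples: list[SampleInfo], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\treplicate\tlibrary_size\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.condition}\t{s.replicate}\t{s.library_size}\n")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# coord is the 1-based true cleavage site; period 0 = non-cycling\n")
        truth.to_csv(fh, sep="\t", index=False)
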