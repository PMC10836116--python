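"""PAC-to-gene assignment and genic region classification.

Each PAC summit is matched against same-strand gene models and labelled with
one of six mutually exclusive regions, resolved in this precedence order:

``utr3_terminal``  within ``terminal_tol_nt`` of the longest transcript end
``utr3_internal``  inside the longest annotated 3'UTR
``internal_exon``  inside any exon upstream of the 3'UTR
``intron``         inside the gene span but not in an exon
``utr3_distal``    within ``distal_window_nt`` downstream of the transcript
                   end, with no overlapping gene there
``intergenic``     none of the above

Strand-mismatched overlaps are intergenic for that gene (antisense calling
is out of scope).  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pas_calling import PAC

__all__ = [
    "Transcript",
    "GeneModel",
    "PACAnnotation",
    "read_gtf",
    "assign_region",
    "annotate_pacs",
    "apa_stats",
    "multi_apa_gene_set",
]

INTERGENIC = "INTERGENIC"
REGIONS = ("internal_exon", "intron", "utr3_internal", "utr3_terminal", "utr3_distal", "intergenic")


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by start
    cds_end: int  # 3'-most CDS base in transcript orientation
    tx_start: int = 0
    tx_end: int = 0  # genomic span bounds

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"transcript {self.transcript_id}: overlapping exons")
        self.tx_start = self.exons[0][0]
        self.tx_end = self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.tx_start for t in self.transcripts),
            max(t.tx_end for t in self.transcripts),
        )

    @property
    def terminus(self) -> int:
        """3'-most transcript end in transcript orientation."""
        if self.strand == "+":
            return max(t.tx_end for t in self.transcripts)
        return min(t.tx_start for t in self.transcripts)

    @property
    def longest_utr3(self) -> tuple[int, int] | None:
        """Genomic interval of the longest annotated 3'UTR (CDS end exclusive)."""
        best = None
        best_len = -1
        for t in self.transcripts:
            if self.strand == "+":
                lo, hi = t.cds_end + 1, t.tx_end
            else:
                lo, hi = t.tx_start, t.cds_end - 1
            if hi >= lo and hi - lo > best_len:
                best, best_len = (lo, hi), hi - lo
        return best


@dataclass
class PACAnnotation:
    pac_id: str
    gene_id: str
    region: str
    apa_index: int = 0


def read_gtf(path: str) -> list[GeneModel]:
    """Parse gene models from GTF (exon + CDS features; gene_id/transcript_id attrs)."""
    exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    cds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    tx_gene: dict[str, str] = {}

    def attr(attrs: str, key: str) -> str:
        for part in attrs.strip().split(";"):
            part = part.strip()
            if part.startswith(key + " "):
                return part.split(" ", 1)[1].strip().strip('"')
        raise ValueError(f"GTF attribute {key!r} missing in: {attrs!r}")

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            gid = attr(attrs, "gene_id")
            tid = attr(attrs, "transcript_id")
            meta[gid] = (chrom, strand)
            tx_gene[tid] = gid
            target = exons if feature == "exon" else cds
            target.setdefault((gid, tid), []).append((int(start), int(end)))

    genes: dict[str, GeneModel] = {}
    for (gid, tid), ex in exons.items():
        chrom, strand = meta[gid]
        gene = genes.setdefault(gid, GeneModel(gid, chrom, strand))
        cds_intervals = cds.get((gid, tid), [])
        if cds_intervals:
            cds_end = max(e for _, e in cds_intervals) if strand == "+" else min(
                s for s, _ in cds_intervals
            )
        else:
            # non-coding: treat the whole transcript as untranslated
            cds_end = min(s for s, _ in ex) - 1 if strand == "+" else max(e for _, e in ex) + 1
        gene.transcripts.append(Transcript(tid, ex, cds_end))
    return list(genes.values())


def _locate_in_gene(gene: GeneModel, pos: int, terminal_tol_nt: int) -> str | None:
    """Region for a position inside the gene span (or near its terminus), else None."""
    if abs(pos - gene.terminus) <= terminal_tol_nt:
        return "utr3_terminal"
    utr3 = gene.longest_utr3
    if utr3 and utr3[0] <= pos <= utr3[1]:
        return "utr3_internal"
    lo, hi = gene.span
    if lo <= pos <= hi:
        for t in gene.transcripts:
            if any(s <= pos <= e for s, e in t.exons):
                return "internal_exon"
        return "intron"
    return None


def _downstream_distance(gene: GeneModel, pos: int) -> int:
    """Signed distance of pos past the gene terminus in transcript orientation."""
    return pos - gene.terminus if gene.strand == "+" else gene.terminus - pos


def assign_region(
    pac: PAC,
    genes: list[GeneModel],
    terminal_tol_nt: int = 25,
    distal_window_nt: int = 5000,
) -> PACAnnotation:
    """Classify one PAC summit against same-strand gene models.

    Candidate genes whose span (or downstream distal window) contains the
    summit compete; ties are resolved by the smallest distance between the
    summit and a candidate's transcript end.
    """
    pos = pac.summit
    in_gene: list[tuple[int, str, GeneModel]] = []
    distal: list[tuple[int, GeneModel]] = []
    for gene in genes:
        if gene.chrom != pac.chrom or gene.strand != pac.strand:
            continue
        region = _locate_in_gene(gene, pos, terminal_tol_nt)
        if region is not None:
            in_gene.append((abs(pos - gene.terminus), region, gene))
        else:
            d = _downstream_distance(gene, pos)
            if 0 < d <= distal_window_nt:
                distal.append((d, gene))
    if in_gene:
        _, region, gene = min(in_gene, key=lambda x: x[0])
        return PACAnnotation(pac.pac_id, gene.gene_id, region)
    if distal:
        _, gene = min(distal, key=lambda x: x[0])
        return PACAnnotation(pac.pac_id, gene.gene_id, "utr3_distal")
    return PACAnnotation(pac.pac_id, INTERGENIC, "intergenic")


def annotate_pacs(
    pacs: list[PAC],
    genes: list[GeneModel],
    terminal_tol_nt: int = 25,
    distal_window_nt: int = 5000,
) -> list[PACAnnotation]:
    """Annotate all PACs and set per-gene apa_index in transcript orientation."""
    annots = [assign_region(p, genes, terminal_tol_nt, distal_window_nt) for p in pacs]
    strand = {g.gene_id: g.strand for g in genes}
    summit = {p.pac_id: p.summit for p in pacs}
    by_gene: dict[str, list[PACAnnotation]] = {}
    for a in annots:
        if a.gene_id != INTERGENIC:
            by_gene.setdefault(a.gene_id, []).append(a)
    for gid, members in by_gene.items():
        members.sort(key=lambda a: summit[a.pac_id], reverse=strand[gid] == "-")
        for k, a in enumerate(members, start=1):
            a.apa_index = k
    return annots


def apa_stats(annotations: list[PACAnnotation]) -> dict:
    """Per-gene PAC counts and summary APA statistics.

    Returns a dict with ``per_gene`` (gene -> PAC count), ``histogram``
    (PACs/gene -> number of genes), ``mean_per_gene`` and ``frac_genes_ge``
    (k -> fraction of genes with >= k PACs, k = 2..max).
    """
    per_gene: dict[str, int] = {}
    for a in annotations:
        if a.gene_id != INTERGENIC:
            per_gene[a.gene_id] = per_gene.get(a.gene_id, 0) + 1
    if not per_gene:
        return {"per_gene": {}, "histogram": {}, "mean_per_gene": float("nan"), "frac_genes_ge": {}}
    counts = pd.Series(per_gene)
    histogram = counts.value_counts().sort_index().to_dict()
    frac_ge = {
        k: float((counts >= k).mean()) for k in range(2, int(counts.max()) + 1)
    }
    return {
        "per_gene": per_gene,
        "histogram": histogram,
        "mean_per_gene": float(counts.mean()),
        "frac_genes_ge": frac_ge,
    }


def multi_apa_gene_set(annotations: list[PACAnnotation], min_pas: int = 2) -> set[str]:
    """Genes with at least ``min_pas`` annotated PACs (gates rhythm/DE result sets)."""
    per_gene = apa_stats(annotations)["per_gene"]
    return {g for g, n in per_gene.items() if n >= min_pas}


def write_annotation_tsv(annotations: list[PACAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# apa_index ordered 5'->3' in transcript orientation\n")
        pd.DataFrame(
            [
                {"pac_id": a.pac_id, "gene_id": a.gene_id, "region": a.region,
                 "apa_index": a.apa_index}
                for a in annotations
            ]
        ).to_csv(fh, sep="\t", index=False)
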