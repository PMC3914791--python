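"""Allele collapsing, cluster calling and genome-organization summaries.

The cluster rule follows the Arabidopsis-style definition used across plant
RGA surveys: two or more RGAs belong to one cluster when neighbouring RGAs
are within 250 kb of each other and separated by at most 21 non-RGA open
reading frames.  Putative alleles (overlapping same-scaffold predictions at
>90% protein similarity) are collapsed first and excluded from all further
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import mannwhitneyu

from .models import (
    Cluster,
    ClusterConfig,
    GeneModel,
    GenomeAnnotation,
    RGARecord,
)

__all__ = [
    "protein_similarity",
    "collapse_alleles",
    "call_clusters",
    "summarize_catalog",
    "CatalogSummary",
    "class_chromosome_crosstab",
    "compare_exon_counts",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def protein_similarity(a: str, b: str) -> float:
    """Global-alignment identity fraction, terminal gaps excluded.

    Identities over alignment columns between the first and last aligned
    residue pair; BLOSUM62 with affine gaps picks the alignment.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein")
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # trim terminal gap columns
    first = 0
    last = len(row_a)
    while row_a[first] == "-" or row_b[first] == "-":
        first += 1
    while row_a[last - 1] == "-" or row_b[last - 1] == "-":
        last -= 1
    columns = last - first
    if columns <= 0:
        return 0.0
    ident = sum(
        1 for x, y in zip(row_a[first:last], row_b[first:last]) if x == y and x != "-"
    )
    return ident / columns


def collapse_alleles(
    records: list[RGARecord],
    similarity_threshold: float = 0.90,
) -> list[RGARecord]:
    """Mark putative alleles among same-scaffold, overlapping RGA pairs.

    Pairs whose genomic intervals intersect on the same scaffold and whose
    protein similarity is strictly greater than the threshold are joined;
    connected components are formed transitively and the longest protein
    (ties: smallest gene id) becomes the representative.  Returns new
    records with ``is_allele``/``representative_id`` set; order and all other
    fields preserved.
    """
    for rec in records:
        if not rec.gene.protein:
            raise ValueError(f"missing protein sequence for {rec.gene_id}")
    parent: dict[str, str] = {r.gene_id: r.gene_id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    by_scaffold: dict[str, list[RGARecord]] = {}
    for rec in sorted(records, key=lambda r: (r.gene.scaffold, r.gene.start, r.gene_id)):
        by_scaffold.setdefault(rec.gene.scaffold, []).append(rec)
    for scaffold_recs in by_scaffold.values():
        for i, ra in enumerate(scaffold_recs):
            for rb in scaffold_recs[i + 1 :]:
                if rb.gene.start >= ra.gene.end:
                    break  # sorted by start: no later gene can overlap ra
                if protein_similarity(ra.gene.protein, rb.gene.protein) > similarity_threshold:
                    union(ra.gene_id, rb.gene_id)

    components: dict[str, list[RGARecord]] = {}
    for rec in records:
        components.setdefault(find(rec.gene_id), []).append(rec)
    rep_of: dict[str, str] = {}
    for members in components.values():
        rep = min(members, key=lambda r: (-len(r.gene.protein), r.gene_id))
        for rec in members:
            rep_of[rec.gene_id] = rep.gene_id
    return [
        rec.replace(
            is_allele=rep_of[rec.gene_id] != rec.gene_id,
            representative_id=rep_of[rec.gene_id],
        )
        for rec in records
    ]


def _intervening_count(genes: list[GeneModel], rga_ids: set[str], prev: GeneModel, nxt: GeneModel) -> int:
    """Non-RGA genes lying entirely within the open gap between two RGAs."""
    return sum(
        1
        for g in genes
        if g.gene_id not in rga_ids
        and g.start >= prev.end
        and g.end <= nxt.start
    )


def call_clusters(
    records: list[RGARecord],
    annotation: GenomeAnnotation,
    cfg: ClusterConfig = ClusterConfig(),
) -> tuple[list[Cluster], list[str]]:
    """Chain anchored, non-allele RGAs into positional clusters.

    Consecutive RGAs on a chromosome are linked when the gap between their
    facing interval ends is at most ``cfg.max_gap`` *and* at most
    ``cfg.max_intervening`` non-RGA genes lie strictly between them.
    Clusters are maximal chains of length >= 2; everything else is a
    singleton.  With ``gap_mode="cluster_average"`` the gap condition is that
    the running mean of adjacent gaps within the chain stays <= ``max_gap``.

    Returns ``(clusters, singleton gene ids)``.
    """
    eligible = [r for r in records if r.gene.anchored and not r.is_allele]
    rga_ids = {r.gene_id for r in eligible}
    by_chrom: dict[str, list[RGARecord]] = {}
    for rec in eligible:
        by_chrom.setdefault(rec.gene.chromosome, []).append(rec)  # type: ignore[arg-type]

    clusters: list[Cluster] = []
    singletons: list[str] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.gene.start, r.gene.end, r.gene_id))
        chrom_genes: list[GeneModel] = []
        for scaffold_genes in annotation.by_scaffold.values():
            chrom_genes.extend(g for g in scaffold_genes if g.chromosome == chrom)
        chrom_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

        chains: list[list[RGARecord]] = []
        chain = [recs[0]]
        gaps: list[int] = []
        for prev, nxt in zip(recs, recs[1:]):
            gap = nxt.gene.start - prev.gene.end
            n_between = _intervening_count(chrom_genes, rga_ids, prev.gene, nxt.gene)
            if cfg.gap_mode == "pairwise":
                gap_ok = gap <= cfg.max_gap
            else:
                gap_ok = (sum(gaps) + gap) / (len(gaps) + 1) <= cfg.max_gap
            if gap_ok and n_between <= cfg.max_intervening:
                chain.append(nxt)
                gaps.append(gap)
            else:
                chains.append(chain)
                chain = [nxt]
                gaps = []
        chains.append(chain)

        for chain in chains:
            if len(chain) < 2:
                singletons.append(chain[0].gene_id)
                continue
            idx = len([c for c in clusters if c.chromosome == chrom]) + 1
            clusters.append(
                Cluster(
                    cluster_id=f"{chrom}.C{idx}",
                    chromosome=chrom,
                    members=tuple(r.gene_id for r in chain),
                    span_start=min(r.gene.start for r in chain),
                    span_end=max(r.gene.end for r in chain),
                )
            )
    return clusters, singletons


@dataclass
class CatalogSummary:
    """Genome-organization summary (the catalog's table of record).

    ``per_chromosome`` columns: n_rgas, n_singletons, n_clusters,
    mean_cluster_size.  Share percentages are rounded to whole percent as
    catalog tables conventionally print them; ratios of counts to 2 decimals
    and mean cluster sizes to 1.
    """

    per_chromosome: pd.DataFrame
    n_rgas: int
    n_alleles: int
    n_anchored: int
    n_clustered: int
    n_singletons: int
    n_clusters: int
    pct_clustered: float
    mean_cluster_size: float
    max_cluster_size: int
    pct_of_predicted_genes: float
    density_per_mb: float
    top6_chromosomes: tuple[str, ...]
    pct_on_top6: float
    chromosome_share_pct: dict[str, float]
    mean_exons: float
    mean_exons_by_superclass: dict[str, float] = field(default_factory=dict)


def summarize_catalog(
    records: list[RGARecord],
    clusters: list[Cluster],
    singletons: list[str],
    n_predicted_genes: int,
    genome_mb: float,
) -> CatalogSummary:
    """Compute the full organization summary from a consistent catalog."""
    if n_predicted_genes <= 0:
        raise ValueError("n_predicted_genes must be positive")
    kept = [r for r in records if not r.is_allele]
    n_alleles = len(records) - len(kept)
    anchored = [r for r in kept if r.gene.anchored]
    n_rgas = len(kept)
    n_anchored = len(anchored)

    chroms = sorted({r.gene.chromosome for r in anchored})
    rows = []
    for chrom in chroms:
        c_rgas = sum(1 for r in anchored if r.gene.chromosome == chrom)
        c_clusters = [c for c in clusters if c.chromosome == chrom]
        c_singletons = sum(
            1 for s in singletons if s in {r.gene_id for r in anchored if r.gene.chromosome == chrom}
        )
        clustered = sum(c.size for c in c_clusters)
        rows.append(
            {
                "chromosome": chrom,
                "n_rgas": c_rgas,
                "n_singletons": c_singletons,
                "n_clusters": len(c_clusters),
                "mean_cluster_size": round(clustered / len(c_clusters), 1)
                if c_clusters
                else 0.0,
            }
        )
    per_chromosome = pd.DataFrame(
        rows, columns=["chromosome", "n_rgas", "n_singletons", "n_clusters", "mean_cluster_size"]
    )

    n_singletons = len(singletons)
    n_clustered = sum(c.size for c in clusters)
    pct_clustered = round(100.0 * n_clustered / n_anchored) if n_anchored else 0.0
    mean_cluster_size = round(n_clustered / len(clusters), 1) if clusters else 0.0
    shares = {
        chrom: round(100.0 * row["n_rgas"] / n_anchored) if n_anchored else 0.0
        for chrom, row in zip(chroms, rows)
    }
    top6 = tuple(
        sorted(chroms, key=lambda c: (-per_chromosome.set_index("chromosome").loc[c, "n_rgas"], c))[:6]
    )
    n_top6 = int(
        per_chromosome.set_index("chromosome").loc[list(top6), "n_rgas"].sum()
    ) if chroms else 0

    exon_counts = [r.gene.n_exons for r in kept]
    by_super: dict[str, list[int]] = {}
    for r in kept:
        by_super.setdefault(r.superclass, []).append(r.gene.n_exons)

    return CatalogSummary(
        per_chromosome=per_chromosome,
        n_rgas=n_rgas,
        n_alleles=n_alleles,
        n_anchored=n_anchored,
        n_clustered=n_clustered,
        n_singletons=n_singletons,
        n_clusters=len(clusters),
        pct_clustered=pct_clustered,
        mean_cluster_size=mean_cluster_size,
        max_cluster_size=max((c.size for c in clusters), default=0),
        pct_of_predicted_genes=round(100.0 * n_rgas / n_predicted_genes, 2),
        density_per_mb=round(n_rgas / genome_mb, 2) if genome_mb else 0.0,
        top6_chromosomes=top6,
        pct_on_top6=round(100.0 * n_top6 / n_anchored) if n_anchored else 0.0,
        chromosome_share_pct=shares,
        mean_exons=round(sum(exon_counts) / len(exon_counts), 2) if exon_counts else 0.0,
        mean_exons_by_superclass={
            k: round(sum(v) / len(v), 2) for k, v in sorted(by_super.items())
        },
    )


def class_chromosome_crosstab(
    records: list[RGARecord], by: str = "class"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class x chromosome percentage tables for anchored, non-allele records.

    Returns ``(row_pct, col_pct)``: ``row_pct`` normalizes each class row to
    100 (where is this class?), ``col_pct`` each chromosome column (what is
    on this chromosome?).  ``by`` selects ``"class"`` or ``"superclass"``.
    """
    anchored = [r for r in records if r.gene.anchored and not r.is_allele]
    if not anchored:
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame(
        {
            "group": [r.rga_class if by == "class" else r.superclass for r in anchored],
            "chromosome": [r.gene.chromosome for r in anchored],
        }
    )
    counts = pd.crosstab(df["group"], df["chromosome"])
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return row_pct.round(2), col_pct.round(2)


def compare_exon_counts(
    records: list[RGARecord],
    group_a: str = "CNL",
    group_b: str = "TNL",
    by: str = "class",
) -> tuple[float | None, float | None, float | None]:
    """Mean exon counts of two RGA groups plus a two-sided Mann–Whitney U p.

    Returns ``(mean_a, mean_b, p_value)``; a mean is ``None`` for an empty
    group and the p-value is ``None`` unless both groups have >= 2 members.
    """
    key = (lambda r: r.rga_class) if by == "class" else (lambda r: r.superclass)
    xs = [r.gene.n_exons for r in records if not r.is_allele and key(r) == group_a]
    ys = [r.gene.n_exons for r in records if not r.is_allele and key(r) == group_b]
    mean_a = round(sum(xs) / len(xs), 2) if xs else None
    mean_b = round(sum(ys) / len(ys), 2) if ys else None
    if len(xs) < 2 or len(ys) < 2:
        return mean_a, mean_b, None
    if xs == ys:
        return mean_a, mean_b, 1.0
    _, p = mannwhitneyu(xs, ys, alternative="two-sided")
    return mean_a, mean_b, float(p)
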