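"""Shared domain types for the RGA cataloguing pipeline.

Coordinate convention: everything in memory is 0-based, half-open
``[start, end)``.  GFF3 on disk is 1-based inclusive; the conversion happens
exclusively in :mod:`rgakit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DOMAIN_LABELS",
    "CLASS_SUPERCLASS",
    "GeneModel",
    "DomainHit",
    "GenomeAnnotation",
    "RGARecord",
    "Cluster",
    "CoilConfig",
    "ClusterConfig",
    "LinkConfig",
    "KsEstimate",
    "ChromosomeLink",
]

#: Domain labels accepted in domain-hit tables.  NB-ARC is the NBS token of
#: the architecture grammar; BED and kinase are carried as annotation flags
#: only and never enter a class label.
DOMAIN_LABELS = frozenset({"NB-ARC", "TIR", "LRR", "CC", "BED", "kinase"})

#: Fixed map from the nine architecture labels to their superclass.
#: TIR-NBS groups every TIR-containing architecture; non-TIR NBS-LRR groups
#: NL and CNL; N and CN fall in the residual "other" bin.
CLASS_SUPERCLASS = {
    "TNL": "TIR-NBS",
    "NLT": "TIR-NBS",
    "TCNL": "TIR-NBS",
    "TCN": "TIR-NBS",
    "TN": "TIR-NBS",
    "CNL": "non-TIR-NBS-LRR",
    "NL": "non-TIR-NBS-LRR",
    "CN": "other",
    "N": "other",
}


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene model.

    ``chromosome`` is ``None`` for genes on unanchored scaffolds; such genes
    are kept in the catalog ("not anchored") but excluded from cluster calling
    and from chromosome-level analyses.
    """

    gene_id: str
    scaffold: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    chromosome: str | None = None
    n_exons: int = 1
    protein: str = ""
    cds: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.n_exons < 1:
            raise ValueError(f"gene {self.gene_id}: n_exons must be >= 1")
        if self.cds and len(self.cds) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        if self.cds and self.protein and len(self.protein) * 3 > len(self.cds) + 3:
            raise ValueError(
                f"gene {self.gene_id}: protein too long for CDS "
                f"({len(self.protein)} aa vs {len(self.cds)} nt)"
            )

    @property
    def anchored(self) -> bool:
        return self.chromosome is not None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class DomainHit:
    """A labeled domain interval on a protein (residue coordinates, 0-based)."""

    gene_id: str
    aa_start: int
    aa_end: int
    domain: str
    score: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_LABELS:
            raise ValueError(
                f"unknown domain label {self.domain!r} on {self.gene_id} "
                f"(expected one of {sorted(DOMAIN_LABELS)})"
            )
        if not self.aa_start < self.aa_end:
            raise ValueError(
                f"domain hit on {self.gene_id}: aa_start ({self.aa_start}) "
                f"must be < aa_end ({self.aa_end})"
            )


class GenomeAnnotation:
    """Genes grouped per scaffold, plus genome-level metadata.

    Genes are kept sorted by start within each scaffold.  ``genome_mb`` and
    ``n_predicted_genes`` feed the density and percentage rows of the catalog
    summary.
    """

    def __init__(
        self,
        genes: list[GeneModel],
        chromosome_lengths: dict[str, int] | None = None,
        genome_mb: float | None = None,
    ) -> None:
        self.by_scaffold: dict[str, list[GeneModel]] = {}
        self.by_id: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.by_id[g.gene_id] = g
            self.by_scaffold.setdefault(g.scaffold, []).append(g)
        for scaffold in self.by_scaffold:
            self.by_scaffold[scaffold].sort(key=lambda g: (g.start, g.end, g.gene_id))
        self.chromosome_lengths = dict(chromosome_lengths or {})
        for g in genes:
            if g.chromosome is not None and g.chromosome not in self.chromosome_lengths:
                self.chromosome_lengths[g.chromosome] = 0
        # grow recorded lengths to cover the genes we actually hold
        for g in genes:
            if g.chromosome is not None:
                self.chromosome_lengths[g.chromosome] = max(
                    self.chromosome_lengths[g.chromosome], g.end
                )
        self.genome_mb = genome_mb

    @property
    def genes(self) -> list[GeneModel]:
        out: list[GeneModel] = []
        for scaffold in sorted(self.by_scaffold):
            out.extend(self.by_scaffold[scaffold])
        return out

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.by_id[gene_id]


@dataclass
class RGARecord:
    """A gene promoted to RGA status.

    ``representative_id`` equals the record's own gene id unless the record
    was collapsed as a putative allele of another RGA.  ``flags`` carries
    annotation-only markers (``BED``, ``kinase``, ``multi-NBS``,
    ``short-sequence``).
    """

    gene: GeneModel
    rga_class: str
    coil_prob: float = 0.0
    flags: frozenset[str] = field(default_factory=frozenset)
    is_allele: bool = False
    representative_id: str = ""
    cluster_id: str | None = None
    clade_id: str | None = None

    def __post_init__(self) -> None:
        if self.rga_class not in CLASS_SUPERCLASS:
            raise ValueError(f"unknown RGA class {self.rga_class!r}")
        if not self.representative_id:
            self.representative_id = self.gene.gene_id
        if self.is_allele and self.representative_id == self.gene.gene_id:
            raise ValueError(
                f"{self.gene.gene_id}: an allele must point at a distinct representative"
            )

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def superclass(self) -> str:
        return CLASS_SUPERCLASS[self.rga_class]

    def replace(self, **kw) -> "RGARecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class Cluster:
    """A maximal chain of >=2 RGAs on one chromosome."""

    cluster_id: str
    chromosome: str
    members: tuple[str, ...]  # gene ids sorted by start
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster {self.cluster_id}: needs >= 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CoilConfig:
    """Coiled-coil scorer settings: scan window and acceptance probability.

    The stringent default threshold (0.9) keeps CC calls specific; windows
    other than 14/21/28 have no calibrated score-to-probability mapping.
    """

    window: int = 21
    threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.window not in (14, 21, 28):
            raise ValueError(f"window must be one of 14, 21, 28 (got {self.window})")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1] (got {self.threshold})")


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-calling rule: neighbour gap cap and intervening-ORF cap."""

    max_gap: int = 250_000
    max_intervening: int = 21
    gap_mode: str = "pairwise"  # or "cluster_average"

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if self.gap_mode not in ("pairwise", "cluster_average"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass(frozen=True)
class LinkConfig:
    """Chromosome-connection rule on pairwise Ks values."""

    ks_threshold: float = 0.25
    min_pairs: int = 10
    strict_less: bool = False  # True: ks < threshold instead of <=

    def __post_init__(self) -> None:
        if self.ks_threshold <= 0:
            raise ValueError("ks_threshold must be > 0")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


@dataclass(frozen=True)
class KsEstimate:
    """Nei–Gojobori pairwise estimate.

    ``ks`` is ``None`` when the Jukes–Cantor correction is undefined
    (``ps >= 0.75``, flagged ``saturated``) or no synonymous sites were
    compared (flagged ``zero-sites``).
    """

    gene_a: str
    gene_b: str
    syn_sites: float  # S
    nonsyn_sites: float  # N
    syn_diffs: float  # Sd
    nonsyn_diffs: float  # Nd
    ps: float | None
    pn: float | None
    ks: float | None
    ka: float | None
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ChromosomeLink:
    """An (unordered) chromosome pair with its low-Ks pair support."""

    chr_a: str
    chr_b: str
    n_low_ks_pairs: int
    accepted: bool
    pairs: tuple[tuple[str, str], ...] = ()

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.chr_a, self.chr_b)))  # type: ignore[return-value]
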