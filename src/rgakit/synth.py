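"""Synthetic genomes, proteomes and alignments with known ground truth.

The generator plants the structures the downstream modules are meant to
recover: positional RGA clusters among background ORFs, same-scaffold
overlapping allele pairs, whole-genome-duplication partners at a controlled
synonymous divergence, chromosome-biased TIR vs non-TIR composition, and
coiled-coil heptads on CC-class proteins.  Domain content is marked with
sentinel motifs so the domain-hit table can be produced without a profile
search, while coiled-coil segments are genuine heptad repeats so the scorer
is exercised for real.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import io as rio
from .models import DomainHit, GeneModel, GenomeAnnotation
from .phylo import AMINO_ACIDS, DAYHOFF_FREQS, Alignment, transition_matrix
from .ksdup import _CODON_TABLE, syn_site_fraction

__all__ = ["SynthConfig", "GroundTruth", "SynthGenome", "generate_genome", "generate_alignment"]

# Sentinel domain motifs (12-mers).  The NBS motif is the P-loop of real
# NB-ARC domains; the others are distinctive, non-repetitive tags.
MOTIFS = {
    "TIR": "YDVFLSFRGEDT",
    "NB-ARC": "GMGGVGKTTLAR",
    "LRR": "DNSWTGVDHTRN",
    "BED": "WHCKYCNQEFKE",
    "kinase": "HRDVKSTNVMID",
}
#: One idealized heptad (a..g = L A A L E A K); repeated to plant a CC.
HEPTAD_UNIT = "LAALEAK"
CC_REPEATS = 5

_AA = np.array(list(AMINO_ACIDS))
_AA_P = np.array([DAYHOFF_FREQS[a] for a in AMINO_ACIDS])
_AA_P = _AA_P / _AA_P.sum()
# proline and glycine would never hurt, but avoid long accidental heptads by
# sampling filler from the Dayhoff background as-is
_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _SYN_CODONS.setdefault(_aa, []).append(_codon)

_TOKEN_DOMAIN = {"T": "TIR", "C": "CC", "N": "NB-ARC", "L": "LRR"}

_TIR_LABELS = (("TNL", 0.60), ("TN", 0.20), ("TCNL", 0.10), ("TCN", 0.05), ("NLT", 0.05))
_CC_LABELS = (("CNL", 0.80), ("CN", 0.20))
_PLAIN_LABELS = (("NL", 0.80), ("N", 0.20))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic genome.

    ``cluster_spec`` entries are ``(chromosome, n_members, spacing_bp,
    n_intervening)``; a 1-member entry plants a singleton RGA.  ``wgd_spec``
    entries are ``(chr_a, chr_b, target_ks, n_pairs)``.  ``class_bias`` maps
    a chromosome to its TIR-superclass fraction (default ``tir_fraction``).
    Planted blocks are separated by ``block_gap`` so that only the planted
    chains satisfy the cluster rule.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 6_000_000
    n_background_genes: int = 60
    cluster_spec: tuple[tuple[str, int, int, int], ...] = (
        ("Chr1", 3, 60_000, 4),
        ("Chr2", 5, 60_000, 4),
        ("Chr1", 1, 0, 0),
    )
    n_allele_pairs: int = 2
    allele_similarity: float = 0.97
    wgd_spec: tuple[tuple[str, str, float, int], ...] = ()
    tir_fraction: float = 0.4
    class_bias: dict[str, float] = field(default_factory=dict)
    coil_fraction: float = 0.5
    rga_protein_len: int = 150
    background_protein_len: int = 100
    block_gap: int = 400_000

    def __post_init__(self) -> None:
        for _, _, ks, _ in self.wgd_spec:
            if not 0 < ks < 0.75:
                raise ValueError(f"target Ks must be in (0, 0.75), got {ks}")
        chroms = {f"Chr{i + 1}" for i in range(self.n_chromosomes)}
        for spec in self.cluster_spec:
            if spec[0] not in chroms:
                raise ValueError(f"cluster_spec names unknown chromosome {spec[0]}")
        for a, b, _, _ in self.wgd_spec:
            if a not in chroms or b not in chroms:
                raise ValueError(f"wgd_spec names unknown chromosome {a}/{b}")


@dataclass
class GroundTruth:
    """What was planted, keyed the way the pipeline reports results."""

    classes: dict[str, str] = field(default_factory=dict)
    allele_of: dict[str, str] = field(default_factory=dict)  # allele id -> representative
    clusters: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    wgd_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    links: set[tuple[str, str]] = field(default_factory=set)
    has_cc_heptads: dict[str, bool] = field(default_factory=dict)


@dataclass
class SynthGenome:
    config: SynthConfig
    annotation: GenomeAnnotation
    proteins: dict[str, str]
    cds: dict[str, str]
    hits: dict[str, list[DomainHit]]
    truth: GroundTruth

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        outdir = str(outdir)
        rio.write_gff3(self.annotation, os.path.join(outdir, "genes.gff3"))
        rio.write_fasta(self.proteins, os.path.join(outdir, "proteins.faa"))
        rio.write_fasta(self.cds, os.path.join(outdir, "cds.fna"))
        flat = [h for hits in self.hits.values() for h in hits]
        rio.write_domain_hits(flat, os.path.join(outdir, "domain_hits.tsv"))
        truth = {
            "classes": self.truth.classes,
            "allele_of": self.truth.allele_of,
            "clusters": [[c, list(m)] for c, m in self.truth.clusters],
            "wgd_pairs": [list(p) for p in self.truth.wgd_pairs],
            "links": sorted(list(l) for l in self.truth.links),
            "has_cc_heptads": self.truth.has_cc_heptads,
        }
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n, p=_AA_P))


def _sample_label(rng: np.random.Generator, tir_frac: float, coil_frac: float) -> str:
    def pick(table):
        labels, weights = zip(*table)
        w = np.array(weights) / sum(weights)
        return str(rng.choice(labels, p=w))

    if rng.random() < tir_frac:
        return pick(_TIR_LABELS)
    if rng.random() < coil_frac:
        return pick(_CC_LABELS)
    return pick(_PLAIN_LABELS)


def _build_protein(
    rng: np.random.Generator, label: str, total_len: int
) -> tuple[str, list[tuple[str, int, int]]]:
    """Protein with planted ordered domain segments; returns (seq, segments).

    Segments are ``(domain, aa_start, aa_end)``; the CC segment is real
    heptad repeats and is *not* reported as a segment (the scorer must find
    it), every other domain gets a sentinel motif.
    """
    parts: list[str] = [_filler(rng, 15)]
    segments: list[tuple[str, int, int]] = []
    pos = 15
    for token in label:
        domain = _TOKEN_DOMAIN[token]
        seg = HEPTAD_UNIT * CC_REPEATS if domain == "CC" else MOTIFS[domain]
        if domain != "CC":
            segments.append((domain, pos, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
        spacer = _filler(rng, 10)
        parts.append(spacer)
        pos += len(spacer)
    tail = max(total_len - pos, 5)
    parts.append(_filler(rng, tail))
    return "".join(parts), segments


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(str(rng.choice(_SYN_CODONS[aa])) for aa in protein)


def _synonymous_diverge(
    rng: np.random.Generator, cds: str, target_ks: float
) -> str:
    """Copy of ``cds`` carrying synonymous substitutions at NG86 depth ``target_ks``.

    Single-nucleotide synonymous changes are applied in distinct codons until
    the implied proportion of synonymous differences matches the target under
    the Jukes–Cantor correction.
    """
    codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
    S = sum(sum(syn_site_fraction(c)) for c in codons if c in _CODON_TABLE)
    ps_target = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * target_ks))
    n_changes = int(round(ps_target * S))
    mutable = []
    for idx, codon in enumerate(codons):
        if codon not in _CODON_TABLE:
            continue
        aa = _CODON_TABLE[codon]
        alts = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if _CODON_TABLE.get(alt) == aa:
                    alts.append(alt)
        if alts:
            mutable.append((idx, alts))
    if n_changes > len(mutable):
        raise ValueError(
            f"cannot plant {n_changes} synonymous changes in {len(mutable)} codons"
        )
    chosen = rng.choice(len(mutable), size=n_changes, replace=False)
    out = list(codons)
    for k in chosen:
        idx, alts = mutable[int(k)]
        out[idx] = alts[int(rng.integers(len(alts)))]
    return "".join(out)


def _mutate_protein(
    rng: np.random.Generator,
    protein: str,
    segments: list[tuple[str, int, int]],
    similarity: float,
) -> str:
    """Substitute filler residues down to the requested identity."""
    protected = set()
    for _, s, e in segments:
        protected.update(range(s, e))
    free = [i for i in range(len(protein)) if i not in protected]
    n_mut = min(int(round((1.0 - similarity) * len(protein))), len(free))
    targets = rng.choice(len(free), size=n_mut, replace=False)
    seq = list(protein)
    for t in targets:
        i = free[int(t)]
        choices = [a for a in AMINO_ACIDS if a != seq[i]]
        seq[i] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def _exon_count(rng: np.random.Generator, label: str) -> int:
    # TIR-class genes carry more exons than CC-class ones, as in real RGA
    # catalogs (TNL ~6.4 vs CNL ~3.5 on average)
    if "T" in label:
        return 4 + int(rng.poisson(2.4))
    return 1 + int(rng.poisson(2.5))


def generate_genome(cfg: SynthConfig) -> SynthGenome:
    """Emit a fully specified genome + proteome + domain hits + ground truth.

    Deterministic given ``cfg.seed``; independent RNG streams per concern so
    adding one planted feature never reshuffles the others.
    """
    rng_layout = np.random.default_rng([cfg.seed, 1])
    rng_seq = np.random.default_rng([cfg.seed, 2])
    rng_class = np.random.default_rng([cfg.seed, 3])
    rng_wgd = np.random.default_rng([cfg.seed, 4])
    rng_allele = np.random.default_rng([cfg.seed, 5])

    chroms = [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]
    truth = GroundTruth()
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    hits: dict[str, list[DomainHit]] = {}
    cursor: dict[str, int] = {c: 50_000 for c in chroms}
    counters: dict[str, int] = {"rga": 0, "bg": 0}

    def new_rga(chrom: str, start: int, *, diverged_from: str | None = None,
                target_ks: float | None = None) -> GeneModel:
        counters["rga"] += 1
        gid = f"RGA{counters['rga']:04d}"
        tir_frac = cfg.class_bias.get(chrom, cfg.tir_fraction)
        if diverged_from is not None:
            label = truth.classes[diverged_from]
            protein = proteins[diverged_from]
            cds = _synonymous_diverge(rng_wgd, cds_map[diverged_from], target_ks or 0.1)
            segments = [(h.domain, h.aa_start, h.aa_end) for h in hits[diverged_from]]
        else:
            label = _sample_label(rng_class, tir_frac, cfg.coil_fraction)
            protein, segments = _build_protein(rng_seq, label, cfg.rga_protein_len)
            cds = _reverse_translate(rng_seq, protein)
        gene = GeneModel(
            gene_id=gid,
            scaffold=chrom,
            chromosome=chrom,
            start=start,
            end=start + len(cds),
            strand="+" if rng_layout.random() < 0.5 else "-",
            n_exons=_exon_count(rng_class, label),
            protein=protein,
            cds=cds,
        )
        genes.append(gene)
        proteins[gid] = protein
        cds_map[gid] = cds
        hits[gid] = [
            DomainHit(gene_id=gid, domain=d, aa_start=s, aa_end=e, score=100.0)
            for d, s, e in segments
        ]
        truth.classes[gid] = label
        truth.has_cc_heptads[gid] = "C" in label
        return gene

    def new_background(chrom: str, start: int) -> GeneModel:
        counters["bg"] += 1
        gid = f"ORF{counters['bg']:04d}"
        protein = _filler(rng_seq, cfg.background_protein_len)
        cds = _reverse_translate(rng_seq, protein)
        gene = GeneModel(
            gene_id=gid,
            scaffold=chrom,
            chromosome=chrom,
            start=start,
            end=start + len(cds),
            strand="+",
            n_exons=1 + int(rng_class.poisson(2)),
            protein=protein,
            cds=cds,
        )
        genes.append(gene)
        proteins[gid] = protein
        cds_map[gid] = cds
        return gene

    # --- planted clusters and singletons -------------------------------
    for chrom, n_members, spacing, n_between in cfg.cluster_spec:
        members: list[str] = []
        for m in range(n_members):
            gene = new_rga(chrom, cursor[chrom])
            members.append(gene.gene_id)
            if m < n_members - 1:
                gap_span = spacing - gene.length
                if gap_span <= (n_between + 1):
                    raise ValueError(
                        f"spacing {spacing} too small for genes on {chrom}"
                    )
                step = gap_span // (n_between + 1)
                for k in range(n_between):
                    bg_start = gene.end + (k + 1) * step - 400
                    new_background(chrom, bg_start)
                cursor[chrom] = gene.start + spacing
            else:
                cursor[chrom] = gene.end + cfg.block_gap
        if n_members >= 2:
            truth.clusters.append((chrom, tuple(members)))

    # --- WGD doublet partners ------------------------------------------
    for chr_a, chr_b, target_ks, n_pairs in cfg.wgd_spec:
        for _ in range(n_pairs):
            ga = new_rga(chr_a, cursor[chr_a])
            cursor[chr_a] = ga.end + cfg.block_gap
            gb = new_rga(chr_b, cursor[chr_b], diverged_from=ga.gene_id,
                         target_ks=target_ks)
            cursor[chr_b] = gb.end + cfg.block_gap
            truth.wgd_pairs.append((ga.gene_id, gb.gene_id, target_ks))
        truth.links.add(tuple(sorted((chr_a, chr_b))))

    # --- allele pairs: overlapping duplicates on one scaffold ----------
    rga_pool = [g for g in genes if g.gene_id.startswith("RGA")]
    for k in range(cfg.n_allele_pairs):
        src = rga_pool[k % len(rga_pool)]
        gid = f"{src.gene_id}al"
        segments = [(h.domain, h.aa_start, h.aa_end) for h in hits[src.gene_id]]
        protein = _mutate_protein(rng_allele, src.protein, segments, cfg.allele_similarity)
        cds = _reverse_translate(rng_allele, protein)
        gene = GeneModel(
            gene_id=gid,
            scaffold=src.scaffold,
            chromosome=src.chromosome,
            start=src.start + 90,  # overlaps the source interval
            end=src.start + 90 + len(cds),
            strand=src.strand,
            n_exons=src.n_exons,
            protein=protein,
            cds=cds,
        )
        genes.append(gene)
        proteins[gid] = protein
        cds_map[gid] = cds
        hits[gid] = [
            DomainHit(gene_id=gid, domain=d, aa_start=s, aa_end=e, score=100.0)
            for d, s, e in segments
        ]
        truth.classes[gid] = truth.classes[src.gene_id]
        truth.has_cc_heptads[gid] = truth.has_cc_heptads[src.gene_id]
        # the longer protein wins representation; equal lengths fall back to
        # the smaller id, which is the source gene
        truth.allele_of[gid] = src.gene_id

    # --- remaining background genes ------------------------------------
    remaining = cfg.n_background_genes - counters["bg"]
    for k in range(max(remaining, 0)):
        chrom = chroms[k % len(chroms)]
        gene = new_background(chrom, cursor[chrom])
        cursor[chrom] = gene.end + 8_000

    for chrom in chroms:
        if cursor[chrom] > cfg.chromosome_length:
            raise ValueError(
                f"{chrom}: layout needs {cursor[chrom]} bp but chromosome_length "
                f"is {cfg.chromosome_length}"
            )

    annotation = GenomeAnnotation(
        genes,
        chromosome_lengths={c: cfg.chromosome_length for c in chroms},
        genome_mb=cfg.n_chromosomes * cfg.chromosome_length / 1e6,
    )
    return SynthGenome(cfg, annotation, proteins, cds_map, hits, truth)


# ---------------------------------------------------------------------------
# Alignment simulation

def generate_alignment(
    n_leaves: int,
    n_columns: int,
    rate: float,
    seed: int = 0,
    tree: dendropy.Tree | None = None,
) -> tuple[Alignment, dendropy.Tree]:
    """Evolve a gapless protein alignment along a (random) tree.

    The tree, unless given, is a random binary topology with edge lengths
    ``rate * Uniform(0.5, 1.5)`` expected substitutions per site; sequences
    evolve under the same Dayhoff-style model the distance estimator uses.
    ``rate = 0`` yields identical sequences.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    if tree is None:
        taxa = dendropy.TaxonNamespace(labels)
        nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            for k in (i, j):
                parent.add_child(nodes[k])
                nodes[k].edge.length = float(rate * rng.uniform(0.5, 1.5))
            nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
        tree.is_rooted = False
    freqs = _AA_P
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.choice(20, size=n_columns, p=freqs)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = seqs[id(node.parent_node)]
        if t == 0:
            child = parent_states.copy()
        else:
            P = transition_matrix(t)
            child = np.array(
                [rng.choice(20, p=P[s] / P[s].sum()) for s in parent_states]
            )
        seqs[id(node)] = child
    rows = []
    out_labels = []
    for leaf in tree.leaf_node_iter():
        out_labels.append(leaf.taxon.label)
        rows.append("".join(_AA[s] for s in seqs[id(leaf)]))
    return Alignment(out_labels, rows), tree
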