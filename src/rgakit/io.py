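"""Readers and writers for all on-disk formats.

This is the only module that touches 1-based GFF3 coordinates; everything it
hands out is 0-based half-open.  FASTA goes through Biopython, GFF3 parsing
through gffutils (in-memory db), Newick through dendropy.
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainHit, GeneModel, GenomeAnnotation

__all__ = [
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_domain_hits",
    "write_domain_hits",
    "read_newick",
    "write_newick",
]

_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
_NT_CHARS = set("ACGTUNRYSWKMBDHV-")


def read_gff3(
    path: str | os.PathLike,
    proteins: dict[str, str] | None = None,
    cds: dict[str, str] | None = None,
    genome_mb: float | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 file with gene/mRNA/exon/CDS features.

    GFF3 1-based inclusive coordinates become 0-based half-open.  A gene's
    exon count comes from its exon features (1 when none are present, since a
    gene model always has at least one exon).  The chromosome is taken from a
    ``chromosome=`` attribute on the gene when present; otherwise a seqid of
    the form ``ChrNN`` is treated as an anchored chromosome and anything else
    as an unanchored scaffold.  ``proteins``/``cds`` (id -> sequence) attach
    sequences to the models.

    Raises ``ValueError`` naming the line for malformed rows.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ValueError(
                    f"malformed GFF3 line {lineno} in {path}: expected 9 columns"
                )
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils wraps the line in its message
        raise ValueError(f"malformed GFF3 in {path}: {exc}") from exc
    proteins = proteins or {}
    cds = cds or {}
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        n_exons = sum(1 for _ in db.children(feat, featuretype="exon"))
        chrom = feat.attributes.get("chromosome", [None])[0]
        if chrom is None and feat.seqid.lower().startswith("chr"):
            chrom = feat.seqid
        genes.append(
            GeneModel(
                gene_id=feat.id,
                scaffold=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                chromosome=chrom,
                n_exons=max(n_exons, 1),
                protein=proteins.get(feat.id, ""),
                cds=cds.get(feat.id, ""),
            )
        )
    return GenomeAnnotation(genes, genome_mb=genome_mb)


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon features (inverse of :func:`read_gff3`).

    Exons are emitted as even partitions of the gene span purely so the exon
    count round-trips; intron structure is not modelled.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation.genes:
            start1, end1 = gene.start + 1, gene.end
            attrs = f"ID={gene.gene_id}"
            if gene.chromosome is not None:
                attrs += f";chromosome={gene.chromosome}"
            fh.write(
                f"{gene.scaffold}\trgakit\tgene\t{start1}\t{end1}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            mrna = f"{gene.gene_id}.m1"
            fh.write(
                f"{gene.scaffold}\trgakit\tmRNA\t{start1}\t{end1}\t.\t{gene.strand}\t.\t"
                f"ID={mrna};Parent={gene.gene_id}\n"
            )
            # partition the span into n_exons non-overlapping pieces
            n = gene.n_exons
            length = gene.length
            bounds = [gene.start + (length * k) // n for k in range(n + 1)]
            for k in range(n):
                ex_s, ex_e = bounds[k], bounds[k + 1]
                fh.write(
                    f"{gene.scaffold}\trgakit\texon\t{ex_s + 1}\t{ex_e}\t.\t{gene.strand}\t.\t"
                    f"ID={mrna}.e{k + 1};Parent={mrna}\n"
                )


def read_fasta(path: str | os.PathLike, alphabet: str = "protein") -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``.

    Ids are truncated at the first whitespace and sequences uppercased.
    Duplicate ids and characters illegal for the alphabet raise ``ValueError``.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"alphabet must be 'protein' or 'nucleotide', got {alphabet!r}")
    allowed = _PROTEIN_CHARS if alphabet == "protein" else _NT_CHARS
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"illegal {alphabet} character(s) {sorted(bad)} in record {rec.id!r}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences in input order, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_domain_hits(path: str | os.PathLike) -> dict[str, list[DomainHit]]:
    """Read the 5-column domain-hit TSV: gene_id, domain, aa_start, aa_end, score.

    Coordinates in the file are 0-based half-open residue indices.  Hits come
    back grouped by gene and sorted by ``aa_start``; unknown domain labels and
    inverted intervals raise ``ValueError``.
    """
    hits: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "domain", "aa_start", "aa_end", "score"]
        if header != expected:
            raise ValueError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gene_id, domain, s, e, score = parts
            hit = DomainHit(
                gene_id=gene_id,
                domain=domain,
                aa_start=int(s),
                aa_end=int(e),
                score=float(score),
            )
            hits.setdefault(gene_id, []).append(hit)
    for gene_id in hits:
        hits[gene_id].sort(key=lambda h: (h.aa_start, h.aa_end, h.domain))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomain\taa_start\taa_end\tscore\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.domain}\t{h.aa_start}\t{h.aa_end}\t{h.score:g}\n")


def _check_leaf_labels(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen = set()
    dups = {x for x in labels if x in seen or seen.add(x)}
    if dups:
        raise ValueError(f"duplicate leaf labels: {sorted(dups)}")
    meta = set("();:,[]")
    bad = {x for x in labels if set(x) & meta or " " in x}
    if bad:
        raise ValueError(f"leaf labels contain Newick metacharacters: {sorted(bad)}")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Write Newick with 6-significant-digit branch lengths.

    Internal-node bootstrap supports (integer node labels) are preserved.
    """
    _check_leaf_labels(tree)
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                real_value_format_specifier=".6g",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    _check_leaf_labels(tree)
    return tree
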