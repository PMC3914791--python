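"""Pairwise synonymous divergence (Ks) and chromosome duplication links.

Ks is estimated with the Nei–Gojobori (1986) counting method: per-codon
synonymous site fractions averaged over the two sequences, differences
averaged over all shortest mutational pathways (pathways through stop codons
excluded), and a Jukes–Cantor correction ``ks = -(3/4) ln(1 - (4/3) ps)``.
Codon alignments are obtained by threading each CDS through a protein
alignment, which keeps reading frames intact for diverged NBS genes.

A connection between two chromosomes is accepted when at least
``min_pairs`` RGA pairs between them have a defined Ks at or below the
threshold (default 0.25, the first quartile of the apple RGA Ks
distribution); intra-chromosome pairs count towards self-links.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

from .models import ChromosomeLink, KsEstimate, LinkConfig, RGARecord

__all__ = [
    "codon_align",
    "ng86",
    "all_pairs_ks",
    "chromosome_links",
    "empirical_first_quartile",
    "syn_site_fraction",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of single-nucleotide changes that are synonymous.

    Changes to stop codons count as nonsynonymous, so the three fractions sum
    with their complements to exactly 3 sites per codon.
    """
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon}")
    fractions = []
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:
                syn += 1
        fractions.append(syn / 3.0)
    return tuple(fractions)  # type: ignore[return-value]


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon."""
    fr = syn_site_fraction(codon)
    s = sum(fr)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over shortest mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used (the standard fallback).
    """
    positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        cur = codon_a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_nxt is None:
                through_stop = True
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn, through_stop))
    valid = [p for p in pathways if not p[2]] or pathways
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0:
        return None
    import math

    return -0.75 * math.log(arg)


def _is_clean(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


def ng86(codons_a: str, codons_b: str, gene_a: str = "a", gene_b: str = "b") -> KsEstimate:
    """Nei–Gojobori estimate from two aligned codon strings.

    Inputs are equal-length nucleotide strings whose length is a multiple of
    three; codons containing gaps, ambiguous bases or stops in either
    sequence are skipped pairwise.
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("aligned codon strings differ in length")
    if len(codons_a) % 3:
        raise ValueError("aligned length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for k in range(0, len(codons_a), 3):
        ca, cb = codons_a[k : k + 3], codons_b[k : k + 3]
        if not (_is_clean(ca) and _is_clean(cb)):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _pathway_diffs(ca, cb)
        Sd += ds
        Nd += dn
    flags: set[str] = set()
    if S == 0:
        return KsEstimate(gene_a, gene_b, S, N, Sd, Nd, None, None, None, None,
                          frozenset({"zero-sites"}))
    ps = Sd / S
    pn = Nd / N if N > 0 else None
    ks = _jc_correct(ps)
    ka = _jc_correct(pn) if pn is not None else None
    if ks is None:
        flags.add("saturated")
    return KsEstimate(gene_a, gene_b, S, N, Sd, Nd, ps, pn, ks, ka, frozenset(flags))


def codon_align(
    aligned_protein_a: str,
    aligned_protein_b: str,
    cds_a: str,
    cds_b: str,
) -> tuple[str, str]:
    """Thread two CDS through their pairwise protein alignment.

    Each protein alignment column becomes a codon (or ``---`` for a gap).
    The ungapped proteins must equal the translations of their CDS (an
    unstranslated trailing stop codon on the CDS is allowed); mismatches
    raise ``ValueError`` naming the residue position, internal stops raise
    as well.
    """
    out = []
    for aligned, cds, name in (
        (aligned_protein_a, cds_a, "first"),
        (aligned_protein_b, cds_b, "second"),
    ):
        if len(cds) % 3:
            raise ValueError(f"{name} CDS length not divisible by 3")
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]  # trailing stop carries no residue
        residues = [r for r in aligned if r != "-"]
        if len(residues) != len(codons):
            raise ValueError(
                f"{name} protein has {len(residues)} residues but CDS encodes "
                f"{len(codons)} codons"
            )
        for pos, (res, codon) in enumerate(zip(residues, codons), start=1):
            aa = _translate(codon)
            if aa is None:
                raise ValueError(f"internal stop codon at residue {pos} of {name} CDS")
            if res != "X" and aa != res:
                raise ValueError(
                    f"translation mismatch at residue {pos} of {name} sequence: "
                    f"protein {res!r} vs codon {codon} ({aa!r})"
                )
        it = iter(codons)
        out.append("".join(next(it) if r != "-" else "---" for r in aligned))
    return out[0], out[1]


def _align_proteins(a: str, b: str) -> tuple[str, str]:
    from .catalog import _ALIGNER

    alignment = _ALIGNER.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def all_pairs_ks(
    records: list[RGARecord],
    cds_map: dict[str, str] | None = None,
    scope: str = "anchored_only",
) -> list[KsEstimate]:
    """NG86 estimates for every unordered pair of in-scope RGAs.

    In-scope records are non-allele RGAs, restricted to anchored genes under
    ``scope="anchored_only"``.  CDS come from the gene models or from
    ``cds_map``; missing CDS raise ``ValueError`` listing the genes.  The
    output contains exactly ``n*(n-1)/2`` estimates, ordered by gene id.
    Identical CDS pairs short-circuit to a zero-difference estimate.
    """
    if scope not in ("anchored_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    cds_map = cds_map or {}
    in_scope = [
        r
        for r in records
        if not r.is_allele and (scope == "all" or r.gene.anchored)
    ]
    in_scope.sort(key=lambda r: r.gene_id)

    def cds_of(rec: RGARecord) -> str:
        return cds_map.get(rec.gene_id) or rec.gene.cds

    missing = sorted(r.gene_id for r in in_scope if not cds_of(r))
    if missing:
        raise ValueError(f"missing CDS for gene(s): {missing}")

    site_cache: dict[str, tuple[float, float]] = {}

    def seq_sites(cds: str) -> tuple[float, float]:
        if cds not in site_cache:
            S = N = 0.0
            codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
            if codons and codons[-1] in _STOPS:
                codons = codons[:-1]
            for c in codons:
                if _is_clean(c) and c not in _STOPS:
                    s, n = _codon_sites(c)
                    S += s
                    N += n
            site_cache[cds] = (S, N)
        return site_cache[cds]

    estimates: list[KsEstimate] = []
    for i, ra in enumerate(in_scope):
        for rb in in_scope[i + 1 :]:
            ca, cb = cds_of(ra), cds_of(rb)
            if ca == cb:
                S, N = seq_sites(ca)
                flags = frozenset() if S > 0 else frozenset({"zero-sites"})
                estimates.append(
                    KsEstimate(
                        ra.gene_id, rb.gene_id, S, N, 0.0, 0.0,
                        0.0 if S else None, 0.0 if N else None,
                        0.0 if S else None, 0.0 if N else None, flags,
                    )
                )
                continue
            prot_a = ra.gene.protein or _protein_of(ca)
            prot_b = rb.gene.protein or _protein_of(cb)
            aa, ab = _align_proteins(prot_a, prot_b)
            na, nb = codon_align(aa, ab, ca, cb)
            est = ng86(na, nb, ra.gene_id, rb.gene_id)
            estimates.append(est)
    return estimates


def _protein_of(cds: str) -> str:
    codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    out = []
    for c in codons:
        aa = _translate(c) if _is_clean(c) else "X"
        out.append(aa if aa else "X")
    return "".join(out)


def empirical_first_quartile(estimates: list[KsEstimate]) -> float:
    """First quartile of the defined Ks values (for the quartile-mode cutoff)."""
    import numpy as np

    values = [e.ks for e in estimates if e.ks is not None]
    if not values:
        raise ValueError("no defined Ks values")
    return float(np.percentile(values, 25))


def chromosome_links(
    estimates: list[KsEstimate],
    records: list[RGARecord],
    cfg: LinkConfig = LinkConfig(),
) -> list[ChromosomeLink]:
    """Group low-Ks anchored pairs by chromosome pair and apply the rule.

    Self-pairs (both genes on one chromosome) produce intra-chromosome
    links.  A link is accepted iff its qualifying pair count reaches
    ``cfg.min_pairs``.  Only chromosome pairs with at least one qualifying
    pair are reported.
    """
    chrom_of = {r.gene_id: r.gene.chromosome for r in records}
    rows = [
        (est.gene_a, est.gene_b, chrom_of.get(est.gene_a), chrom_of.get(est.gene_b), est.ks)
        for est in estimates
    ]
    return links_from_rows(rows, cfg)


def links_from_rows(
    rows: list[tuple[str, str, str | None, str | None, float | None]],
    cfg: LinkConfig = LinkConfig(),
) -> list[ChromosomeLink]:
    """Apply the connection rule to ``(gene_a, gene_b, chr_a, chr_b, ks)`` rows."""
    buckets: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for gene_a, gene_b, ca, cb, ks in rows:
        if ks is None:
            continue
        if cfg.strict_less:
            if not ks < cfg.ks_threshold:
                continue
        elif not ks <= cfg.ks_threshold:
            continue
        if ca is None or cb is None:
            continue
        key = tuple(sorted((ca, cb)))
        buckets.setdefault(key, []).append(tuple(sorted((gene_a, gene_b))))
    links = [
        ChromosomeLink(
            chr_a=key[0],
            chr_b=key[1],
            n_low_ks_pairs=len(pairs),
            accepted=len(pairs) >= cfg.min_pairs,
            pairs=tuple(sorted(pairs)),
        )
        for key, pairs in sorted(buckets.items())
    ]
    return links
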