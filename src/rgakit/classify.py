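"""Architecture classification of candidate RGAs.

A gene is an RGA iff it carries an NB-ARC (NBS) domain hit.  Its class is
read off the left-to-right order of the first occurrence of each of the
tokens TIR, CC, NBS and LRR along the protein, giving the nine labels
TNL, NLT, TCNL, TCN, TN, CNL, NL, CN and N.  BED and kinase domains are
annotation flags only and never enter the label.

The CC token can come from an explicit CC domain hit or from the built-in
coiled-coil scorer: a COILS-style sliding-window scan of heptad-repeat
propensities whose best window score is converted to a probability with a
two-Gaussian decision rule.
"""

from __future__ import annotations

import math

from .models import (
    CLASS_SUPERCLASS,
    CoilConfig,
    DomainHit,
    GenomeAnnotation,
    RGARecord,
)

__all__ = [
    "coiled_coil_max_prob",
    "classify_architecture",
    "promote_to_rga",
    "HEPTAD_PROPENSITY",
]

# ---------------------------------------------------------------------------
# Coiled-coil scoring
#
# Per-residue propensities for the seven heptad positions a..g, curated to
# reflect the canonical coiled-coil signature: hydrophobic residues favoured
# at the core positions a/d, charged residues at the flanking e/g, proline a
# near-absolute breaker.  Values are relative frequencies (1.0 = indifferent).
HEPTAD_PROPENSITY: dict[str, tuple[float, ...]] = {
    #        a     b     c     d     e     f     g
    "L": (3.20, 0.90, 0.80, 3.00, 0.60, 0.80, 0.70),
    "I": (2.20, 0.60, 0.50, 1.50, 0.40, 0.50, 0.50),
    "V": (1.60, 0.60, 0.50, 1.20, 0.40, 0.50, 0.50),
    "M": (2.20, 1.00, 0.90, 1.80, 0.80, 0.90, 0.80),
    "F": (1.20, 0.50, 0.50, 1.00, 0.40, 0.50, 0.40),
    "A": (1.60, 1.30, 1.30, 1.40, 1.10, 1.30, 1.10),
    "Y": (0.80, 0.70, 0.60, 0.70, 0.50, 0.60, 0.50),
    "W": (0.50, 0.40, 0.40, 0.50, 0.30, 0.40, 0.30),
    "E": (0.70, 1.80, 1.60, 0.60, 2.20, 1.50, 1.90),
    "Q": (0.80, 1.60, 1.50, 0.70, 1.80, 1.30, 1.60),
    "K": (0.60, 1.40, 1.40, 0.50, 1.70, 1.30, 2.00),
    "R": (0.70, 1.40, 1.30, 0.60, 1.60, 1.20, 1.70),
    "D": (0.40, 1.20, 1.10, 0.40, 1.30, 1.10, 1.00),
    "N": (0.60, 1.10, 1.00, 0.60, 1.10, 1.00, 1.00),
    "S": (0.70, 1.00, 1.00, 0.70, 1.00, 1.00, 0.90),
    "T": (0.70, 0.90, 0.90, 0.70, 0.90, 0.90, 0.80),
    "H": (0.60, 0.90, 0.90, 0.60, 1.00, 0.90, 0.90),
    "G": (0.30, 0.60, 0.60, 0.30, 0.60, 0.70, 0.60),
    "C": (0.60, 0.50, 0.50, 0.60, 0.40, 0.50, 0.40),
    "P": (0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05),
}

# Two-Gaussian score distributions (mean, sd) for coiled-coil and globular
# windows, per window size, with a 30:1 prior in favour of globular — the
# same decision rule COILS uses to turn a window score into a probability.
_GAUSSIANS = {
    14: ((1.70, 0.26), (0.84, 0.21)),
    21: ((1.63, 0.24), (0.77, 0.20)),
    28: ((1.58, 0.22), (0.73, 0.19)),
}
_GLOBULAR_PRIOR = 30.0
_DEFAULT_PROPENSITY = 0.60  # X / unknown residues


def _window_score(protein: str, start: int, window: int, frame: int) -> float:
    """Geometric mean of propensities over one window in one heptad frame."""
    log_sum = 0.0
    for k in range(window):
        res = protein[start + k]
        pos = (k + frame) % 7
        prop = HEPTAD_PROPENSITY.get(res, (_DEFAULT_PROPENSITY,) * 7)[pos]
        log_sum += math.log(prop)
    return math.exp(log_sum / window)


def _score_to_prob(score: float, window: int) -> float:
    (cc_mu, cc_sd), (gl_mu, gl_sd) = _GAUSSIANS[window]
    g_cc = math.exp(-0.5 * ((score - cc_mu) / cc_sd) ** 2) / cc_sd
    g_gl = math.exp(-0.5 * ((score - gl_mu) / gl_sd) ** 2) / gl_sd
    return g_cc / (g_cc + _GLOBULAR_PRIOR * g_gl)


def coiled_coil_max_prob(protein: str, cfg: CoilConfig = CoilConfig()) -> float:
    """Best coiled-coil probability over all windows and heptad frames.

    Returns 0.0 for sequences shorter than the window (callers flag these
    with ``short-sequence``).
    """
    protein = protein.upper()
    n = len(protein)
    if n < cfg.window:
        return 0.0
    best = 0.0
    for start in range(n - cfg.window + 1):
        for frame in range(7):
            best = max(best, _window_score(protein, start, cfg.window, frame))
    return _score_to_prob(best, cfg.window)


# ---------------------------------------------------------------------------
# Architecture grammar

_TOKEN = {"TIR": "T", "CC": "C", "NB-ARC": "N", "LRR": "L"}

# Content-based fallback for token orders that do not spell one of the nine
# canonical labels (e.g. a C-terminal CC).  NLT is reachable only through the
# exact order N, L, T.
_BY_CONTENT = {
    frozenset("TCNL"): "TCNL",
    frozenset("TNL"): "TNL",
    frozenset("TCN"): "TCN",
    frozenset("TN"): "TN",
    frozenset("CNL"): "CNL",
    frozenset("NL"): "NL",
    frozenset("CN"): "CN",
    frozenset("N"): "N",
}


def classify_architecture(
    hits: list[DomainHit], has_cc: bool = False
) -> tuple[str | None, frozenset[str]]:
    """Label one gene from its ordered domain hits.

    Returns ``(label, flags)``; the label is ``None`` when no NB-ARC hit is
    present (the gene is not an RGA).  ``has_cc`` injects a CC token from
    coiled-coil scoring; since a scored CC carries no interval of its own it
    is placed immediately before the NBS token, matching the N-terminal
    position of coiled coils in the canonical architectures.

    Flags: ``multi-NBS`` (classified on the first NB-ARC hit), ``BED``,
    ``kinase``, ``noncanonical-order`` (label recovered by domain content
    because the observed order spells no canonical name).
    """
    flags: set[str] = set()
    hits = sorted(hits, key=lambda h: (h.aa_start, h.aa_end, h.domain))
    if sum(1 for h in hits if h.domain == "NB-ARC") == 0:
        return None, frozenset()
    if sum(1 for h in hits if h.domain == "NB-ARC") > 1:
        flags.add("multi-NBS")
        first_nbs = next(h for h in hits if h.domain == "NB-ARC")
        hits = [h for h in hits if h.domain != "NB-ARC" or h is first_nbs]
    for annot in ("BED", "kinase"):
        if any(h.domain == annot for h in hits):
            flags.add(annot)

    order: list[str] = []
    for h in hits:
        tok = _TOKEN.get(h.domain)
        if tok and tok not in order:
            order.append(tok)
    if has_cc and "C" not in order:
        order.insert(order.index("N"), "C")

    label = "".join(order)
    if label not in CLASS_SUPERCLASS:
        label = _BY_CONTENT[frozenset(order)]
        flags.add("noncanonical-order")
    return label, frozenset(flags)


def promote_to_rga(
    annotation: GenomeAnnotation,
    hits: dict[str, list[DomainHit]],
    cfg: CoilConfig = CoilConfig(),
) -> list[RGARecord]:
    """Promote every gene with an NB-ARC hit to an :class:`RGARecord`.

    The CC token is contributed either by an explicit CC hit or by
    ``coiled_coil_max_prob(protein) >= cfg.threshold``.  Hits referencing
    unknown genes raise ``ValueError`` listing the offending ids.
    """
    unknown = sorted(g for g in hits if g not in annotation)
    if unknown:
        raise ValueError(f"domain hits reference unknown gene(s): {unknown}")
    records: list[RGARecord] = []
    for gene in annotation.genes:
        gene_hits = hits.get(gene.gene_id, [])
        if not any(h.domain == "NB-ARC" for h in gene_hits):
            continue
        coil_prob = 0.0
        extra: set[str] = set()
        if not any(h.domain == "CC" for h in gene_hits):
            if gene.protein and len(gene.protein) >= cfg.window:
                coil_prob = coiled_coil_max_prob(gene.protein, cfg)
            elif gene.protein:
                extra.add("short-sequence")
        label, flags = classify_architecture(gene_hits, has_cc=coil_prob >= cfg.threshold)
        assert label is not None
        records.append(
            RGARecord(
                gene=gene,
                rga_class=label,
                coil_prob=coil_prob,
                flags=frozenset(flags | extra),
            )
        )
    return records
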