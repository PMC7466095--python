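"""Protein similarity, best-bidirectional-hit extraction and relationship typing.

Orthology between the replaced (background, cultivated) and introgressed
(donor, wild) gene sets is typed operationally, the way introgression studies
report it:

* **BBH** — reciprocal best hit across species, the working definition of
  one-to-one orthology;
* **homology** — a best hit exists above threshold but reciprocity fails;
* **species-specific** — no hit above threshold in the other species' gene
  set for the compared region;
* **duplicated** — two or more genes of one species share the same single
  best partner in the other (a one-to-many group, i.e. a probable duplication
  in the many-side species).

Full inparalog clustering is deliberately not implemented; the four types
above are the distinctions regional introgression accounting actually uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import HitRecord

log = logging.getLogger(__name__)

RELATION_KINDS = (
    "BBH",
    "homology",
    "species_specific_donor",
    "species_specific_background",
    "duplicated_donor",
    "duplicated_background",
)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

# Karlin-Altschul parameters for the e-value proxy (gapped BLOSUM62 defaults)
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class OrthologyRelation:
    """Typed link between a donor gene and a background gene.

    A species-specific relation has exactly one empty id. A non-specific
    relation normally names both genes; an empty partner there marks a
    partner a source table left unlisted (kept as printed, never invented).
    Duplicated relations come in groups sharing one partner.
    """

    donor_gene_id: str
    background_gene_id: str
    relation: str
    score: float = 0.0
    evalue: float = math.inf

    def __post_init__(self):
        if self.relation not in RELATION_KINDS:
            raise ValueError(f"unknown relation kind {self.relation!r}")
        one_empty = (self.donor_gene_id == "") != (self.background_gene_id == "")
        if self.relation.startswith("species_specific") and not one_empty:
            raise ValueError(
                "species-specific relations must leave exactly one gene id "
                f"empty (got {self})"
            )


# ---------------------------------------------------------------------------
# pairwise protein alignment


def align_proteins(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, float, float]:
    """Smith-Waterman local alignment with affine gaps.

    Returns ``(score, identity_pct, evalue)`` where the e-value is a
    Karlin-Altschul proxy ``K * m * n * exp(-lambda * S)`` with fixed default
    parameters — adequate for ranking at desk scale, not a database e-value.
    For real data the supported path is ingesting an external 12-column hit
    table instead.
    """
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {name} contains invalid residues {sorted(bad)}"
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = aligner.align(seq_a, seq_b)
    best = aln[0]
    score = float(best.score)
    counts = best.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity_pct = 100.0 * counts.identities / ncols if ncols else 0.0
    evalue = _KA_K * len(seq_a) * len(seq_b) * math.exp(-_KA_LAMBDA * score)
    return score, identity_pct, evalue


def hits_from_proteins(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    **align_kwargs,
) -> list[HitRecord]:
    """All-vs-all alignment of two protein sets, emitted in both directions."""
    hits: list[HitRecord] = []
    for qid, qseq in proteins_a.items():
        for sid, sseq in proteins_b.items():
            score, ident, ev = align_proteins(qseq, sseq, **align_kwargs)
            for q, s, lq, ls in ((qid, sid, qseq, sseq), (sid, qid, sseq, qseq)):
                hits.append(
                    HitRecord(
                        query_id=q, subject_id=s, identity_pct=ident,
                        aln_length=min(len(lq), len(ls)), mismatches=0,
                        gap_opens=0, qstart=1, qend=len(lq), sstart=1,
                        send=len(ls), evalue=ev, score=score,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# best hits


def _best_partner(
    hits: Sequence[HitRecord], evalue_threshold: float
) -> dict[str, HitRecord]:
    """Best subject per query; ties broken by score, then lexicographic id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > evalue_threshold or h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
        elif (h.score, ) == (cur.score, ) and h.subject_id != cur.subject_id:
            chosen = min(h, cur, key=lambda x: x.subject_id)
            log.info(
                "best-hit tie for %s between %s and %s (score %.1f); "
                "keeping %s", h.query_id, cur.subject_id, h.subject_id,
                h.score, chosen.subject_id,
            )
            best[h.query_id] = chosen
        elif h.score > cur.score:
            best[h.query_id] = h
    return best


def best_bidirectional_hits(
    hits: Sequence[HitRecord], evalue_threshold: float = 1e-10
) -> list[tuple[str, str, float, float]]:
    """Reciprocal best hit pairs ``(a, b, score, evalue)`` with ``a < b``."""
    best = _best_partner(hits, evalue_threshold)
    pairs = []
    for q, h in best.items():
        mate = best.get(h.subject_id)
        if mate is not None and mate.subject_id == q and q < h.subject_id:
            pairs.append(
                (q, h.subject_id, h.score, max(h.evalue, mate.evalue))
            )
    return sorted(pairs)


# ---------------------------------------------------------------------------
# relationship typing


def classify_relationships(
    hits: Sequence[HitRecord],
    donor_genes: Iterable[str],
    background_genes: Iterable[str],
    evalue_threshold: float = 1e-10,
) -> list[OrthologyRelation]:
    """Type every gene of the two regional sets into one relation group.

    Precedence: one-to-many (duplicated) groups are extracted before BBH
    pairs, so a duplicated copy that happens to be a mutual best hit is still
    reported with its group; then BBH, then species-specific (no qualifying
    hit in either direction), then homology for whatever remains.
    Every input gene ends up in exactly one relation group as focal gene.
    """
    donor = sorted(set(donor_genes))
    background = sorted(set(background_genes))
    donor_set, background_set = set(donor), set(background)

    def side(g: str) -> str | None:
        if g in donor_set:
            return "donor"
        if g in background_set:
            return "background"
        return None

    cross = [
        h for h in hits
        if h.evalue <= evalue_threshold
        and side(h.query_id) is not None
        and side(h.subject_id) is not None
        and side(h.query_id) != side(h.subject_id)
    ]
    best = _best_partner(cross, evalue_threshold)
    has_hit = {h.query_id for h in cross} | {h.subject_id for h in cross}

    relations: list[OrthologyRelation] = []
    covered: set[str] = set()

    def rel(d: str, b: str, kind: str, score=0.0, ev=math.inf):
        relations.append(OrthologyRelation(d, b, kind, score, ev))

    # 1. one-to-many groups
    pointers: dict[str, list[str]] = {}
    for q, h in best.items():
        pointers.setdefault(h.subject_id, []).append(q)
    for partner, members in sorted(pointers.items()):
        if len(members) < 2:
            continue
        kind = (
            "duplicated_donor" if side(partner) == "background"
            else "duplicated_background"
        )
        for m in sorted(members):
            h = best[m]
            if kind == "duplicated_donor":
                rel(m, partner, kind, h.score, h.evalue)
            else:
                rel(partner, m, kind, h.score, h.evalue)
        covered.update(members)
        covered.add(partner)

    # 2. reciprocal best hits
    for a, b, score, ev in best_bidirectional_hits(cross, evalue_threshold):
        if a in covered or b in covered:
            continue
        d, bg = (a, b) if side(a) == "donor" else (b, a)
        rel(d, bg, "BBH", score, ev)
        covered.update((a, b))

    # 3. species-specific: no qualifying hit in either direction
    for g in donor:
        if g not in covered and g not in has_hit:
            rel(g, "", "species_specific_donor")
            covered.add(g)
    for g in background:
        if g not in covered and g not in has_hit:
            rel("", g, "species_specific_background")
            covered.add(g)

    # 4. homology for the remainder (unidirectional best match)
    def best_match(g: str) -> HitRecord:
        if g in best:
            return best[g]
        incoming = [h for h in cross if h.subject_id == g]
        return max(incoming, key=lambda h: (h.score, h.query_id))

    for g in donor + background:
        if g in covered:
            continue
        h = best_match(g)
        partner = h.subject_id if h.query_id == g else h.query_id
        d, bg = (g, partner) if side(g) == "donor" else (partner, g)
        rel(d, bg, "homology", h.score, h.evalue)
        covered.add(g)
        if partner not in covered:
            covered.add(partner)

    return relations
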