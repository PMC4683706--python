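"""Orthology by reciprocal best hits and protein→codon alignment
processing.

One species (default the mouse) acts as hub: every other proteome is
scored against it, reciprocal best hits give 1:1 pairs, and hub genes hit
in every species become 1:1:...:1 ortholog tuples. Protein alignments are
back-translated to codon alignments against the source CDS, trimmed with
a conserved-block rule, and length-filtered.

The pairwise scorer is pluggable; the default is Smith-Waterman local
alignment with BLOSUM62 and gap open/extend 11/1, which preserves the
only property reciprocal-best-hit orthology needs — the score ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alignment import AlignmentError, CodonAlignment
from .codon_model import STANDARD_CODE, GeneticCode
from .io_formats import SequenceSet

__all__ = [
    "ScoreMatrix",
    "Rejection",
    "BacktranslateError",
    "blosum62_scorer",
    "score_pairs",
    "reciprocal_best_hits",
    "intersect_orthologues",
    "pass_through_align",
    "backtranslate_alignment",
    "trim_and_filter",
]


@dataclass
class ScoreMatrix:
    """Dense pairwise protein alignment scores between two species."""

    species_a: str
    species_b: str
    ids_a: list[str]
    ids_b: list[str]
    scores: np.ndarray  # shape (len(ids_a), len(ids_b)), raw SW scores

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.ids_a), len(self.ids_b)):
            raise ValueError("score matrix shape does not match id lists")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite alignment scores")


@dataclass
class Rejection:
    """A gene dropped by a filter, with the reason recorded for the log."""

    reason: str  # in_frame_stop | too_short_after_trim | translation_mismatch
    detail: str = ""


class BacktranslateError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason
        self.detail = detail


# ---------------------------------------------------------------------------
# pairwise scoring and RBH
# ---------------------------------------------------------------------------


def blosum62_scorer(gap_open: float = 11.0, gap_extend: float = 1.0):
    """Local-alignment scoring contract: f(seq_a, seq_b) -> float."""
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
    )

    def score(a: str, b: str) -> float:
        return float(aligner.score(a, b))

    return score


def score_pairs(
    prot_a: SequenceSet,
    prot_b: SequenceSet,
    scorer=None,
    species_a: str = "A",
    species_b: str = "B",
) -> ScoreMatrix:
    """Score every protein of one species against every protein of another."""
    if len(prot_a) == 0 or len(prot_b) == 0:
        raise ValueError("empty sequence set")
    for seqs in (prot_a, prot_b):
        for name, seq in seqs.items():
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
    scorer = scorer or blosum62_scorer()
    ids_a, ids_b = prot_a.names(), prot_b.names()
    scores = np.empty((len(ids_a), len(ids_b)))
    for i, ga in enumerate(ids_a):
        sa = prot_a[ga]
        for j, gb in enumerate(ids_b):
            scores[i, j] = scorer(sa, prot_b[gb])
    return ScoreMatrix(species_a, species_b, ids_a, ids_b, scores)


def reciprocal_best_hits(scores: ScoreMatrix) -> list[tuple[str, str]]:
    """1:1 pairs that are each other's unique top hit.

    A gene whose best score is tied between two partners is disqualified
    outright — no arbitrary winner is picked.
    """
    S = scores.scores
    if S.size == 0:
        return []

    def unique_argmax(v: np.ndarray) -> int | None:
        m = v.max()
        hits = np.flatnonzero(v == m)
        return int(hits[0]) if len(hits) == 1 else None

    best_b_for_a = [unique_argmax(S[i, :]) for i in range(S.shape[0])]
    best_a_for_b = [unique_argmax(S[:, j]) for j in range(S.shape[1])]
    pairs = []
    for i, j in enumerate(best_b_for_a):
        if j is not None and best_a_for_b[j] == i:
            pairs.append((scores.ids_a[i], scores.ids_b[j]))
    return pairs


def intersect_orthologues(
    hub_pairs: dict[str, list[tuple[str, str]]], hub: str = "mouse"
) -> list[dict[str, str]]:
    """Hub genes with a reciprocal best hit in *every* other species.

    ``hub_pairs`` maps each non-hub species to its (hub_gene, species_gene)
    RBH list. Returns one {species: gene} tuple per surviving hub gene, in
    hub-gene order.
    """
    if not hub_pairs:
        raise ValueError("no species RBH lists supplied")
    maps = {sp: dict(pairs) for sp, pairs in hub_pairs.items()}
    tuples = []
    all_hub_genes = sorted({g for m in maps.values() for g in m})
    for hub_gene in all_hub_genes:
        if all(hub_gene in m for m in maps.values()):
            row = {hub: hub_gene}
            row.update({sp: m[hub_gene] for sp, m in maps.items()})
            tuples.append(row)
    return tuples


# ---------------------------------------------------------------------------
# alignment construction
# ---------------------------------------------------------------------------


def pass_through_align(proteins: dict[str, str]) -> dict[str, str]:
    """The identity "aligner" for indel-free sequences: requires equal
    lengths and returns the input unchanged."""
    lengths = {len(s) for s in proteins.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"pass-through aligner needs equal-length proteins, got {sorted(lengths)}"
        )
    return dict(proteins)


def backtranslate_alignment(
    protein_aln: dict[str, str],
    cds_by_taxon: dict[str, str],
    code: GeneticCode = STANDARD_CODE,
    source_genes: list[str] | None = None,
) -> CodonAlignment:
    """Thread each CDS through its aligned protein (gap → ``---``).

    The ungapped protein must equal the CDS translation (a trailing stop
    codon on the CDS is stripped); any internal stop codon rejects the
    alignment. Raises :class:`BacktranslateError` with reason
    ``translation_mismatch`` or ``in_frame_stop``.
    """
    rows: dict[str, str] = {}
    for taxon, prot in protein_aln.items():
        cds = cds_by_taxon[taxon].upper()
        if len(cds) % 3 != 0:
            raise BacktranslateError(
                "translation_mismatch", f"{taxon}: CDS length not divisible by 3"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if codon in code.stop_codons:
                raise BacktranslateError(
                    "in_frame_stop", f"{taxon}: stop codon {codon} at codon {pos}"
                )
        ungapped = prot.replace("-", "")
        if len(ungapped) != len(codons):
            raise BacktranslateError(
                "translation_mismatch",
                f"{taxon}: protein length {len(ungapped)} vs {len(codons)} codons",
            )
        out = []
        k = 0
        for pos, aa in enumerate(prot):
            if aa == "-":
                out.append("---")
                continue
            codon = codons[k]
            translated = code.codon_to_aa.get(codon, "X")
            if translated != aa and aa != "X" and translated != "X":
                raise BacktranslateError(
                    "translation_mismatch",
                    f"{taxon}: codon {codon} is {translated}, protein says {aa} "
                    f"at position {pos}",
                )
            out.append(codon)
            k += 1
        rows[taxon] = "".join(out)
    try:
        return CodonAlignment(seqs=rows, source_genes=source_genes or [])
    except AlignmentError as exc:  # e.g. stop slipped through as invariant
        raise BacktranslateError("in_frame_stop", str(exc)) from exc


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def trim_and_filter(
    codon_aln: CodonAlignment,
    min_bp: int = 150,
    max_gap_frac: float = 0.0,
    min_block: int = 3,
    min_unit: str = "bp",
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment | Rejection:
    """Conserved-block trimming at codon granularity, then a length floor.

    A codon column is *conserved* when its gap fraction is at most
    ``max_gap_frac`` and at least half the taxa share one amino acid.
    Maximal runs of at least ``min_block`` consecutive conserved columns
    are kept; everything else is dropped. The result is a
    :class:`Rejection` (reason ``too_short_after_trim``) when the kept
    length falls below ``min_bp`` base pairs (or codons when
    ``min_unit="codon"``).
    """
    n_taxa = len(codon_aln.taxa)
    L = codon_aln.n_codons
    conserved = np.zeros(L, dtype=bool)
    for i in range(L):
        col = [codon_aln.codon(t, i) for t in codon_aln.taxa]
        n_gap = sum(1 for c in col if not set(c) <= set("ACGT"))
        if n_gap > max_gap_frac * n_taxa:
            continue
        aas = [code.codon_to_aa.get(c) for c in col if set(c) <= set("ACGT")]
        if not aas:
            continue
        top = max(aas.count(a) for a in set(aas))
        conserved[i] = top >= n_taxa / 2.0
    keep: list[int] = []
    run: list[int] = []
    for i in range(L + 1):
        if i < L and conserved[i]:
            run.append(i)
            continue
        if len(run) >= min_block:
            keep.extend(run)
        run = []
    kept_len = len(keep)
    threshold_codons = min_bp / 3.0 if min_unit == "bp" else float(min_bp)
    if kept_len < threshold_codons:
        return Rejection(
            "too_short_after_trim",
            f"{kept_len} codons kept (< {threshold_codons:g})",
        )
    if kept_len == L:
        return codon_aln
    seqs = {
        t: "".join(codon_aln.seqs[t][3 * i : 3 * (i + 1)] for i in keep)
        for t in codon_aln.taxa
    }
    return CodonAlignment(seqs=seqs, source_genes=list(codon_aln.source_genes))
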