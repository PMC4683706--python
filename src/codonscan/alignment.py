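"""Codon alignments: the unit every likelihood computation consumes.

A :class:`CodonAlignment` holds equal-length, in-frame, stop-free codon
sequences over a set of named taxa. Codons containing ``N`` or gap
characters are treated as fully ambiguous downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CodonAlignment", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when sequences violate the codon-alignment invariants."""


@dataclass
class CodonAlignment:
    """Aligned codon sequences (nucleotide strings with ``-`` gaps).

    Invariants: all sequences have the same length, divisible by 3; no
    sequence contains an in-frame stop codon (a codon made only of
    A/C/G/T that is TAA, TAG or TGA).
    """

    seqs: dict[str, str]
    source_genes: list[str] = field(default_factory=list)

    _STOPS = frozenset({"TAA", "TAG", "TGA"})

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("empty alignment")
        self.seqs = {t: s.upper() for t, s in self.seqs.items()}
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        for taxon, seq in self.seqs.items():
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if codon in self._STOPS:
                    raise AlignmentError(
                        f"in-frame stop codon {codon} in {taxon!r} at codon {i // 3}"
                    )

    # -- basic views -------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.seqs.values()))) // 3

    def codon(self, taxon: str, i: int) -> str:
        return self.seqs[taxon][3 * i : 3 * (i + 1)]

    def __len__(self) -> int:
        return self.n_codons

    # -- numeric view ------------------------------------------------------

    def state_matrix(self, codon_index: dict[str, int], taxa_order: list[str]) -> np.ndarray:
        """Integer codon states, shape (n_taxa, n_codons); -1 marks a codon
        containing a gap or ambiguity character (fully ambiguous state)."""
        out = np.full((len(taxa_order), self.n_codons), -1, dtype=np.int16)
        for row, taxon in enumerate(taxa_order):
            seq = self.seqs[taxon]
            for i in range(self.n_codons):
                out[row, i] = codon_index.get(seq[3 * i : 3 * (i + 1)], -1)
        return out

    # -- construction helpers ---------------------------------------------

    @classmethod
    def concatenate(cls, alignments: list["CodonAlignment"]) -> "CodonAlignment":
        """Concatenate alignments sharing one taxon set, in the given order."""
        if not alignments:
            raise AlignmentError("nothing to concatenate")
        taxa = set(alignments[0].taxa)
        for aln in alignments[1:]:
            if set(aln.taxa) != taxa:
                raise AlignmentError("mismatched taxon sets in concatenation")
        order = sorted(taxa)
        seqs = {t: "".join(a.seqs[t] for a in alignments) for t in order}
        genes = [g for a in alignments for g in (a.source_genes or [])]
        return cls(seqs=seqs, source_genes=genes)

    def drop_all_gap_columns(self) -> "CodonAlignment":
        """Remove codon columns that are gap/ambiguous in every taxon."""
        keep = []
        for i in range(self.n_codons):
            col = [self.codon(t, i) for t in self.taxa]
            if any(set(c) <= set("ACGT") for c in col):
                keep.append(i)
        if len(keep) == self.n_codons:
            return self
        seqs = {
            t: "".join(self.seqs[t][3 * i : 3 * (i + 1)] for i in keep)
            for t in self.taxa
        }
        return CodonAlignment(seqs=seqs, source_genes=list(self.source_genes))
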