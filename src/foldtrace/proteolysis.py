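"""In-silico tryptic digestion, residue coverage and peptide span bookkeeping.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); cleavage is
commonly suppressed when the following residue is proline.  Whether a DIA
search observes the proline-suppressed form, the cleaved form, or both
depends on the actual enzyme kinetics, so the digest can be built with the
proline rule on, off, or as the union of both peptide universes ("both") —
the mode needed to represent observing both LFFSWTR and LFFSWTRPILR in the
CFTR N terminus (R21 is followed by P22).

All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: N-terminal 60 residues of human CFTR, covering the lasso domain with
#: helix Lh1 (~residues 11-29), tryptic site K14 and the overlapping
#: peptides LFFSWTR (15-21) and LFFSWTRPILR (15-25).
CFTR_NTERM = "MQRSPLEKASVVSKLFFSWTRPILRKGYRQRLELSDIYQIPSVDSADNLSEKLEREWDRE"


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its 1-based inclusive span on the protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    proline_rule: bool


@dataclass(frozen=True)
class ProteinDigest:
    sequence: str
    peptides: tuple[Peptide, ...]
    max_missed_cleavages: int
    proline_rule: bool | str

    def spans(self) -> list[tuple[int, int]]:
        return [(p.start, p.end) for p in self.peptides]

    def find(self, peptide_sequence: str) -> Peptide:
        """First digest peptide with the given sequence (lowest start)."""
        for p in sorted(self.peptides, key=lambda q: (q.start, q.end)):
            if p.sequence == peptide_sequence:
                return p
        raise KeyError(f"{peptide_sequence!r} not in digest")

    def __contains__(self, peptide_sequence: str) -> bool:
        return any(p.sequence == peptide_sequence for p in self.peptides)


def _validate_sequence(sequence: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS:
            raise ValidationError(
                f"invalid residue {ch!r} at position {i + 1} (1-based)"
            )
    if not sequence:
        raise ValidationError("empty protein sequence")


def cleavage_sites(sequence: str, proline_rule: bool) -> list[int]:
    """1-based positions of K/R after which trypsin cleaves."""
    sites = []
    for i, ch in enumerate(sequence[:-1]):  # no cleavage after last residue
        if ch in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def _digest_one_rule(
    sequence: str, max_missed: int, proline_rule: bool
) -> list[Peptide]:
    bounds = [0] + cleavage_sites(sequence, proline_rule) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for mc in range(max_missed + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(
                Peptide(sequence[start - 1 : end], start, end, mc, proline_rule)
            )
    return peptides


def digest(
    sequence: str,
    max_missed_cleavages: int = 0,
    proline_rule: bool | str = True,
) -> ProteinDigest:
    """Tryptic digest with 0..max_missed_cleavages missed cleavages.

    ``proline_rule`` may be True, False or ``"both"`` (union of the two
    peptide universes, deduplicated by span).
    """
    _validate_sequence(sequence)
    if max_missed_cleavages < 0:
        raise ValidationError("max_missed_cleavages must be >= 0")
    if proline_rule not in (True, False, "both"):
        raise ValidationError("proline_rule must be True, False or 'both'")
    if proline_rule == "both":
        seen: dict[tuple[int, int], Peptide] = {}
        for rule in (True, False):
            for p in _digest_one_rule(sequence, max_missed_cleavages, rule):
                seen.setdefault((p.start, p.end), p)
        peptides = tuple(sorted(seen.values(), key=lambda p: (p.start, p.end)))
    else:
        peptides = tuple(
            _digest_one_rule(sequence, max_missed_cleavages, proline_rule)
        )
    return ProteinDigest(sequence, peptides, max_missed_cleavages, proline_rule)


def coverage(
    spans: Iterable[tuple[int, int]] | Sequence[Peptide], protein_length: int
) -> float:
    """Percent of protein residues covered by the union of peptide spans."""
    if protein_length <= 0:
        raise ValidationError("protein_length must be > 0")
    covered: set[int] = set()
    for item in spans:
        start, end = (item.start, item.end) if isinstance(item, Peptide) else item
        if start < 1 or end > protein_length or start > end:
            raise ValidationError(
                f"span ({start}, {end}) outside protein of length {protein_length}"
            )
        covered.update(range(start, end + 1))
    return 100.0 * len(covered) / protein_length
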