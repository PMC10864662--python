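"""In silico digestion and peptide-to-protein context mapping.

Cleavage is specified by a P1 residue set (cut C-terminal to these residues),
optionally blocked by the identity of the P1' residue — trypsin/P is the
unblocked {K,R} rule. Positions are 1-based; ``cleavage_sites`` returns
positions *i* such that the bond between residues *i* and *i+1* is cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .io_formats import CANONICAL_RESIDUES, ProteinRecord


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "p1_residues", frozenset(self.p1_residues))
        object.__setattr__(self, "blocked_p1prime", frozenset(self.blocked_p1prime))
        if not self.p1_residues:
            raise ValueError("p1_residues must be nonempty")
        bad = (self.p1_residues | self.blocked_p1prime) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residues in rule {self.name}: {sorted(bad)}")


#: Trypsin/P: cleaves after K or R with no proline block (search-engine default here).
TRYPSIN_P = ProteaseRule("trypsin_p", frozenset("KR"))
#: Trypsin with the classical proline block.
TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
#: Elastase-like specificity of ELANE/PRTN3: after Ala/Ile/Val, not Leu.
ELANE_PRTN3_RULE = ProteaseRule("elane_prtn3", frozenset("AIV"))
#: Cathepsin G: preferentially after Trp/Leu/Phe/Tyr.
CTSG_RULE = ProteaseRule("ctsg", frozenset("WLFY"))


@dataclass(frozen=True)
class DigestPeptide:
    peptide: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    nterm_is_protein_terminus: bool
    cterm_is_protein_terminus: bool


SequenceLike = Union[str, ProteinRecord]


def _seq(protein: SequenceLike) -> str:
    return protein.sequence if isinstance(protein, ProteinRecord) else protein


def cleavage_sites(protein: SequenceLike, rule: ProteaseRule) -> list[int]:
    """Internal cleavage positions (cut after position i), strictly within the chain."""
    seq = _seq(protein)
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in rule.p1_residues and seq[i] not in rule.blocked_p1prime
    ]


def digest(
    protein: SequenceLike,
    rule: ProteaseRule,
    max_missed: int = 0,
    length_range: tuple[int, float] = (1, float("inf")),
) -> list[DigestPeptide]:
    """Enumerate digest peptides with up to ``max_missed`` internal sites.

    Output is ordered by (start, end). ``length_range`` filters on peptide
    length inclusively.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"invalid length_range {length_range}")
    seq = _seq(protein)
    bounds = [0] + cleavage_sites(seq, rule) + [len(seq)]
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            if not (lo <= end - start + 1 <= hi):
                continue
            out.append(
                DigestPeptide(
                    peptide=seq[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                    nterm_is_protein_terminus=start == 1,
                    cterm_is_protein_terminus=end == len(seq),
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def map_peptide(
    peptide: str,
    proteins: Union[Mapping[str, ProteinRecord], Iterable[ProteinRecord]],
) -> list[tuple[str, int, int, str, str]]:
    """All exact occurrences of ``peptide`` with flanking residues.

    Returns (accession, start, end, preceding, following) tuples ordered by
    accession then start; ``-`` flanks a protein terminus. Overlapping
    occurrences are all reported.
    """
    if not peptide:
        raise ValueError("peptide must be nonempty")
    if isinstance(proteins, Mapping):
        records = list(proteins.values())
    else:
        records = list(proteins)
    hits = []
    for rec in sorted(records, key=lambda r: r.accession):
        seq = rec.sequence
        pos = seq.find(peptide)
        while pos != -1:
            start, end = pos + 1, pos + len(peptide)
            preceding = seq[pos - 1] if pos > 0 else "-"
            following = seq[end] if end < len(seq) else "-"
            hits.append((rec.accession, start, end, preceding, following))
            pos = seq.find(peptide, pos + 1)
    return hits
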