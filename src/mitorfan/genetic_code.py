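"""Genetic-code handling for mitochondrial ORFan analysis.

Everything downstream depends on correct stop-codon identification under
the invertebrate mitochondrial code (NCBI translation table 5), where the
only stops are TAA and TAG, TGA codes tryptophan, ATA methionine, and
AGA/AGG serine.  The :class:`GeneticCode` wrapper is pluggable to any NCBI
table id, but table 5 is the default throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the stop-codon set for one NCBI table.

    Attributes
    ----------
    table_id : int
        NCBI translation table identifier (5 = invertebrate mitochondrial).
    codon_to_aa : dict
        64-entry map from codon to one-letter amino acid; stop codons map
        to ``'*'``.
    stops : frozenset
        The stop codons of the table.
    """

    table_id: int = 5
    codon_to_aa: Dict[str, str] = field(default_factory=dict)
    stops: FrozenSet[str] = frozenset()

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"table {table_id} does not cover 64 codons")
        return cls(table_id=table_id, codon_to_aa=mapping,
                   stops=frozenset(table.stop_codons))

    @property
    def sense_codons(self) -> List[str]:
        return [c for c in sorted(self.codon_to_aa) if c not in self.stops]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def aa(self, codon: str) -> str:
        """Amino acid for one codon; codons containing N translate to X."""
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            if "N" in codon and all(b in "ACGTN" for b in codon):
                return "X"
            raise ValueError(f"invalid codon {codon!r}") from None


#: Module-level default: the invertebrate mitochondrial code.
TABLE5 = GeneticCode.from_ncbi(5)


def translate(seq: str, code: GeneticCode = TABLE5) -> str:
    """Translate a coding sequence, one letter per codon, stops as '*'.

    Parameters
    ----------
    seq : str
        Nucleotide sequence over {A,C,G,T,N}; length must be a multiple
        of three.  Codons containing N yield 'X'.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return "".join(code.aa(seq[i:i + 3]) for i in range(0, len(seq), 3))


def stop_positions(sequence: str, frame: int, strand: str = "+",
                   code: GeneticCode = TABLE5,
                   circular: bool = False) -> List[int]:
    """0-based forward-strand start positions of in-frame stop codons.

    For the minus strand the frame is counted on the reverse complement,
    and the returned positions are the forward-strand coordinates of each
    stop codon's first (leftmost) base.  On circular sequences codons
    spanning the origin are included; positions are reported mod L.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = sequence.upper()
    n = len(seq)
    work = seq if strand == "+" else revcomp(seq)
    scan = work + work if circular else work
    limit = n if circular else n - 2
    out = []
    for p in range(frame, max(limit, 0), 3):
        codon = scan[p:p + 3]
        if len(codon) == 3 and code.is_stop(codon):
            out.append(p % n)
    if strand == "-":
        # leftmost base of the codon on the forward strand
        out = sorted((n - (p % n) - 3) % n for p in out)
    return out
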