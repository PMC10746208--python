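"""Core sequence containers and validation.

A :class:`GenomeSequence` is a single contig (chromosome or plasmid) with an
explicit topology; bacterial chromosomes are circular, so k-mer windows are
allowed to wrap across the origin.  A :class:`CodingSequence` is an in-frame
protein-coding sequence read in frame 0, validated against a codon table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .errors import AlphabetError, CdsValidationError

GENOME_ALPHABET = frozenset("ACGTN")
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Topology(str, enum.Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class StrandMode(str, enum.Enum):
    FORWARD = "forward"
    BOTH = "both"


class OrientationMode(str, enum.Enum):
    FORWARD_ONLY = "forward_only"
    BOTH = "both"


@dataclass
class GenomeSequence:
    """A contig: identifier, upper-case base string, and topology.

    Bases outside ``{A, C, G, T, N}`` are rejected at construction time.
    """

    id: str
    seq: str
    topology: Topology = Topology.CIRCULAR

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        self.topology = Topology(self.topology)
        bad = set(self.seq) - GENOME_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal characters {sorted(bad)}; "
                "genome sequences must be over A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CodingSequence:
    """An in-frame CDS, frame 0, validated against an NCBI codon table.

    Parameters
    ----------
    id, seq
        Record identifier and base string (upper-cased; A/C/G/T only — a CDS
        with ambiguous bases cannot be recoded safely).
    codon_table
        NCBI translation table id; default 11 (bacterial, archaeal, plastid).
    require_stop
        When true (default) the final codon must be a stop codon and no
        internal codon may be a stop.  Turn off for CDS fragments.
    """

    id: str
    seq: str
    codon_table: int = 11
    require_stop: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal characters {sorted(bad)}; "
                "coding sequences must be over A/C/G/T"
            )
        if len(self.seq) == 0 or len(self.seq) % 3 != 0:
            raise CdsValidationError(
                f"record {self.id!r}: length {len(self.seq)} is not a "
                "positive multiple of 3"
            )
        table = CodonTable.unambiguous_dna_by_id[self.codon_table]
        stops = set(table.stop_codons)
        codons = self.codons()
        internal = codons[:-1] if self.require_stop else codons
        for i, codon in enumerate(internal):
            if codon in stops:
                raise CdsValidationError(
                    f"record {self.id!r}: internal stop codon {codon} "
                    f"at codon index {i}"
                )
        if self.require_stop and codons[-1] not in stops:
            raise CdsValidationError(
                f"record {self.id!r}: final codon {codons[-1]} is not a stop"
            )

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def translate(self) -> str:
        """Amino-acid string with '*' for stop codons."""
        return translate_cds(self.seq, self.codon_table)

    def __len__(self) -> int:
        return len(self.seq)


def translate_cds(seq: str, codon_table: int = 11) -> str:
    """Codon-by-codon translation; stop codons become '*'."""
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    stops = set(table.stop_codons)
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append("*" if codon in stops else table.forward_table[codon])
    return "".join(out)
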