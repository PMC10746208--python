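"""Readers and writers: FASTA, motif TSV, substitution ledger, residual BED.

All coordinates written are 0-based half-open (BED convention); FASTA output
wraps at 70 columns.  The motif TSV (columns ``motif k observed expected z``)
is the interchange format between the scanner and the recoder; the recoder
also accepts a bare one-motif-per-line file.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .errors import EmptyBlacklistError, FastaParseError, MotifTableError
from .kmer_stats import MotifList
from .recoder import MotifHit, Substitution
from .sequences import CodingSequence, GenomeSequence, Topology

_FASTA_WIDTH = 70


def _read_records(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    except Exception as exc:  # malformed input surfaced with the file name
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rid, seq in records:
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record identifier {rid!r}")
        seen.add(rid)
        if not seq:
            raise FastaParseError(f"{path}: record {rid!r} is empty")
    return records


def read_genome_fasta(
    path: str | Path, topology: Topology | str = Topology.CIRCULAR
) -> list[GenomeSequence]:
    """Parse a (multi-record) genome FASTA; upper-cases and validates bases."""
    topology = Topology(topology)
    return [
        GenomeSequence(id=rid, seq=seq, topology=topology)
        for rid, seq in _read_records(path)
    ]


def read_cds_fasta(
    path: str | Path, codon_table: int = 11, require_stop: bool = True
) -> list[CodingSequence]:
    """Parse in-frame CDS records; frame and stop-codon invariants enforced."""
    return [
        CodingSequence(id=rid, seq=seq, codon_table=codon_table, require_stop=require_stop)
        for rid, seq in _read_records(path)
    ]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def write_motif_tsv(motifs: MotifList, path: str | Path) -> None:
    """Write the ranked motif blacklist; expected/z with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("motif\tk\tobserved\texpected\tz\n")
        for e in motifs:
            fh.write(f"{e.motif}\t{e.k}\t{e.observed}\t{e.expected:.6g}\t{e.z:.6g}\n")


def read_motif_tsv(
    path: str | Path, k_range: tuple[int, int] = (4, 8)
) -> list[str]:
    """Read a motif blacklist: the scanner's TSV or a bare motif-per-line file.

    Motifs are validated as A/C/G/T words with length inside ``k_range``
    (ambiguity codes are unsupported).  An empty blacklist is an error, never
    a silent no-op.
    """
    path = Path(path)
    if not path.exists():
        raise MotifTableError(f"no such file: {path}")
    motifs: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            word = fields[0].strip().upper()
            if lineno == 1 and word == "MOTIF":
                continue  # TSV header
            if set(word) - set("ACGT"):
                raise MotifTableError(
                    f"{path}:{lineno}: motif {fields[0]!r} contains "
                    "characters outside A/C/G/T (ambiguity codes unsupported)"
                )
            lo, hi = k_range
            if not lo <= len(word) <= hi:
                raise MotifTableError(
                    f"{path}:{lineno}: motif {word!r} has length {len(word)}, "
                    f"outside the allowed range {lo}-{hi}"
                )
            if word not in motifs:
                motifs.append(word)
    if not motifs:
        raise EmptyBlacklistError(f"{path}: empty motif blacklist")
    return motifs


def write_substitutions_tsv(subs: list[Substitution], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref\talt\tcodon_index\tcodon_position\n")
        for s in subs:
            fh.write(
                f"{s.position}\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.codon_index}\t{s.codon_position}\n"
            )


def write_residual_bed(
    hits: list[MotifHit], chrom: str, path: str | Path
) -> None:
    """Residual (unremovable) hits as BED intervals on the input CDS."""
    with open(path, "w") as fh:
        for h in hits:
            strand = "+" if h.orientation.value == "forward" else "-"
            fh.write(f"{chrom}\t{h.start}\t{h.end}\t{h.motif}\t0\t{strand}\n")
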