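"""Synonymous recoding of a CDS to eliminate blacklisted motifs.

Given a blacklist of words (typically the genome scan's under-represented
motifs), every occurrence in a coding sequence is destroyed by synonymous
codon substitutions, preferring single third-position ("wobble") edits, then
other single-base synonymous edits, then whole-codon swaps.  No edit may
create a new blacklisted occurrence.  Elimination is greedy left-to-right
with bounded backtracking; hits with no synonymous escape are reported as
residual rather than silently left in place.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .errors import EmptyBlacklistError, StealthError
from .kmer_stats import MotifList
from .sequences import (
    CodingSequence,
    OrientationMode,
    reverse_complement,
    translate_cds,
)

logger = logging.getLogger(__name__)


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE_COMPLEMENT = "reverse_complement"


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a blacklisted motif: [start, start+len) 0-based."""

    motif: str
    start: int
    orientation: Orientation = Orientation.FORWARD

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


@dataclass(frozen=True)
class Substitution:
    """A single synonymous base change.

    ``codon_position`` is 1-based within the codon; position 3 is the wobble
    position.
    """

    position: int
    ref_base: str
    alt_base: str
    codon_index: int
    codon_position: int


@dataclass
class RecodeResult:
    recoded_seq: str
    substitutions: list[Substitution]
    residual_hits: list[MotifHit]
    status: str  # "clean" or "partial"


def _as_words(motifs: MotifList | set[str] | list[str] | tuple[str, ...]) -> list[str]:
    words = motifs.motifs() if isinstance(motifs, MotifList) else list(motifs)
    seen: dict[str, None] = {}
    for w in words:
        seen[w.upper()] = None
    if not seen:
        raise EmptyBlacklistError("motif blacklist is empty")
    return list(seen)


def find_hits(
    seq: str,
    motifs: MotifList | set[str] | list[str],
    orientation_mode: OrientationMode | str = OrientationMode.FORWARD_ONLY,
) -> list[MotifHit]:
    """All occurrences of every motif in ``seq``, overlaps included.

    Under orientation mode ``both`` occurrences of each motif's reverse
    complement are also reported (as reverse_complement hits); palindromic
    motifs are reported once per offset.  Sorted by start, then motif.
    """
    orientation_mode = OrientationMode(orientation_mode)
    words = _as_words(motifs)
    hits: list[MotifHit] = []
    for motif in words:
        targets = [(motif, Orientation.FORWARD)]
        if orientation_mode is OrientationMode.BOTH:
            rc = reverse_complement(motif)
            if rc != motif:
                targets.append((rc, Orientation.REVERSE_COMPLEMENT))
        for target, orient in targets:
            start = seq.find(target)
            while start != -1:
                hits.append(MotifHit(motif=motif, start=start, orientation=orient))
                start = seq.find(target, start + 1)
    hits.sort(key=lambda h: (h.start, h.motif, h.orientation.value))
    return hits


@lru_cache(maxsize=None)
def _codon_groups(table_id: int) -> dict[str, frozenset[str]]:
    """codon -> set of codons encoding the same amino acid (stops grouped)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, set[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, set()).add(codon)
    by_aa["*"] = set(table.stop_codons)
    groups: dict[str, frozenset[str]] = {}
    for members in by_aa.values():
        fs = frozenset(members)
        for codon in members:
            groups[codon] = fs
    return groups


def synonymous_codons(codon: str, codon_table: int = 11) -> set[str]:
    """All codons (excluding the input) encoding the same amino acid.

    A stop codon returns the table's other stop codons, so stop identity is
    preserved under swaps.
    """
    codon = codon.upper()
    groups = _codon_groups(codon_table)
    if codon not in groups:
        raise StealthError(f"{codon!r} is not a codon of table {codon_table}")
    return set(groups[codon]) - {codon}


def _matched_word(hit: MotifHit) -> str:
    if hit.orientation is Orientation.REVERSE_COMPLEMENT:
        return reverse_complement(hit.motif)
    return hit.motif


def _hit_tuples_in_region(
    seq: str, lo: int, hi: int, words: list[str], mode: OrientationMode
) -> set[tuple[int, str, Orientation]]:
    """Hit identity tuples whose span lies within [lo, hi) of ``seq``."""
    region = seq[lo:hi]
    return {
        (h.start + lo, h.motif, h.orientation)
        for h in find_hits(region, words, mode)
    }


def _apply(seq: str, subs: list[Substitution]) -> str:
    chars = list(seq)
    for s in subs:
        if chars[s.position] != s.ref_base:
            raise StealthError(
                f"substitution ref mismatch at {s.position}: "
                f"{chars[s.position]} != {s.ref_base}"
            )
        chars[s.position] = s.alt_base
    return "".join(chars)


def candidate_edits(
    cds: CodingSequence,
    hit: MotifHit,
    blacklist: MotifList | set[str] | list[str],
    orientation_mode: OrientationMode | str = OrientationMode.FORWARD_ONLY,
    seq: str | None = None,
) -> list[list[Substitution]]:
    """Ordered synonymous substitution sets that destroy ``hit``.

    Every returned set (a) changes at least one base inside the hit span,
    (b) is synonymous codon-for-codon, and (c) creates no new blacklisted
    occurrence within the hit window extended by (max motif length - 1) on
    each side.  Ordering encodes the edit preference: single wobble edits
    first, then other single-base synonymous edits, then whole-codon swaps;
    within a tier leftmost position first, then alphabetical replacement.

    ``seq`` lets the recoder evaluate candidates against a partially edited
    sequence; it defaults to the CDS's own sequence.  The start codon is
    never edited.  An empty list means the hit is unresolvable.
    """
    orientation_mode = OrientationMode(orientation_mode)
    words = _as_words(blacklist)
    seq = cds.seq if seq is None else seq
    span_lo, span_hi = hit.start, hit.end
    if span_lo < 0 or span_hi > len(seq):
        raise StealthError(f"hit {hit} lies outside the CDS")
    lmax = max(len(w) for w in words)
    ext_lo = max(0, span_lo - (lmax - 1))
    ext_hi = min(len(seq), span_hi + (lmax - 1))
    before = _hit_tuples_in_region(seq, ext_lo, ext_hi, words, orientation_mode)

    n_codons = len(seq) // 3
    first_ci = max(span_lo // 3, 1)  # start codon protected
    last_ci = min((span_hi - 1) // 3, n_codons - 1)

    tier1: list[tuple[tuple, list[Substitution]]] = []
    tier2: list[tuple[tuple, list[Substitution]]] = []
    tier3: list[tuple[tuple, list[Substitution]]] = []
    for ci in range(first_ci, last_ci + 1):
        codon = seq[ci * 3 : ci * 3 + 3]
        for alt in sorted(synonymous_codons(codon, cds.codon_table)):
            diff = [p for p in range(3) if codon[p] != alt[p]]
            in_span = [p for p in diff if span_lo <= ci * 3 + p < span_hi]
            if not in_span:
                continue
            subs = [
                Substitution(
                    position=ci * 3 + p,
                    ref_base=codon[p],
                    alt_base=alt[p],
                    codon_index=ci,
                    codon_position=p + 1,
                )
                for p in diff
            ]
            if len(diff) == 1:
                p = diff[0]
                entry = ((ci * 3 + p, alt[p]), subs)
                (tier1 if p == 2 else tier2).append(entry)
            else:
                tier3.append(((ci, alt), subs))

    out: list[list[Substitution]] = []
    for tier in (tier1, tier2, tier3):
        for _, subs in sorted(tier, key=lambda t: t[0]):
            edited = _apply(seq, subs)
            after = _hit_tuples_in_region(
                edited, ext_lo, ext_hi, words, orientation_mode
            )
            if (span_lo, hit.motif, hit.orientation) in after:
                continue  # paranoia: hit survived
            if after - before:
                continue  # would create a new blacklisted occurrence
            out.append(subs)
    return out


def recode_cds(
    cds: CodingSequence,
    motifs: MotifList | set[str] | list[str],
    orientation_mode: OrientationMode | str = OrientationMode.FORWARD_ONLY,
    backtrack_depth: int = 3,
) -> RecodeResult:
    """Remove every blacklisted motif occurrence from a CDS synonymously.

    Greedy left-to-right: take the leftmost remaining hit, apply the first
    candidate edit, re-scan, repeat.  Because candidate edits never create
    new occurrences the hit count strictly decreases, but an early edit can
    strand a later overlapping hit without synonymous escapes; up to
    ``backtrack_depth`` alternative candidates are explored across the whole
    search before falling back to the greedy path.  Hits that no candidate
    can destroy are returned in ``residual_hits`` with status "partial".
    Deterministic for identical inputs.
    """
    orientation_mode = OrientationMode(orientation_mode)
    words = _as_words(motifs)
    budget = [backtrack_depth]

    def search(seq: str) -> str | None:
        hits = find_hits(seq, words, orientation_mode)
        if not hits:
            return seq
        cands = candidate_edits(cds, hits[0], words, orientation_mode, seq=seq)
        for i, cand in enumerate(cands):
            if i > 0:
                if budget[0] <= 0:
                    return None
                budget[0] -= 1
            result = search(_apply(seq, cand))
            if result is not None:
                return result
        return None

    final = search(cds.seq)
    residual: list[MotifHit] = []
    if final is None:
        # Greedy fallback: first candidate per hit, unresolvable hits skipped.
        seq = cds.seq
        skipped: set[tuple[int, str, Orientation]] = set()
        while True:
            hits = [
                h
                for h in find_hits(seq, words, orientation_mode)
                if (h.start, h.motif, h.orientation) not in skipped
            ]
            if not hits:
                break
            hit = hits[0]
            cands = candidate_edits(cds, hit, words, orientation_mode, seq=seq)
            if cands:
                seq = _apply(seq, cands[0])
            else:
                logger.warning("unresolvable hit %s at %d", hit.motif, hit.start)
                skipped.add((hit.start, hit.motif, hit.orientation))
                residual.append(hit)
        final = seq

    substitutions = _diff_substitutions(cds.seq, final)
    _warn_novel_codons(cds, final)
    return RecodeResult(
        recoded_seq=final,
        substitutions=substitutions,
        residual_hits=sorted(residual, key=lambda h: (h.start, h.motif)),
        status="clean" if not residual else "partial",
    )


def _diff_substitutions(original: str, recoded: str) -> list[Substitution]:
    """Net substitution ledger: one entry per position that differs."""
    return [
        Substitution(
            position=i,
            ref_base=a,
            alt_base=b,
            codon_index=i // 3,
            codon_position=i % 3 + 1,
        )
        for i, (a, b) in enumerate(zip(original, recoded))
        if a != b
    ]


def _warn_novel_codons(cds: CodingSequence, recoded: str) -> None:
    original_codons = set(cds.codons())
    for i in range(0, len(recoded), 3):
        codon = recoded[i : i + 3]
        if codon not in original_codons:
            logger.warning(
                "edit introduces codon %s (absent from the original CDS) "
                "at codon index %d",
                codon,
                i // 3,
            )


@dataclass
class RecodeReport:
    """Independent audit of a RecodeResult; all checks recomputed fresh."""

    checks: dict[str, bool] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def verify_recode(
    original: CodingSequence,
    result: RecodeResult,
    motifs: MotifList | set[str] | list[str],
    orientation_mode: OrientationMode | str = OrientationMode.FORWARD_ONLY,
) -> RecodeReport:
    """Re-check all recoding invariants with a fresh scan.

    Checks: translation identity (codon-for-codon, stop included), hit
    absence for clean results (residual consistency for partial ones), and
    substitution-ledger completeness (the ledger lists exactly the differing
    positions with correct ref/alt).
    """
    orientation_mode = OrientationMode(orientation_mode)
    words = _as_words(motifs)
    report = RecodeReport()

    same_len = len(result.recoded_seq) == len(original.seq)
    report.checks["length_preserved"] = same_len
    if not same_len:
        report.messages.append("recoded sequence length differs from original")

    translation_ok = same_len and translate_cds(
        result.recoded_seq, original.codon_table
    ) == translate_cds(original.seq, original.codon_table)
    report.checks["translation_identity"] = translation_ok
    if not translation_ok:
        report.messages.append("translation differs from the original protein")

    hits = find_hits(result.recoded_seq, words, orientation_mode)
    if result.status == "clean":
        report.checks["no_residual_hits"] = not hits
        if hits:
            report.messages.append(
                f"status clean but {len(hits)} blacklisted hits remain"
            )
    else:
        expected = {(h.start, h.motif, h.orientation) for h in result.residual_hits}
        actual = {(h.start, h.motif, h.orientation) for h in hits}
        report.checks["residuals_consistent"] = actual == expected and bool(expected)
        if actual != expected:
            report.messages.append(
                "residual_hits does not match a fresh scan of the recoded CDS"
            )

    ledger = {(s.position, s.ref_base, s.alt_base) for s in result.substitutions}
    diff = {
        (i, a, b)
        for i, (a, b) in enumerate(zip(original.seq, result.recoded_seq))
        if a != b
    }
    report.checks["ledger_complete"] = same_len and ledger == diff
    if ledger != diff:
        report.messages.append(
            "substitution ledger does not match the observed base differences"
        )
    return report
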