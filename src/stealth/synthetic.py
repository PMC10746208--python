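"""Seeded synthetic genomes and coding sequences for testing and power studies.

A scientist validating an under-representation scanner needs genomes whose
true word statistics are known.  The generator samples Markov chains of
order 0-2 and can "plant" depletion of chosen motifs by destroying a random
subset of their occurrences with single-base resampling — mimicking how real
genomes lose restriction sites by point mutation while keeping length and
local composition nearly unchanged, so the Markov null stays approximately
correct.  Toy CDS fixtures embed motifs at known codon offsets so recoding
claims are testable end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .errors import ConfigError, StealthError, UnrealizableEmbeddingError
from .sequences import CodingSequence, GenomeSequence, Topology

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic Markov genome.

    ``planted`` lists (motif, depletion_factor) pairs applied after
    generation; factor 1.0 leaves the motif untouched, 0.0 removes every
    occurrence.  ``transition`` (for order >= 1) is a (4**order, 4) row-
    stochastic matrix over contexts in lexicographic A<C<G<T order.
    """

    length: int
    order: int = 0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    transition: np.ndarray | None = None
    planted: list[tuple[str, float]] = field(default_factory=list)
    topology: Topology = Topology.CIRCULAR
    seed: int = 0

    def __post_init__(self) -> None:
        self.topology = Topology(self.topology)
        if self.length < 1:
            raise ConfigError("genome length must be positive")
        if not 0 <= self.order <= 2:
            raise ConfigError(f"Markov order must be 0-2, got {self.order}")
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0):
            raise ConfigError("base_frequencies must be 4 non-negative probabilities summing to 1")
        if self.order >= 1:
            if self.transition is None:
                raise ConfigError(f"order-{self.order} generation needs a transition matrix")
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4**self.order, 4) or (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0):
                raise ConfigError(
                    f"transition must be a ({4**self.order}, 4) row-stochastic matrix"
                )
            self.transition = t
        for motif, factor in self.planted:
            if set(motif.upper()) - set(_BASES):
                raise ConfigError(f"planted motif {motif!r} must be over A/C/G/T")
            if not 0.0 <= factor <= 1.0:
                raise ConfigError(f"depletion factor {factor} outside [0, 1]")


def generate_markov_genome(spec: SyntheticGenomeSpec) -> GenomeSequence:
    """Sample a genome from the specified Markov process; seeded, reproducible."""
    rng = np.random.default_rng(spec.seed)
    if spec.order == 0:
        codes = rng.choice(4, size=spec.length, p=np.asarray(spec.base_frequencies))
    else:
        codes = np.empty(spec.length, dtype=np.int64)
        m = spec.order
        init = rng.choice(4, size=min(m, spec.length), p=np.asarray(spec.base_frequencies))
        codes[: len(init)] = init
        cum = np.cumsum(spec.transition, axis=1)
        u = rng.random(spec.length)
        ctx = 0
        for b in init:
            ctx = (ctx * 4 + int(b)) % (4**m)
        mask = 4 ** (m - 1)
        for i in range(m, spec.length):
            row = cum[ctx]
            b = int(np.searchsorted(row, u[i], side="right"))
            b = min(b, 3)
            codes[i] = b
            ctx = (ctx % mask) * 4 + b if m > 1 else b
    seq = "".join(_BASES[c] for c in codes)
    genome = GenomeSequence(id=f"synthetic_seed{spec.seed}", seq=seq, topology=spec.topology)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.planted))
    for (motif, factor), ss in zip(spec.planted, child_seeds):
        genome = plant_depletion(genome, motif, factor, seed=ss)
    return genome


def _occurrences(seq: str, motif: str) -> list[int]:
    out, start = [], seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def plant_depletion(
    genome: GenomeSequence,
    motif: str,
    factor: float,
    seed: int | np.random.SeedSequence = 0,
) -> GenomeSequence:
    """Deplete a motif: each occurrence survives independently with prob ``factor``.

    A removed occurrence is destroyed by resampling one of its bases; a
    rejection loop guarantees the edit creates no new occurrence of the motif
    nearby and sequence length is preserved.  The motif's count never
    increases.  Occurrences spanning the origin of a circular contig are left
    untouched (at most len(motif)-1 windows).
    """
    if not 0.0 <= factor <= 1.0:
        raise ConfigError(f"depletion factor {factor} outside [0, 1]")
    motif = motif.upper()
    rng = np.random.default_rng(seed)
    chars = list(genome.seq)
    positions = _occurrences(genome.seq, motif)
    if not positions:
        logger.warning("motif %s absent from %s; nothing to deplete", motif, genome.id)
        return genome
    L = len(motif)
    for p in positions:
        if "".join(chars[p : p + L]) != motif:
            continue  # already destroyed by an earlier edit
        if rng.random() < factor:
            continue  # retained
        lo, hi = max(0, p - L + 1), min(len(chars), p + 2 * L - 1)
        before = set(_occurrences("".join(chars[lo:hi]), motif))
        destroyed = False
        for _ in range(1000):
            j = int(rng.integers(L))
            old = chars[p + j]
            new = _BASES[int(rng.integers(4))]
            if new == old:
                continue
            chars[p + j] = new
            after = set(_occurrences("".join(chars[lo:hi]), motif))
            if (p - lo) not in after and after <= before:
                destroyed = True
                break
            chars[p + j] = old  # reject: re-created or shifted an occurrence
        if not destroyed:  # pragma: no cover - essentially impossible
            raise StealthError(f"could not destroy occurrence of {motif} at {p}")
    return GenomeSequence(id=genome.id, seq="".join(chars), topology=genome.topology)


def generate_toy_cds(
    n_codons: int,
    embed: list[tuple[str, int]] | None = None,
    seed: int = 0,
    codon_table: int = 11,
) -> CodingSequence:
    """Random valid CDS (ATG ... stop) with motifs embedded at codon offsets.

    ``embed`` lists (motif, codon_index) pairs; each motif is written starting
    at the first base of that codon.  Embeddings may not touch the start or
    stop codon, and an embedding whose bases force a stop codon raises
    :class:`UnrealizableEmbeddingError`.  Fully reproducible from ``seed``.
    """
    embed = embed or []
    if n_codons < 3:
        raise ConfigError("need at least 3 codons (start, one sense, stop)")
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    stops = sorted(table.stop_codons)
    sense = sorted(table.forward_table)
    rng = np.random.default_rng(seed)

    codons = ["ATG"]
    codons += [sense[int(i)] for i in rng.integers(len(sense), size=n_codons - 2)]
    codons.append(stops[int(rng.integers(len(stops)))])
    chars = list("".join(codons))
    total = n_codons * 3

    fixed = [False] * total
    for motif, ci in embed:
        motif = motif.upper()
        start = ci * 3
        if ci < 1 or start + len(motif) > total - 3:
            raise UnrealizableEmbeddingError(
                f"embedding {motif!r} at codon {ci} overlaps the start/stop "
                f"codon or runs past the CDS ({n_codons} codons)"
            )
        for off, base in enumerate(motif):
            chars[start + off] = base
            fixed[start + off] = True

    # Repair partially-covered codons that became stops using their free bases.
    for ci in range(1, n_codons - 1):
        lo = ci * 3
        codon = "".join(chars[lo : lo + 3])
        if codon not in stops:
            continue
        free = [p for p in range(3) if not fixed[lo + p]]
        if not free:
            raise UnrealizableEmbeddingError(
                f"embedding forces internal stop codon {codon} at codon {ci}"
            )
        repaired = False
        for _ in range(100):
            cand = list(codon)
            for p in free:
                cand[p] = _BASES[int(rng.integers(4))]
            if "".join(cand) not in stops:
                chars[lo : lo + 3] = cand
                repaired = True
                break
        if not repaired:  # pragma: no cover
            raise UnrealizableEmbeddingError(
                f"could not repair stop codon at codon {ci}"
            )

    seq = "".join(chars)
    for motif, ci in embed:
        if seq[ci * 3 : ci * 3 + len(motif)] != motif.upper():
            raise UnrealizableEmbeddingError(
                f"embeddings conflict: {motif!r} at codon {ci} was overwritten"
            )
    return CodingSequence(
        id=f"toy_cds_seed{seed}", seq=seq, codon_table=codon_table
    )
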