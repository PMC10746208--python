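"""Detection of under-represented DNA words under a maximal-order Markov null.

For a word of length k the expected count is taken from a Markov model of
order k-2, the highest order whose parameters are estimable from the genome
itself:

    E(w) = C(w[0:k-1]) * C(w[1:k]) / C(w[1:k-1])

i.e. prefix count times suffix count over middle count.  This is the
contingency-table estimate: for a fixed middle word m, the (first base,
last base) table of counts of a+m+b has expected cell values
row_total * column_total / grand_total.

Significance is scored with the normal approximation to the binomial:
Z = (O - E) / sqrt(E * (1 - E/N)) with N the number of counted windows.
Strongly negative Z marks words the genome avoids — candidate
restriction-enzyme recognition sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import (
    ConfigError,
    ContigTooShortError,
    DegenerateVarianceError,
    InestimableMotifError,
)
from .sequences import GenomeSequence, StrandMode, Topology

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map bases to integer codes A=0 C=1 G=2 T=3; N (or anything else) -> 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _count_codes(arr: np.ndarray, k: int, circular: bool) -> tuple[np.ndarray, int]:
    """Count k-windows of an encoded contig; returns (4**k array, n_windows).

    Windows containing an ambiguous base are skipped and excluded from
    n_windows.  Circular contigs wrap across the origin.
    """
    n = len(arr)
    if n < k:
        raise ContigTooShortError(f"contig of length {n} is shorter than k={k}")
    ext = np.concatenate([arr, arr[: k - 1]]) if circular and k > 1 else arr
    m = len(ext) - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        seg = ext[j : j + m]
        ok &= seg < 4
        codes = codes * 4 + seg
    codes = codes[ok]
    counts = np.bincount(codes, minlength=4**k)
    return counts, int(codes.size)


def _revcomp_counts(counts: np.ndarray, k: int) -> np.ndarray:
    """Re-index a count array so entry w holds the count of revcomp(w)."""
    idx = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp & 3))
        tmp >>= 2
    return counts[rc]


@dataclass
class KmerTable:
    """Observed counts of all k-length windows of a genome.

    ``counts`` maps each *observed* word to its count; unobserved words are
    implicitly zero (use :meth:`get`).  ``n_windows`` is N, the total number
    of valid windows; it equals the contig length for a circular N-free
    contig and length - k + 1 for a linear one, and doubles when both strands
    are counted.
    """

    k: int
    counts: dict[str, int]
    n_windows: int

    def get(self, word: str) -> int:
        return self.counts.get(word, 0)

    @classmethod
    def _from_array(cls, k: int, arr: np.ndarray, n_windows: int) -> "KmerTable":
        (nz,) = np.nonzero(arr)
        return cls(
            k=k,
            counts={_decode(int(c), k): int(arr[c]) for c in nz},
            n_windows=n_windows,
        )


def _pooled_count_array(
    genomes: list[GenomeSequence],
    k: int,
    strand_mode: StrandMode,
    topology: Topology,
) -> tuple[np.ndarray, int]:
    """Sum window counts over contigs (pooled, never concatenated)."""
    total = np.zeros(4**k, dtype=np.int64)
    n_windows = 0
    circular = topology is Topology.CIRCULAR
    for g in genomes:
        counts, n = _count_codes(_encode(g.seq), k, circular)
        total += counts
        n_windows += n
    if strand_mode is StrandMode.BOTH:
        total = total + _revcomp_counts(total, k)
        n_windows *= 2
    return total, n_windows


def count_kmers(
    genome: GenomeSequence | list[GenomeSequence],
    k: int,
    strand_mode: StrandMode | str = StrandMode.FORWARD,
    topology: Topology | str | None = None,
) -> KmerTable:
    """Count every k-length window of a genome.

    Each window containing only A/C/G/T is counted once; windows with N are
    skipped and excluded from ``n_windows``.  For circular topology windows
    wrap across the origin.  Under ``strand_mode="both"`` the counts of the
    reverse-complement strand are added and ``n_windows`` doubles.

    ``topology`` defaults to the genome's own topology.
    """
    genomes = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    strand_mode = StrandMode(strand_mode)
    topo = Topology(topology) if topology is not None else genomes[0].topology
    arr, n = _pooled_count_array(genomes, k, strand_mode, topo)
    return KmerTable._from_array(k, arr, n)


def expected_count(
    prefix_table: KmerTable,
    suffix_table: KmerTable,
    middle_table: KmerTable,
    motif: str,
) -> float:
    """Markov(k-2) expected count of ``motif``: C(prefix)*C(suffix)/C(middle).

    ``prefix_table`` and ``suffix_table`` are (k-1)-mer tables (normally the
    same object) and ``middle_table`` the (k-2)-mer table, all built from the
    same genome with the same strand mode and topology.

    Raises
    ------
    InestimableMotifError
        If the middle word has count zero; such motifs are excluded from
        testing rather than reported with an infinite score.
    """
    k = len(motif)
    if prefix_table.k != k - 1 or middle_table.k != k - 2:
        raise ConfigError(
            f"table orders ({prefix_table.k}, {middle_table.k}) do not match "
            f"motif length {k}"
        )
    mid = middle_table.get(motif[1 : k - 1])
    if mid == 0:
        raise InestimableMotifError(
            f"middle word {motif[1:k-1]!r} unobserved; expectation undefined"
        )
    return prefix_table.get(motif[: k - 1]) * suffix_table.get(motif[1:]) / mid


def z_score(observed: int, expected: float, n_windows: int) -> float:
    """Binomial-approximation Z-score (O - E) / sqrt(E * (1 - E/N)).

    The observed count of a word among N windows is modelled as
    Binomial(N, p = E/N); the score standardises O by that distribution's
    normal approximation.  Requires 0 < E < N.
    """
    if not 0 < expected < n_windows:
        raise DegenerateVarianceError(
            f"expected count {expected} outside (0, {n_windows}); "
            "variance degenerate"
        )
    sigma = np.sqrt(expected * (1.0 - expected / n_windows))
    return float((observed - expected) / sigma)


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """One-tailed standard-normal quantile at alpha / n_tests (negative).

    Utility for a principled family-wise cutoff; the scanner's default cutoff
    is the fixed -6.7 in :class:`ScanConfig`, which is stricter than
    alpha=0.05 over the full 4-to-8-mer universe (87,296 tests, about -4.86).
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1, got {n_tests}")
    return float(norm.ppf(alpha / n_tests))


@dataclass
class MotifStat:
    """One word with its observed count O, Markov expectation E and Z-score."""

    motif: str
    k: int
    observed: int
    expected: float
    z: float
    strand_mode: StrandMode = StrandMode.FORWARD


@dataclass
class ScanConfig:
    """Parameters of an under-representation scan.

    The default Z cutoff of -6.7 is a conservative family-wise threshold for
    the 4..8-mer universe; ``strand_mode`` both adds reverse-complement
    counts (restriction sites are double-stranded), and circular topology
    counts origin-spanning windows.
    """

    k_min: int = 4
    k_max: int = 8
    z_cutoff: float = -6.7
    strand_mode: StrandMode = StrandMode.FORWARD
    topology: Topology = Topology.CIRCULAR
    max_motifs: int | None = None

    def __post_init__(self) -> None:
        self.strand_mode = StrandMode(self.strand_mode)
        self.topology = Topology(self.topology)
        if not 1 < self.k_min <= self.k_max:
            raise ConfigError(
                f"need 1 < k_min <= k_max, got k_min={self.k_min}, "
                f"k_max={self.k_max}"
            )
        if self.z_cutoff >= 0:
            raise ConfigError(f"z_cutoff must be negative, got {self.z_cutoff}")


@dataclass
class MotifList:
    """Ranked blacklist of significantly under-represented motifs.

    Sorted by Z ascending (most under-represented first), ties broken
    lexicographically on the motif.
    """

    entries: list[MotifStat]
    provenance: ScanConfig = field(default_factory=ScanConfig)

    def motifs(self) -> list[str]:
        return [e.motif for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def scan_genome(
    genome: GenomeSequence | list[GenomeSequence],
    config: ScanConfig | None = None,
) -> MotifList:
    """Scan a genome for under-represented words of length k_min..k_max.

    For each k, counts the k, k-1 and k-2 tables (pooled over contigs),
    computes the Markov(k-2) expectation and Z-score of every word whose
    expectation is estimable and non-degenerate, keeps words with
    Z <= z_cutoff, merges across k and sorts by Z then motif.  Words with an
    unobserved middle, zero expectation, or E >= N are excluded from the test
    set (and logged), not reported as infinitely depleted.
    """
    config = config or ScanConfig()
    genomes = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    for g in genomes:
        if len(g) < config.k_max:
            raise ContigTooShortError(
                f"contig {g.id!r} (length {len(g)}) shorter than k_max="
                f"{config.k_max}"
            )
    # Count arrays for every order needed: k_min-2 .. k_max.
    arrays: dict[int, tuple[np.ndarray, int]] = {}
    for k in range(config.k_min - 2, config.k_max + 1):
        arrays[k] = _pooled_count_array(
            genomes, k, config.strand_mode, config.topology
        )

    entries: list[MotifStat] = []
    for k in range(config.k_min, config.k_max + 1):
        cnt_k, n_windows = arrays[k]
        cnt_km1, _ = arrays[k - 1]
        cnt_km2, _ = arrays[k - 2]
        idx = np.arange(4**k, dtype=np.int64)
        pre = idx >> 2
        suf = idx & (4 ** (k - 1) - 1)
        mid = suf >> 2
        mid_counts = cnt_km2[mid]
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = cnt_km1[pre].astype(float) * cnt_km1[suf] / mid_counts
        estimable = (mid_counts > 0) & (expected > 0) & (expected < n_windows)
        n_excluded = int((~estimable).sum())
        z = np.full(4**k, np.nan)
        e_ok = expected[estimable]
        z[estimable] = (cnt_k[estimable] - e_ok) / np.sqrt(
            e_ok * (1.0 - e_ok / n_windows)
        )
        flagged = estimable & (z <= config.z_cutoff)
        logger.info(
            "k=%d: %d words tested, %d inestimable/degenerate, %d flagged "
            "at z <= %.3g",
            k,
            int(estimable.sum()),
            n_excluded,
            int(flagged.sum()),
            config.z_cutoff,
        )
        for c in np.nonzero(flagged)[0]:
            entries.append(
                MotifStat(
                    motif=_decode(int(c), k),
                    k=k,
                    observed=int(cnt_k[c]),
                    expected=float(expected[c]),
                    z=float(z[c]),
                    strand_mode=config.strand_mode,
                )
            )
    entries.sort(key=lambda e: (e.z, e.motif))
    if config.max_motifs is not None:
        entries = entries[: config.max_motifs]
    return MotifList(entries=entries, provenance=config)
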