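# Methods

## Statistical model

For each word length k in [k_min, k_max] (default 4–8) every window of the
genome is counted. A window is valid when it contains only A/C/G/T; windows
containing N are skipped and excluded from the window total N. Circular
contigs (the default — bacterial chromosomes) contribute windows that wrap
across the origin, so an N-free circular contig of length L has exactly L
windows at every k. Multi-contig inputs are **pooled**: counts and window
totals are summed per contig, never concatenated, so no artificial junction
words are created.

The null for a k-mer is the maximal-order Markov model, order k−2 — the
highest order whose parameters the genome itself can estimate. Its expected
count factorises over observed sub-word counts:

    E(w) = C(prefix) · C(suffix) / C(middle)

with prefix = w[0..k−2], suffix = w[1..k−1], middle = w[1..k−2]. This is
identical to the contingency-table estimate: fix the middle word m and
tabulate counts of a·m·b over (first base a, last base b); the expected cell
value is row total × column total / grand total. On a circular N-free
contig the model is exactly conservative: Σ_b E(w·b) = C(w) for every
(k−1)-mer w, an identity the test suite verifies in exact rational
arithmetic.

The observed count is scored against Binomial(N, p = E/N) through its
normal approximation, Z = (O − E) / sqrt(E(1 − E/N)). Words are reported
when Z ≤ z_cutoff (default −6.7). Only the under-represented (negative)
tail is reported; over-representation is computed but filtered out, since
the scientific target is sites the genome avoids.

### Choices at the edges

- **Inestimable words** (middle count 0, or E = 0, or E ≥ N, the last
  possible only on toy inputs) are excluded from the test set and logged,
  not reported as infinitely depleted. They also do not count toward any
  multiple-testing universe.
- **Cutoff.** −6.7 is deliberately stricter than the Bonferroni quantile for
  α = 0.05 over the full universe of Σ₄⁸ 4^k = 87,296 words (≈ −4.86);
  `bonferroni_cutoff(alpha, n_tests)` is exposed for users who prefer a
  quantile derived from an explicit universe. The fixed default favours
  specificity: a blacklist is costly to a gene designer, so false flags
  matter more than misses.
- **Strand.** Default is forward-strand counting. `strand_mode="both"` adds
  reverse-complement counts (and doubles N) because restriction sites are
  double-stranded objects; under it a word and its reverse complement
  receive identical statistics by construction.
- **Ties** in the ranked output are broken lexicographically — output order
  is a deterministic function of the input.

## Recoding procedure

Hits are every occurrence (overlaps included) of every blacklisted word in
the CDS — and of each word's reverse complement under orientation mode
`both` (default `forward_only`, matching a direct comparison of the gene
string against the motif list; the choice changes the substitution count).

Elimination is greedy left-to-right: take the leftmost hit, apply the first
acceptable edit, re-scan, repeat. Candidate edits for a hit are ordered:

1. single synonymous edits at the codon's third (wobble) position;
2. other single-base synonymous edits (e.g. TTA→CTA leucine at position 1);
3. whole-codon synonymous swaps changing ≥2 bases.

Within a tier: leftmost genomic position first, then alphabetical
replacement. Every candidate must change at least one base inside the hit
span (which necessarily destroys that occurrence) and must not create any
new blacklisted occurrence within the hit window extended by
(max motif length − 1) on each side — checked by re-scanning the edited
neighbourhood. Because accepted edits never create occurrences, the hit
count strictly decreases and termination is guaranteed. An early edit can
still strand a later overlapping hit with no synonymous escape, so the
search explores up to `backtrack_depth` (default 3) alternative candidates
across the whole run before falling back to the pure greedy path; hits no
candidate can destroy are reported as residual with status `partial` (CLI
exit code 3). The wobble-first ordering makes the edit count per
wobble-resolvable hit exactly one.

The start codon is never edited (initiation fidelity); stop codons may only
be swapped for other stop codons of the table (default NCBI table 11,
bacterial). No codon-usage or mRNA-structure optimisation is applied; a
warning is logged when an edit introduces a codon absent from the original
gene, which on short toy genes fires often and is informational only.

The substitution ledger is derived by diffing the original and final
sequences, so it lists the *net* change at every differing position even if
backtracking touched a codon twice. `verify_recode` re-checks translation
identity, hit absence (or residual consistency) and ledger completeness
from scratch; the CLI runs it after every recode.

## Synthetic data

`generate_markov_genome` samples order-0–2 Markov chains (default: order 0,
uniform composition — the simplest null under which the scanner's model is
correct up to sampling noise). `plant_depletion` then destroys each
occurrence of a chosen motif independently with probability 1 − factor by
resampling a single base, with a rejection loop guaranteeing no occurrence
is re-created nearby; length and local composition stay nearly constant, the
way real genomes lose restriction sites by point mutation, so the Markov
null remains approximately correct after planting. Occurrences spanning a
circular origin (at most k−1 of them) are left untouched. `generate_toy_cds`
builds valid CDSs (ATG … sense codons … stop) with motifs embedded at
requested codon offsets, rejecting embeddings that would force an internal
stop.

What the generator does **not** emulate: real genomes have skewed base
composition, strand asymmetry, repeats, coding constraint and multiple
overlapping avoidance signals. Passing the synthetic power and calibration
checks shows the statistic behaves as designed under its own null, not that
every flag on a real genome is a restriction site.

## Problem sizes and tolerances

Power and calibration use twenty seeded 500 kb order-0 genomes — large
enough that a 6-mer depleted to 10% of expectation scores well past −6.7
(E ≈ 90 after planting, giving Z ≈ −8) while an undepleted genome stays
empty. The
order-1 transition-recovery check runs at 120 kb, where empirical transition
frequencies concentrate within 0.02 of truth. Oracle-equivalence checks use
2 kb contigs (at that size most 7/8-mers are inestimable and are excluded
identically by both paths) at 1e−9 relative tolerance; the conservation
identity is asserted exactly in rational arithmetic and at 1e−9 relative in
floating point. Recoder soundness uses 100 seeded 30-codon fixtures with
1–3 embedded sites. A full 4–8-mer scan of a 1.6 Mb genome takes well under
a second on one CPU (counting is vectorised over encoded windows;
enumeration covers all 4^k words per k, observed or not — a word with
O = 0 and large E is precisely the strongest signal).

## Known limitations

- The scanner infers avoidance purely statistically; it performs no
  methylome analysis or recognition-site database lookup, no
  palindrome-specific treatment, and no positional/replichore analysis.
- Recoding applies to in-frame CDSs only; non-coding flanks have no
  synonymous degrees of freedom and are out of scope.
- Greedy-plus-backtracking minimises edits per hit, not globally; a
  globally minimal edit set is exponential to find and not attempted.
- The binomial Z-score treats window counts as independent; overlapping
  windows correlate slightly, which is one reason a conservative cutoff is
  the default.
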