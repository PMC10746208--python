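"""Synonymously recode a gene so it contains no blacklisted motif.

A toy CDS carries an EcoRI site (GAATTC) and the word CATC.  Recoding
destroys every occurrence with synonymous codon substitutions — preferring a
single change at the codon's third (wobble) position — and never alters the
encoded protein.  The audit at the end re-checks everything from scratch.
"""

import logging

from stealth import generate_toy_cds, recode_cds, translate_cds, verify_recode

logging.basicConfig(level=logging.ERROR)

blacklist = ["GAATTC", "CATC"]
cds = generate_toy_cds(30, embed=[("GAATTC", 5), ("CATC", 15)], seed=3)
result = recode_cds(cds, blacklist)

print(f"original: {cds.seq}")
print(f"recoded : {result.recoded_seq}")
print(f"status  : {result.status}, {len(result.substitutions)} substitution(s)")
for s in result.substitutions:
    print(
        f"  position {s.position:>3}  {s.ref_base}->{s.alt_base}  "
        f"codon {s.codon_index} (codon position {s.codon_position})"
    )
print(f"protein unchanged: {translate_cds(result.recoded_seq) == cds.translate()}")
print(f"independent audit passed: {verify_recode(cds, result, blacklist).passed}")
print(
    "\nEach blacklisted site cost one wobble-position edit; the protein "
    "sequence is untouched."
)
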