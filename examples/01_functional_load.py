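"""Functional load of a phonological contrast in a toy lexicon.

The functional load of a contrast is the information lost when the
contrast is erased: fl = H(S) - H(S with the contrasting phonemes
merged), where S is the distribution of (tonic vowel, post-tonic
consonant) string types in the analysis domain.  This script builds a
six-word lexicon by hand, extracts the domain profile, and computes the
load carried by vowel length and by consonant manner.
"""

import phylofl as pf

table = pf.tradeoff_segment_table()
forms = [
    ["p", "a", "t", "a"],    # short vowel, stop
    ["p", "aː", "t", "a"],   # long vowel, stop
    ["p", "a", "n", "a"],    # short vowel, nasal
    ["k", "a", "t", "a"],
    ["k", "aː", "t", "a"],
    ["k", "a", "t", "a"],
]
lex = pf.Lexicon("toy", [pf.Wordform("toy", tuple(segs)) for segs in forms])
prof = pf.profile(lex, table)
print("domain profile (tonic V, medial C) -> count:")
for s, n in sorted(prof.counts.items()):
    print(f"  {s}: {n}")
print(f"full entropy H = {pf.entropy(prof):.4f} bits")

flv, flc, flp = pf.build_contrasts(table)
for spec in (flv, flc, flp):
    res = pf.functional_load(prof, spec)
    print(f"{spec.name}: fl = {res.fl:.4f} bits, "
          f"normalized = {res.fl_norm:.4f}")

print("\nMerging vowel length destroys more information here than merging"
      "\nconsonant manner or place: the length contrast does more work in"
      "\nkeeping these word types distinct.")
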