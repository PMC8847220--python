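"""Screen mitogenome-like sequences by length window, N count and
per-country group size.

Complete human mitogenomes are ~16,569 bp; the filter keeps lengths in
[16,564, 16,574] with at most one ambiguous N, then drops countries
with fewer than two surviving sequences.
"""

from dnvphylo import FilterConfig, NucleotideSequence
from dnvphylo.mito import filter_pipeline


def seq(name, length, n=0):
    return NucleotideSequence(name, "A" * (length - n) + "N" * n)


seqs = [
    seq("KE_1", 16_569),          # kept
    seq("KE_2", 16_570, n=1),     # kept: one N is allowed
    seq("KE_3", 16_540),          # rejected: too short
    seq("ER_1", 16_569),          # kept, but its country ends up alone...
    seq("ER_2", 16_600),          # rejected: too long
    seq("TD_1", 16_569, n=2),     # rejected: two Ns
]
countries = {"KE_1": "Kenya", "KE_2": "Kenya", "KE_3": "Kenya",
             "ER_1": "Eritrea", "ER_2": "Eritrea", "TD_1": "Chad"}

kept, rejected, dropped = filter_pipeline(seqs, countries, FilterConfig())
print("kept:    ", [s.identifier for s in kept])
print("rejected:", [(s.identifier, reason) for s, reason in rejected])
print("dropped groups (fewer than 2 survivors):", dropped)
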