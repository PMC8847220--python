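"""The packaged five-sample VCF reconstruction example.

A 70 bp reference and three variant records illustrate every
reconstruction rule: a simple SNP (T→C at position 10), a second SNP
(C→T at position 26), and a multi-allelic record at position 55 whose
multi-base REF window is replaced by the second ALT allele, CATTTT.
Samples HG00096 and HG02231 carry only reference genotypes and so
reconstruct to the reference itself; HG01992 and HG02230 both carry the
second alternative at position 55 and reconstruct identically.
"""

from __future__ import annotations

from .sequences import NucleotideSequence

SAMPLES = ["HG00096", "HG00770", "HG01992", "HG02230", "HG02231"]

# positions (1-based): 10 = T, 26 = C, 55-59 = CTTTT
_REFERENCE = (
    "ACGGACGTA" "T"          # 1-10
    "GGCATACGTAGCCAT" "C"    # 11-26
    "ATTGCAGGCATCGATACGGATTCAGACT"  # 27-54
    "CTTTT"                  # 55-59
    "AGCATCGGATC"            # 60-70
)

REFERENCE = NucleotideSequence("ref", _REFERENCE)

VCF_TEXT = "\n".join(
    [
        "##fileformat=VCFv4.3",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLES),
        "20\t10\t.\tT\tC\t.\tPASS\t.\tGT\t0|0\t1|1\t0|0\t0|0\t0|0",
        "20\t26\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|1\t0|0\t0|0\t0|0",
        "20\t55\t.\tCTTTT\tC,CATTTT\t.\tPASS\t.\tGT\t0|0\t0|0\t2|2\t2|2\t0|0",
    ]
) + "\n"


def worked_example() -> tuple[NucleotideSequence, str, list[str]]:
    """Return (reference, vcf_text, sample_names) of the packaged example."""
    return REFERENCE, VCF_TEXT, list(SAMPLES)
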