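"""Consensus haplotype reconstruction from VCF variant calls.

Rebuilds per-haplotype sequences by splicing called alleles into a
reference chromosome, the way ``bcftools consensus`` does: each
non-reference allele replaces the reference substring starting at the
record's POS, multi-allelic sites are handled natively (genotype index
j selects the j-th ALT), and structural records (symbolic alleles such
as ``<CN0>``, or any record carrying an SVTYPE) are excluded because
their placement in duplicated regions is ambiguous.

A diploid chromosome yields a pair of haplotype sequences labelled
``a``/``b``; the assignment to parental origin is arbitrary and may
differ between chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .sequences import NucleotideSequence

logger = logging.getLogger(__name__)

#: sentinel for a missing ("." ) allele call
MISSING: Optional[int] = None


@dataclass
class VariantRecord:
    """One parsed VCF data line (positions 1-based, as in the VCF standard).

    ``genotypes`` maps sample name to an ordered tuple of per-haplotype
    allele indices: 0 = REF, j >= 1 = j-th ALT allele, ``None`` = missing.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, tuple[Optional[int], ...]] = field(default_factory=dict)
    svtype: Optional[str] = None
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF POS must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        for sample, gt in self.genotypes.items():
            for a in gt:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range for sample {sample!r} "
                        f"at {self.chrom}:{self.pos} ({n_alleles} alleles)"
                    )

    @property
    def end(self) -> int:
        """Last reference position covered by the REF allele (1-based)."""
        return self.pos + len(self.ref_allele) - 1


@dataclass(frozen=True)
class HaplotypePair:
    """The two reconstructed haplotypes of one sample for one chromosome."""

    sample: str
    hap_a: NucleotideSequence
    hap_b: NucleotideSequence


def is_structural(rec: VariantRecord) -> bool:
    """True iff the record is a structural variant to be excluded.

    A record is structural when any ALT allele is symbolic (angle-bracketed,
    e.g. ``<CN2>``) or when INFO carried an SVTYPE. Multi-base explicit
    alleles are small indels, not SVs.
    """
    if rec.svtype is not None:
        return True
    return any(a.startswith("<") and a.endswith(">") for a in rec.alt_alleles)


def haplotype_allele(
    rec: VariantRecord, sample: str, hap_index: int
) -> str:
    """The allele string the given haplotype carries, or ``"reference"``.

    Missing calls (".") are conservatively treated as reference.
    """
    if sample not in rec.genotypes:
        raise KeyError(f"sample {sample!r} absent from record at {rec.chrom}:{rec.pos}")
    gt = rec.genotypes[sample]
    if hap_index >= len(gt):
        raise IndexError(
            f"haplotype {hap_index} requested but sample {sample!r} has "
            f"ploidy {len(gt)} at {rec.chrom}:{rec.pos}"
        )
    allele = gt[hap_index]
    if allele is None or allele == 0:
        return "reference"
    return rec.alt_alleles[allele - 1]


def apply_variants(
    reference: NucleotideSequence,
    records: Sequence[VariantRecord],
    sample: str,
    hap_index: int,
    *,
    verify_ref: bool = True,
    label: str | None = None,
) -> NucleotideSequence:
    """Splice a sample haplotype's alleles into the reference sequence.

    Records are applied in descending position order on a mutable copy, so
    indel-induced coordinate shifts never invalidate the VCF POS of a
    not-yet-applied record; the result equals simultaneous left-to-right
    splicing. Structural records are skipped. Overlapping applied records
    are a hard error. With ``verify_ref`` (default) a REF allele that does
    not match the reference at POS raises; otherwise it logs a warning.
    """
    applied = []
    for rec in records:
        if is_structural(rec):
            continue
        allele = haplotype_allele(rec, sample, hap_index)
        if allele == "reference":
            continue
        applied.append((rec, allele))
    applied.sort(key=lambda pair: pair[0].pos)

    for (a, _), (b, _) in zip(applied, applied[1:]):
        if b.pos <= a.end:
            raise ValueError(
                f"overlapping variants at {a.chrom}:{a.pos}-{a.end} and "
                f"{b.chrom}:{b.pos} for sample {sample!r}"
            )

    residues = reference.residues
    for rec, allele in reversed(applied):
        start = rec.pos - 1  # to 0-based
        ref_here = residues[start : start + len(rec.ref_allele)]
        # residues to the right of this record are untouched so far, so the
        # slice at the original coordinate is still the reference substring
        if ref_here != rec.ref_allele:
            msg = (
                f"REF allele {rec.ref_allele!r} does not match reference "
                f"{ref_here!r} at {rec.chrom}:{rec.pos}"
            )
            if verify_ref:
                raise ValueError(msg)
            logger.warning(msg)
        residues = residues[:start] + allele + residues[start + len(rec.ref_allele):]

    name = label or f"{sample}_{'ab'[hap_index]}"
    return NucleotideSequence(name, residues)


def reconstruct_cohort(
    reference: NucleotideSequence,
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    *,
    verify_ref: bool = True,
) -> list[HaplotypePair]:
    """Reconstruct both haplotypes of every sample against one reference."""
    pairs = []
    for sample in samples:
        hap_a = apply_variants(reference, records, sample, 0, verify_ref=verify_ref)
        hap_b = apply_variants(reference, records, sample, 1, verify_ref=verify_ref)
        pairs.append(HaplotypePair(sample, hap_a, hap_b))
    return pairs


def reconstruct_haploid(
    reference: NucleotideSequence,
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    *,
    verify_ref: bool = True,
) -> list[NucleotideSequence]:
    """One sequence per sample, from the first genotype field (e.g. Y chromosome)."""
    return [
        apply_variants(
            reference, records, s, 0, verify_ref=verify_ref, label=s
        )
        for s in samples
    ]
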