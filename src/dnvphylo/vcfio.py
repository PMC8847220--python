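"""Minimal VCF reader for the reconstruction pipeline.

Parses the VCFv4.x subset the pipeline needs — CHROM, POS, REF, ALT and
per-sample GT — from plain or gzipped text. Only the ``#CHROM`` header
line (which names the sample columns) is required; ``##`` meta lines are
skipped. INFO is ignored except for SVTYPE, which marks structural
records for exclusion. Phased (``|``) and unphased (``/``) genotype
separators are both accepted: the "a"/"b" haplotype labels are arbitrary
with respect to parental origin, so phase bookkeeping beyond field order
is not needed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .reconstruct import VariantRecord
from .sequences import _open_text

_FIXED_COLS = 9  # CHROM POS ID REF ALT QUAL FILTER INFO FORMAT


def _parse_gt(gt_field: str) -> tuple[Optional[int], ...]:
    gt = gt_field.split(":", 1)[0]
    alleles = gt.replace("|", "/").split("/")
    out = []
    for a in alleles:
        if a == ".":
            out.append(None)
        else:
            out.append(int(a))
    return tuple(out)


def _parse_info_svtype(info: str) -> Optional[str]:
    for item in info.split(";"):
        if item.startswith("SVTYPE="):
            return item.split("=", 1)[1]
    return None


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF file into :class:`~dnvphylo.reconstruct.VariantRecord` list.

    Raises ``ValueError`` if the ``#CHROM`` header is missing, a data line
    has fewer columns than the declared samples, or POS is not an integer.
    """
    records: list[VariantRecord] = []
    samples: list[str] | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[_FIXED_COLS:]
                continue
            if samples is None:
                raise ValueError(f"{path}: data line {lineno} before #CHROM header")
            cols = line.split("\t")
            if len(cols) < _FIXED_COLS + len(samples):
                raise ValueError(
                    f"{path}: line {lineno} has {len(cols)} columns, expected "
                    f"{_FIXED_COLS + len(samples)} for {len(samples)} samples"
                )
            chrom, pos_s, rid, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} has non-integer POS {pos_s!r}"
                ) from None
            alts = [] if alt == "." else alt.split(",")
            genotypes = {
                s: _parse_gt(g) for s, g in zip(samples, cols[_FIXED_COLS:])
            }
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    genotypes=genotypes,
                    svtype=_parse_info_svtype(cols[7]),
                    id=rid,
                )
            )
    if samples is None:
        raise ValueError(f"{path}: no #CHROM header line found")
    return records


def vcf_samples(path: str | Path) -> list[str]:
    """Sample column names declared in the #CHROM header."""
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                return line.rstrip("\n").split("\t")[_FIXED_COLS:]
    raise ValueError(f"{path}: no #CHROM header line found")
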