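"""Mitogenome quality filtering.

Complete human mitochondrial genomes cluster tightly around the
reference length of 16,569 bp; sequences far outside that window are
usually partial or misassembled, and sequences with more than one
ambiguous ``N`` carry too little signal for position-sensitive
descriptors. The filters here implement that screen: an inclusive
length window, a maximum N count, and a per-group (per-country)
minimum number of surviving sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .sequences import NucleotideSequence

TOO_SHORT = "TOO_SHORT"
TOO_LONG = "TOO_LONG"
TOO_MANY_N = "TOO_MANY_N"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for mitogenome screening.

    Defaults: keep lengths in [16564, 16574] (reference 16,569 bp, ±5),
    at most one N, and drop groups with fewer than 2 survivors.
    """

    min_length: int = 16_564
    max_length: int = 16_574
    max_n: int = 1
    min_group_size: int = 2

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.max_n < 0:
            raise ValueError("max_n must be >= 0")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


def filter_sequences(
    seqs: Sequence[NucleotideSequence], cfg: FilterConfig = FilterConfig()
) -> tuple[list[NucleotideSequence], list[tuple[NucleotideSequence, str]]]:
    """Partition sequences into (kept, rejected-with-reason-code).

    A sequence is kept iff its length lies in the inclusive window and its
    count of literal 'N' symbols is at most ``max_n``. Other IUPAC
    ambiguity codes do not count as N. Rejections carry one of the codes
    TOO_SHORT, TOO_LONG, TOO_MANY_N (the first failing check, in that
    order).
    """
    kept, rejected = [], []
    for seq in seqs:
        n = len(seq)
        if n < cfg.min_length:
            rejected.append((seq, TOO_SHORT))
        elif n > cfg.max_length:
            rejected.append((seq, TOO_LONG))
        elif seq.residues.count("N") > cfg.max_n:
            rejected.append((seq, TOO_MANY_N))
        else:
            kept.append(seq)
    return kept, rejected


def filter_groups(
    seqs: Sequence[NucleotideSequence],
    groups: Mapping[str, str],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[NucleotideSequence], list[str]]:
    """Drop whole groups with fewer than ``min_group_size`` sequences.

    ``groups`` maps sequence identifier to its group (country) label;
    an unlabeled sequence is an error. Returns surviving sequences (in
    input order) and the sorted list of dropped group labels.
    """
    counts: dict[str, int] = {}
    for seq in seqs:
        if seq.identifier not in groups:
            raise ValueError(f"sequence {seq.identifier!r} has no group label")
        g = groups[seq.identifier]
        counts[g] = counts.get(g, 0) + 1
    dropped = sorted(g for g, c in counts.items() if c < cfg.min_group_size)
    dropped_set = set(dropped)
    kept = [s for s in seqs if groups[s.identifier] not in dropped_set]
    return kept, dropped


def filter_pipeline(
    seqs: Sequence[NucleotideSequence],
    groups: Mapping[str, str],
    cfg: FilterConfig = FilterConfig(),
):
    """Sequence-level filter, then group-level filter, in that order.

    The group filter counts only sequence-filter survivors, so the two
    stages do not commute in the other order.
    """
    kept, rejected = filter_sequences(seqs, cfg)
    kept, dropped = filter_groups(kept, groups, cfg)
    return kept, rejected, dropped
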