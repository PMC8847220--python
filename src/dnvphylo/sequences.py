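"""Nucleotide sequence container and FASTA input/output.

Sequences are stored uppercase over the IUPAC nucleotide alphabet
(A, C, G, T plus the ambiguity codes R, Y, S, W, K, M, B, D, H, V, N).
Reconstructed consensus genomes routinely contain long N runs, so
ambiguity codes are first-class citizens here rather than errors.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

UNAMBIGUOUS = "ACGT"
IUPAC_AMBIGUITY = "RYSWKMBDHVN"
IUPAC_ALPHABET = frozenset(UNAMBIGUOUS + IUPAC_AMBIGUITY)


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified nucleotide sequence, uppercase, IUPAC alphabet.

    Parameters
    ----------
    identifier : str
        Nonempty record name (FASTA header word).
    residues : str
        Nonempty string over the IUPAC nucleotide alphabet.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.identifier!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.identifier!r} contains non-IUPAC character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into a list of :class:`NucleotideSequence`.

    Lines are case-folded to uppercase and whitespace is stripped; wrapped
    and unwrapped dialects both parse. Raises ``ValueError`` on an empty
    file, a duplicate identifier, or a character outside the IUPAC set
    (the error names the offending character and record).
    """
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        records.append(NucleotideSequence(name, "".join(chunks)))

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if name in seen:
                    raise ValueError(f"duplicate FASTA identifier {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA data before first '>' header")
                chunks.append(line)
        flush()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(
    seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70
) -> None:
    """Write sequences as wrapped FASTA; round-trips through read_fasta."""
    with _open_text(path, "wt") as fh:
        for seq in seqs:
            fh.write(f">{seq.identifier}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")
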