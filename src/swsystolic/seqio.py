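"""FASTA input/output and synthetic sequence generation."""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DNA, Alphabet, Sequence
from .errors import AlphabetError, InputError

__all__ = [
    "read_fasta",
    "write_fasta",
    "random_sequence",
    "generate_sequences",
]


def _precheck_fasta(path: Path) -> None:
    # Bio.SeqIO does not report line numbers; scan the header ourselves so
    # malformed files fail with a useful location.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise InputError(
                    f"{path}: line {lineno}: expected a FASTA header "
                    f"starting with '>', got {line.strip()[:30]!r}"
                )
            return
    raise InputError(f"{path}: file contains no FASTA records")


def read_fasta(path, alphabet: Alphabet = DNA) -> list[Sequence]:
    """Parse a FASTA file into validated sequences.

    Header text becomes the sequence name; symbols are upper-cased and
    validated against ``alphabet`` (strict: ambiguity codes such as ``N``
    are rejected under DNA).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    _precheck_fasta(path)
    sequences: list[Sequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        symbols = str(record.seq).upper()
        if not symbols:
            raise InputError(f"{path}: record {record.id!r} has no symbols")
        for offset, sym in enumerate(symbols):
            if sym not in alphabet:
                raise AlphabetError(
                    f"{path}: record {record.id!r}: symbol {sym!r} at "
                    f"offset {offset} is not in the {alphabet.name} alphabet"
                )
        sequences.append(
            Sequence(symbols=symbols, alphabet=alphabet, name=record.description)
        )
    return sequences


def write_fasta(sequences, path_or_handle) -> None:
    """Write sequences as FASTA (one record per sequence, in order)."""
    records = [
        SeqRecord(Seq(seq.symbols), id=seq.name or f"seq{k}", description="")
        for k, seq in enumerate(sequences)
    ]
    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as handle:
            SeqIO.write(records, handle, "fasta")
    else:
        SeqIO.write(records, path_or_handle, "fasta")


def random_sequence(
    length: int,
    alphabet: Alphabet = DNA,
    rng: np.random.Generator | None = None,
    name: str = "",
) -> Sequence:
    """One uniform i.i.d. random sequence of the given length."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if rng is None:
        rng = np.random.default_rng()
    letters = rng.choice(list(alphabet.symbols), size=length)
    return Sequence(symbols="".join(letters), alphabet=alphabet, name=name)


def generate_sequences(
    n: int,
    m: int,
    alphabet: Alphabet = DNA,
    seed: int | None = None,
) -> tuple[Sequence, Sequence]:
    """Random query (length ``n``) and database (length ``m``) sequences.

    Symbols are uniform i.i.d. over the alphabet; an identical seed yields
    identical output.
    """
    if n < 1 or m < 1:
        raise ValueError(f"sequence lengths must be >= 1, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    q = random_sequence(n, alphabet, rng, name="q")
    s = random_sequence(m, alphabet, rng, name="s")
    return q, s
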