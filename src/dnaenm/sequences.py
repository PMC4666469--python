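"""DNA sequence handling: validation, complementation, random generation, FASTA I/O.

Sequences are plain Python strings over the alphabet {A, C, G, T}.  The
random-sequence generator draws each position independently: G/C with
probability ``gc``, A/T otherwise, uniformly within each class.  A single
master seed deterministically spawns one stream per sequence so that batch
results do not depend on evaluation order.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate(seq: str) -> str:
    """Return ``seq`` upper-cased, rejecting any symbol outside {A,C,G,T}."""
    s = seq.upper()
    for pos, sym in enumerate(s):
        if sym not in ALPHABET:
            raise ValueError(f"invalid symbol {sym!r} at position {pos}")
    return s


def complement_strand(seq: str) -> str:
    """Watson-Crick complement of ``seq``, returned 5'->3' on the other strand.

    This is the reverse complement: position-wise A<->T, C<->G, then reversal
    so the result reads 5'->3' along the complementary strand.
    """
    return validate(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C symbols in ``seq``."""
    s = validate(seq)
    if not s:
        raise ValueError("empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Draw a random sequence of ``length`` bp with expected GC content ``gc``.

    Each position independently is G or C (each with probability gc/2) or
    A or T (each with probability (1-gc)/2).
    """
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def random_sequences(n: int, length: int, gc: float, seed) -> list[str]:
    """Reproducible batch of ``n`` random sequences from one master seed.

    ``seed`` is an integer or a :class:`numpy.random.SeedSequence`;
    per-sequence streams are spawned from it, so element ``k`` of the batch
    is identical no matter how many sequences are requested.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n)
    return [
        random_sequence(length, gc, np.random.default_rng(s)) for s in streams
    ]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``[(id, sequence), ...]`` (validated)."""
    return [(rec.id, validate(str(rec.seq))) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``[(id, sequence), ...]`` to a FASTA file."""
    SeqIO.write(
        (SeqRecord(Seq(validate(s)), id=name, description="") for name, s in records),
        path,
        "fasta",
    )


def read_sequences(path) -> list[tuple[str, str]]:
    """Read sequences from FASTA or one-sequence-per-line plain text."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return read_fasta(path)
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if line:
                out.append((f"seq{k + 1}", validate(line)))
    return out
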