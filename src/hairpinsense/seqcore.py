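"""Nucleic-acid sequence primitives, reading-frame logic and FASTA I/O.

The canonical internal alphabet is RNA: every designed molecule is an RNA
transcript, so DNA inputs are converted at the boundary (T -> U) and the
original alphabet is remembered on the object.  DNA <-> RNA conversion is a
bijection and round-trips exactly.  All coordinates are 0-based, half-open.

Ambiguity codes (N, R, Y, ...) are rejected here: a designed construct must
be fully specified.  Sequencing reads, which legitimately contain N, are
handled as plain strings by :mod:`hairpinsense.editquant`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_rna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, InputError

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

#: In-frame translation terminators of the standard genetic code.
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

_CODON_TABLE = unambiguous_rna_by_id[1].forward_table

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_T_TO_U = str.maketrans("T", "U")
_U_TO_T = str.maketrans("U", "T")

#: Watson-Crick pairs on the RNA alphabet (wobble G:U is *not* included;
#: folding code opts into wobble explicitly).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})


def is_wc(a: str, b: str) -> bool:
    """True if ``a``/``b`` (RNA letters) form a strict Watson-Crick pair."""
    return (a, b) in WC_PAIRS


@dataclass(frozen=True)
class NucSeq:
    """A validated nucleotide sequence over a declared alphabet.

    Parameters
    ----------
    residues:
        Uppercase nucleotide string over ``{A,C,G,U}`` (RNA) or
        ``{A,C,G,T}`` (DNA).
    alphabet:
        ``"rna"`` or ``"dna"``.
    """

    residues: str
    alphabet: str = "rna"

    def __post_init__(self) -> None:
        if self.alphabet not in ("rna", "dna"):
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        valid = RNA_BASES if self.alphabet == "rna" else DNA_BASES
        for i, ch in enumerate(self.residues):
            if ch not in valid:
                raise AlphabetError(ch, i, self.alphabet)

    # -- constructors ------------------------------------------------------
    @classmethod
    def rna(cls, s: str) -> "NucSeq":
        return cls(s.upper(), "rna")

    @classmethod
    def dna(cls, s: str) -> "NucSeq":
        return cls(s.upper(), "dna")

    @classmethod
    def auto(cls, s: str) -> "NucSeq":
        """Guess the alphabet: a sequence containing U is RNA, else DNA if it
        contains T, else RNA (the package's canonical alphabet)."""
        s = s.upper()
        if "U" in s:
            return cls(s, "rna")
        if "T" in s:
            return cls(s, "dna")
        return cls(s, "rna")

    # -- dunder plumbing ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    # -- conversions -------------------------------------------------------
    def to_rna(self) -> "NucSeq":
        if self.alphabet == "rna":
            return self
        return NucSeq(self.residues.translate(_T_TO_U), "rna")

    def to_dna(self) -> "NucSeq":
        if self.alphabet == "dna":
            return self
        return NucSeq(self.residues.translate(_U_TO_T), "dna")


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement in the same alphabet.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    if len(seq) == 0:
        raise InputError("cannot reverse-complement an empty sequence")
    table = _RNA_COMPLEMENT if seq.alphabet == "rna" else _DNA_COMPLEMENT
    return NucSeq(seq.residues.translate(table)[::-1], seq.alphabet)


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    return base.translate(_RNA_COMPLEMENT)


@dataclass(frozen=True)
class TranslationResult:
    peptide: str
    stopped: bool
    #: True when a trailing partial codon was ignored.
    partial_codon: bool


def translate(seq: NucSeq, frame_offset: int = 0) -> TranslationResult:
    """Standard-genetic-code translation halting at the first stop codon.

    DNA input is auto-converted to RNA.  A trailing partial codon is ignored
    and flagged, never an error.
    """
    if frame_offset not in (0, 1, 2):
        raise InputError("frame_offset must be 0, 1 or 2")
    rna = seq.to_rna().residues[frame_offset:]
    peptide = []
    stopped = False
    for c in range(len(rna) // 3):
        codon = rna[3 * c : 3 * c + 3]
        if codon in STOP_CODONS:
            stopped = True
            break
        peptide.append(_CODON_TABLE[codon])
    partial = not stopped and len(rna) % 3 != 0
    return TranslationResult("".join(peptide), stopped, partial)


@dataclass(frozen=True)
class FrameAudit:
    """In-frame stop-codon inventory of a sequence at a given frame."""

    frame_offset: int
    #: 0-based nucleotide indices (in the original sequence) of the first
    #: base of every in-frame stop codon, strictly increasing.
    stop_positions: tuple[int, ...]
    length_mod3: int

    @property
    def stop_count(self) -> int:
        return len(self.stop_positions)


def audit_frame(seq: NucSeq, frame_offset: int = 0) -> FrameAudit:
    """List every in-frame stop codon start index and the length mod 3."""
    if frame_offset not in (0, 1, 2):
        raise InputError("frame_offset must be 0, 1 or 2")
    rna = seq.to_rna().residues
    stops = []
    for i in range(frame_offset, len(rna) - 2, 3):
        if rna[i : i + 3] in STOP_CODONS:
            stops.append(i)
    return FrameAudit(frame_offset, tuple(stops), len(rna) % 3)


def contains_stop_any_frame(s: str) -> bool:
    """True if any of the three frames of ``s`` (RNA string) holds a stop."""
    return any(s[i : i + 3] in STOP_CODONS for i in range(len(s) - 2))


# -- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "auto") -> list[tuple[str, NucSeq]]:
    """Read a FASTA file into ``(id, NucSeq)`` tuples.

    ``alphabet`` may be ``"rna"``, ``"dna"`` or ``"auto"`` (detect from the
    presence of U/T per record).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if alphabet == "auto":
            records.append((rec.id, NucSeq.auto(s)))
        else:
            records.append((rec.id, NucSeq(s, alphabet)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, NucSeq]]) -> None:
    """Write ``(id, NucSeq)`` tuples as 60-column wrapped FASTA."""
    seqrecords = [
        SeqRecord(Seq(seq.residues), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
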