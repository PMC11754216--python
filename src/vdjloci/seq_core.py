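"""Sequence primitives shared by every stage of the pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to
1-based inclusive happens only at the GFF3 boundary (see :mod:`vdjloci.formats`).

Pairwise alignment is affine-gap and delegates the dynamic programming to
:class:`Bio.Align.PairwiseAligner`; the scoring convention is that a gap of
length ``k`` costs ``gap_open + k * gap_extend`` (both negative numbers).
Percent identity is computed over columns where *both* rows are non-gap, and
the ambiguity code ``N`` never counts as a match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable

# '-' is tolerated in records so that alignment rows round-trip as SeqRecords.
NT_ALPHABET = set("ACGTN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, codon -> amino acid, stop rendered '*'.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE.stop_codons})


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, empty record, ...)."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence, nucleotide (``moltype='nt'``) or amino acid (``'aa'``)."""

    id: str
    seq: str
    moltype: str = "nt"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.moltype not in ("nt", "aa"):
            raise SequenceError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class PairwiseAlignment:
    """Gapped alignment of two sequences plus score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    # Coordinates of the aligned region on each *ungapped* input sequence.
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0


def read_fasta(path: str | Path, moltype: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased; for nucleotide input ``U`` is mapped to ``T``.
    Duplicate ids or empty sequences raise :class:`SequenceError` naming the
    offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if moltype == "nt":
            seq = seq.replace("U", "T")
        records.append(SeqRecord(id=rec.id, seq=seq, moltype=moltype))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _check_nt(seq: str) -> None:
    if not seq:
        raise SequenceError("empty nucleotide sequence")
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise SequenceError(f"invalid nucleotide characters {sorted(bad)}")


def revcomp(seq: str) -> str:
    """Reverse complement; ``N`` maps to ``N``. Rejects empty/non-nt input."""
    _check_nt(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the standard genetic code.

    Stops render as ``'*'``; any codon containing ``N`` renders as ``'X'``;
    a trailing partial codon is dropped.
    """
    _check_nt(seq)
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float, mode: str
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Our convention: a gap of length k costs gap_open + k*gap_extend.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _identity_pct(aligned_a: str, aligned_b: str) -> float:
    both = matches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y and x != "N":
                matches += 1
    return 100.0 * matches / both if both else 0.0


def _wrap_alignment(alignment, score: float) -> PairwiseAlignment:
    aligned_a = str(alignment[0])
    aligned_b = str(alignment[1])
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a):
        a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
        b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    else:  # degenerate: no aligned columns
        a_start = a_end = b_start = b_end = 0
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity_pct=_identity_pct(aligned_a, aligned_b),
        a_start=a_start,
        a_end=a_end,
        b_start=b_start,
        b_end=b_end,
    )


def global_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal affine-gap Needleman–Wunsch global alignment of two sequences."""
    if not a or not b:
        raise SequenceError("global_align requires two non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "global")
    alignments = aligner.align(a, b)
    return _wrap_alignment(alignments[0], alignments.score)


def fit_align(
    query: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Semi-global ("fit") alignment: full *query* against the best-scoring
    substring of *reference* (end gaps on the reference are free).

    In the returned alignment, row ``a`` is the query and row ``b`` the
    reference; ``b_start``/``b_end`` give the matched reference interval.
    """
    if not query or not reference:
        raise SequenceError("fit_align requires two non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "global")
    # Free end gaps on the reference (the target of the aligner call below):
    # unaligned reference overhangs cost nothing. In Bio.Align terms a
    # "deletion" is a target letter without a query partner.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    alignments = aligner.align(reference, query)
    best = alignments[0]
    wrapped = _wrap_alignment(best, alignments.score)
    # swap rows so that a = query, b = reference
    return PairwiseAlignment(
        aligned_a=wrapped.aligned_b,
        aligned_b=wrapped.aligned_a,
        score=wrapped.score,
        identity_pct=wrapped.identity_pct,
        a_start=wrapped.b_start,
        a_end=wrapped.b_end,
        b_start=wrapped.a_start,
        b_end=wrapped.a_end,
    )


def local_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Smith–Waterman local alignment (used for transcript-to-germline mapping,
    where exonucleolytic trimming makes segment ends non-homologous)."""
    if not a or not b:
        raise SequenceError("local_align requires two non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "local")
    alignments = aligner.align(a, b)
    return _wrap_alignment(alignments[0], alignments.score)


def build_msa(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Stack sequences into a simple multiple alignment.

    Equal-length inputs are returned as-is (already column-compatible).
    Otherwise a star alignment is built: every sequence is globally aligned to
    the longest input and gap columns introduced in the centre are merged.
    This is deliberately minimal — enough to feed the distance-based
    phylogenetics, not a general-purpose MSA tool.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) == 1:
        return list(records)
    centre = max(records, key=lambda r: len(r.seq))
    pairwise = []
    for rec in records:
        if rec.id == centre.id:
            pairwise.append((rec, centre.seq, centre.seq))
        else:
            aln = global_align(centre.seq, rec.seq)
            pairwise.append((rec, aln.aligned_a, aln.aligned_b))
    # Column map: for each centre residue, the max number of inserted columns after it.
    ins_after = [0] * (len(centre.seq) + 1)
    for _, c_row, _ in pairwise:
        pos = 0
        run = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                ins_after[pos] = max(ins_after[pos], run)
                run = 0
                pos += 1
        ins_after[pos] = max(ins_after[pos], run)
    out = []
    for rec, c_row, s_row in pairwise:
        cols = []
        pos = 0
        run_chars: list[str] = []

        def flush(p: int) -> None:
            cols.append("".join(run_chars) + "-" * (ins_after[p] - len(run_chars)))

        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == "-":
                run_chars.append(s_ch)
            else:
                flush(pos)
                run_chars = []
                cols.append(s_ch)
                pos += 1
        flush(pos)
        out.append(SeqRecord(id=rec.id, seq="".join(cols), moltype=rec.moltype))
    assert len({len(r.seq) for r in out}) == 1
    return out


_J_MOTIF = re.compile(r"FG.G")


def has_fgxg(aa: str) -> bool:
    """True iff the canonical J-region F-G-x-G anchor occurs in *aa*."""
    return bool(_J_MOTIF.search(aa))
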