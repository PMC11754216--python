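"""Transcript-to-germline mapping, junction calls, and productivity analysis.

Each cDNA transcript is mapped to germline V, J and C segments by local
alignment (local rather than fit alignment because exonucleolytic trimming
during V(D)J recombination makes the germline segment ends non-homologous to
the transcript). A transcript is

* **5'-complete** when its V alignment covers at least ``complete_cov`` (95%)
  of the germline V and a C region is present — operationalizing "complete
  enough at the 5' end to show evidence of V(D)J recombination";
* **in frame** when the nucleotide distance between the V-derived codon
  anchor and the C-derived codon anchor is 0 mod 3;
* **productive** iff it is 5'-complete, in frame, and the read-through from
  the V start to the end of J encodes no stop codon.

D-segment evidence is sought inside the V→J junction as the longest exact
substring match to a germline D; it is reported only and never affects
productivity (frame is a V→C property).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .seq_core import SeqRecord, local_align, translate

logger = logging.getLogger(__name__)


@dataclass
class SegmentHit:
    name: str
    score: float
    identity_pct: float
    g_start: int  # on germline segment
    g_end: int
    t_start: int  # on transcript
    t_end: int
    g_len: int

    @property
    def coverage(self) -> float:
        return (self.g_end - self.g_start) / self.g_len


@dataclass
class RearrangementCall:
    transcript_id: str
    v_name: str | None = None
    d_name: str | None = None
    j_name: str | None = None
    c_name: str | None = None
    junction_nt: str = ""
    complete_5p: bool = False
    in_frame: bool = False
    has_stop: bool = False
    productive: bool = False
    v_hit: SegmentHit | None = None
    j_hit: SegmentHit | None = None
    c_hit: SegmentHit | None = None

    def validate(self) -> None:
        if self.productive and not (self.complete_5p and self.in_frame and not self.has_stop):
            raise AssertionError("productive call violates completeness/frame/stop invariant")


@dataclass
class RepertoireSummary:
    n_total: int
    n_complete: int
    n_productive: int
    pct_complete: float
    pct_productive_of_complete: float


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# minimum fraction of the germline segment a local hit must cover to count;
# V is allowed short (5'-truncated transcripts must still be assigned)
_MIN_COVERAGE = {"V": 0.15, "J": 0.5, "C": 0.7}

_PRESCREEN_K = 12


def _kmers(seq: str, k: int = _PRESCREEN_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _shortlist(transcript: str, germline: list[SeqRecord]) -> list[SeqRecord]:
    """Cheap shared-k-mer prescreen: alignment is only attempted for germline
    segments sharing a competitive number of exact 12-mers with the transcript
    (at least half the best count). Order, and hence the leftmost tie rule,
    is preserved."""
    tx = _kmers(transcript)
    counts = [len(tx & _kmers(rec.seq)) for rec in germline]
    top = max(counts, default=0)
    if top == 0:
        return list(germline)  # nothing shares a seed; let alignment decide
    cutoff = max(1, top // 2)
    return [rec for rec, c in zip(germline, counts) if c >= cutoff]


def _best_hit(
    transcript: str, germline: list[SeqRecord], kind: str, min_identity: float
) -> SegmentHit | None:
    best: SegmentHit | None = None
    tied = False
    for rec in _shortlist(transcript, germline):
        aln = local_align(rec.seq, transcript)
        hit = SegmentHit(
            name=rec.id, score=aln.score, identity_pct=aln.identity_pct,
            g_start=aln.a_start, g_end=aln.a_end,
            t_start=aln.b_start, t_end=aln.b_end, g_len=len(rec.seq),
        )
        if hit.identity_pct < min_identity or hit.coverage < _MIN_COVERAGE[kind]:
            continue
        if best is None or hit.score > best.score:
            best, tied = hit, False
        elif hit.score == best.score:
            tied = True  # first (leftmost germline) kept
    if tied:
        logger.info("tied %s assignment; keeping leftmost germline %s", kind, best.name)
    return best


def assign_segments(
    transcript: SeqRecord,
    germline_v: list[SeqRecord],
    germline_j: list[SeqRecord],
    germline_c: list[SeqRecord],
    min_identity: float = 90.0,
) -> RearrangementCall:
    """Best-scoring germline V/J/C per transcript; V/J/C must appear 5'→3'."""
    call = RearrangementCall(transcript_id=transcript.id)
    c = _best_hit(transcript.seq, germline_c, "C", min_identity)
    if c is None:
        logger.info("transcript %s: no C hit, left unassigned", transcript.id)
        return call
    call.c_name, call.c_hit = c.name, c
    v = _best_hit(transcript.seq, germline_v, "V", min_identity)
    j = _best_hit(transcript.seq, germline_j, "J", min_identity)
    if v is not None and v.t_end > c.t_start:
        logger.warning("transcript %s: V hit 3' of C, dropped", transcript.id)
        v = None
    if j is not None and (j.t_end > c.t_start + 2 or (v is not None and j.t_start < v.t_end)):
        logger.warning("transcript %s: J hit out of 5'→3' order, dropped", transcript.id)
        j = None
    if v is not None:
        call.v_name, call.v_hit = v.name, v
    if j is not None:
        call.j_name, call.j_hit = j.name, j
    if v is not None and j is not None:
        call.junction_nt = transcript.seq[v.t_end : j.t_start]
    return call


def detect_d(junction_nt: str, d_segments: list[SeqRecord], min_match: int = 8) -> str | None:
    """Longest exact substring shared between the junction and any germline D,
    reported when at least *min_match* nt (ties: longer match, then 5'-most D)."""
    if not junction_nt:
        return None
    best_name, best_len = None, min_match - 1
    for rec in d_segments:
        d = rec.seq
        longest = 0
        for i in range(len(d)):
            for jj in range(i + longest + 1, len(d) + 1):
                if d[i:jj] in junction_nt:
                    longest = jj - i
                else:
                    break
        if longest > best_len:
            best_name, best_len = rec.id, longest
    return best_name


def classify_productivity(
    call: RearrangementCall,
    transcript: SeqRecord,
    complete_cov: float = 0.95,
) -> RearrangementCall:
    """Fill completeness, frame, stop and productivity flags on a call.

    The reading frame is anchored on the germline V codon frame at the
    V-alignment start; the in-frame test asks whether the C anchor sits a
    multiple of 3 downstream. The stop scan runs from the anchored V start
    through the end of the J alignment.
    """
    v, j, c = call.v_hit, call.j_hit, call.c_hit
    if v is None or c is None:
        call.complete_5p = False
        call.productive = False
        return call
    call.complete_5p = v.coverage >= complete_cov
    # transcript position where the V-derived codon frame begins
    origin = v.t_start - (v.g_start % 3)
    while origin < 0:
        origin += 3
    c_anchor = c.t_start - (c.g_start % 3)
    call.in_frame = (c_anchor - origin) % 3 == 0
    stop_end = j.t_end if j is not None else c.t_start
    call.has_stop = "*" in translate(transcript.seq[origin:stop_end])
    call.productive = call.complete_5p and call.in_frame and not call.has_stop
    call.validate()
    return call


def analyze_transcript(
    transcript: SeqRecord,
    germline_v: list[SeqRecord],
    germline_d: list[SeqRecord],
    germline_j: list[SeqRecord],
    germline_c: list[SeqRecord],
    min_identity: float = 90.0,
) -> RearrangementCall:
    """Full per-transcript pipeline: assign segments, D evidence, productivity."""
    call = assign_segments(transcript, germline_v, germline_j, germline_c, min_identity)
    if call.c_hit is None:
        return call
    call.d_name = detect_d(call.junction_nt, germline_d)
    return classify_productivity(call, transcript)


def summarize(calls: list[RearrangementCall]) -> RepertoireSummary:
    """Counts and percentages (one decimal, half-up rounding)."""
    n_total = len(calls)
    n_complete = sum(1 for c in calls if c.complete_5p)
    n_productive = sum(1 for c in calls if c.productive)
    return RepertoireSummary(
        n_total=n_total,
        n_complete=n_complete,
        n_productive=n_productive,
        pct_complete=_round1(100.0 * n_complete / n_total) if n_total else 0.0,
        pct_productive_of_complete=(
            _round1(100.0 * n_productive / n_complete) if n_complete else 0.0
        ),
    )


def calls_to_frame(calls: list[RearrangementCall]) -> pd.DataFrame:
    """AIRR-like per-transcript table."""
    return pd.DataFrame(
        [
            dict(
                sequence_id=c.transcript_id, v_call=c.v_name, d_call=c.d_name,
                j_call=c.j_name, c_call=c.c_name, junction=c.junction_nt,
                complete=c.complete_5p, in_frame=c.in_frame, has_stop=c.has_stop,
                productive=c.productive,
            )
            for c in calls
        ]
    )
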