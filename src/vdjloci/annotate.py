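"""Assemble RSS hits into typed V/D/J/C gene-segment calls and a locus map.

Segment models (12/23 rule architecture, as in TCR β-like loci):

* **V**: an open reading frame immediately 5' of a 23-spacer RSS on the same
  strand. The window must start with ATG, be a multiple of 3 within
  ``[min_v, max_v]`` nt, and contain no stop codon; the longest such window
  is taken.
* **D**: a short window (``[min_d, max_d]`` nt) between an upstream 12-RSS
  and a downstream 23-RSS facing it.
* **J**: a window of ``[min_j, max_j]`` nt immediately 3' of a 12-RSS, ending
  right before a splice-donor ``GT`` and whose translation carries the
  F-G-x-G anchor; the shortest qualifying window (first donor) is taken.
* **C**: supplied externally (transcript evidence or a known C-region
  database located by fit alignment), never called from RSS.

Each RSS heptamer is consumed by at most one segment; conflicts are resolved
greedily by descending combined RSS score (leftmost wins ties) and losers are
dropped with a logged warning, never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .rss import RssHit
from .seq_core import Interval, has_fgxg, revcomp, translate, fit_align

logger = logging.getLogger(__name__)


@dataclass
class AnnotatorParams:
    min_v: int = 270
    max_v: int = 330
    min_d: int = 8
    max_d: int = 25
    min_j: int = 30
    max_j: int = 70


@dataclass
class GeneSegment:
    """A typed genomic gene segment with its flanking RSS.

    ``sequence`` is coding-strand oriented (reverse-complemented for '-'
    strand segments).
    """

    name: str
    kind: str  # V, D, J or C
    ivl: Interval
    strand: str
    sequence: str
    rss5: RssHit | None = None
    rss3: RssHit | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("V", "D", "J", "C"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        self._check_rss()

    def _check_rss(self) -> None:
        """Enforce the 12/23 architecture per segment type.

        RSS may be absent (germline databases loaded from FASTA carry none),
        but an RSS on the wrong side or with the wrong spacer class is always
        an error: V takes only a 23-RSS 3', D a 12-RSS 5' plus a 23-RSS 3',
        J only a 12-RSS 5', and C none.
        """
        expect = {
            "V": (None, 23),
            "D": (12, 23),
            "J": (12, None),
            "C": (None, None),
        }[self.kind]
        for side, rss, want in zip(("rss5", "rss3"), (self.rss5, self.rss3), expect):
            if rss is None:
                continue
            if want is None:
                raise ValueError(f"{self.kind} segment must not carry {side}")
            if rss.spacer_class != want:
                raise ValueError(
                    f"{self.kind} segment {side} has spacer class {rss.spacer_class}, expected {want}"
                )


@dataclass
class LocusMap:
    locus_name: str
    segments: list[GeneSegment]
    span_bp: int
    flanking_genes: list[tuple[str, Interval, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {"V": 0, "D": 0, "J": 0, "C": 0}
        for seg in self.segments:
            out[seg.kind] += 1
        return out


def _candidate_v(seq: str, hit: RssHit, params: AnnotatorParams) -> GeneSegment | None:
    """Longest ATG-initiated, stop-free, in-frame window abutting the heptamer."""
    for length in range(params.max_v - params.max_v % 3, params.min_v - 1, -3):
        if hit.strand == "+":
            start, end = hit.heptamer_ivl.start - length, hit.heptamer_ivl.start
            if start < 0:
                continue
            coding = seq[start:end]
        else:
            start, end = hit.heptamer_ivl.end, hit.heptamer_ivl.end + length
            if end > len(seq):
                continue
            coding = revcomp(seq[start:end])
        if coding.startswith("ATG") and "*" not in translate(coding):
            return GeneSegment(
                name="", kind="V", ivl=Interval(start, end), strand=hit.strand,
                sequence=coding, rss3=hit,
            )
    return None


def _candidate_j(seq: str, hit: RssHit, params: AnnotatorParams) -> GeneSegment | None:
    """Shortest window ending before a splice-donor GT and carrying F-G-x-G."""
    for length in range(params.min_j + (3 - params.min_j % 3) % 3, params.max_j + 1, 3):
        if hit.strand == "-":
            # segment to the right of the heptamer, read on '+'
            start, end = hit.heptamer_ivl.end, hit.heptamer_ivl.end + length
            if end + 2 > len(seq):
                break
            coding = seq[start:end]
            donor = seq[end : end + 2] == "GT"
            seg_strand = "+"
        else:
            # '+' strand 12-RSS faces left: segment on '-' strand to its left
            start, end = hit.heptamer_ivl.start - length, hit.heptamer_ivl.start
            if start - 2 < 0:
                break
            coding = revcomp(seq[start:end])
            donor = seq[start - 2 : start] == "AC"  # revcomp of GT
            seg_strand = "-"
        if donor:
            aa = translate(coding)
            if has_fgxg(aa) and "*" not in aa:
                return GeneSegment(
                    name="", kind="J", ivl=Interval(start, end), strand=seg_strand,
                    sequence=coding, rss5=hit,
                )
    return None


def _candidate_ds(seq: str, hits12: list[RssHit], hits23: list[RssHit], params: AnnotatorParams) -> list[GeneSegment]:
    out = []
    for h5 in hits12:
        for h3 in hits23:
            if h5.strand == "-" and h3.strand == "+":
                # D on '+': 12-RSS reads leftward on '-', 23-RSS rightward on '+'
                start, end = h5.heptamer_ivl.end, h3.heptamer_ivl.start
                seg_strand = "+"
            elif h5.strand == "+" and h3.strand == "-":
                # D on '-': mirrored arrangement, 12-RSS genomically right
                start, end = h3.heptamer_ivl.end, h5.heptamer_ivl.start
                seg_strand = "-"
            else:
                continue
            if params.min_d <= end - start <= params.max_d:
                core = seq[start:end]
                out.append(
                    GeneSegment(
                        name="", kind="D", ivl=Interval(start, end), strand=seg_strand,
                        sequence=core if seg_strand == "+" else revcomp(core),
                        rss5=h5, rss3=h3,
                    )
                )
    return out


def _hit_key(hit: RssHit) -> tuple[int, int, str]:
    return (hit.heptamer_ivl.start, hit.heptamer_ivl.end, hit.strand)


def call_segments(
    seq: str,
    hits12: list[RssHit],
    hits23: list[RssHit],
    c_regions: list[Interval] | None = None,
    params: AnnotatorParams | None = None,
) -> list[GeneSegment]:
    """Call V/D/J segments from scanner hits (plus externally supplied C regions).

    Greedy by descending combined RSS score; every heptamer is consumed at
    most once and called segments never overlap. Returns segments sorted by
    coordinate, unnamed (see :func:`assign_names`).
    """
    params = params or AnnotatorParams()
    candidates: list[tuple[float, int, GeneSegment]] = []
    for d in _candidate_ds(seq, hits12, hits23, params):
        candidates.append((d.rss5.score + d.rss3.score, d.ivl.start, d))
    for h in hits23:
        v = _candidate_v(seq, h, params)
        if v is not None:
            candidates.append((h.score, v.ivl.start, v))
    for h in hits12:
        j = _candidate_j(seq, h, params)
        if j is not None:
            candidates.append((h.score, j.ivl.start, j))

    accepted: list[GeneSegment] = []
    if c_regions:
        for ivl in c_regions:
            cseq = seq[ivl.start : ivl.end]
            accepted.append(
                GeneSegment(
                    name="", kind="C", ivl=ivl, strand=ivl.strand,
                    sequence=cseq if ivl.strand == "+" else revcomp(cseq),
                )
            )
    consumed: set[tuple[int, int, str]] = set()
    for score, _start, seg in sorted(candidates, key=lambda t: (-t[0], t[1])):
        seg_hits = [h for h in (seg.rss5, seg.rss3) if h is not None]
        if any(_hit_key(h) in consumed for h in seg_hits):
            continue  # same heptamer already used (e.g. spacer-tolerance duplicate)
        if any(seg.ivl.overlaps(other.ivl) for other in accepted):
            logger.warning(
                "dropping %s candidate at [%d, %d): overlaps an accepted segment",
                seg.kind, seg.ivl.start, seg.ivl.end,
            )
            continue
        consumed.update(_hit_key(h) for h in seg_hits)
        accepted.append(seg)
    accepted.sort(key=lambda s: s.ivl.start)
    return accepted


def find_c_regions(seq: str, c_db: list, min_identity: float = 90.0) -> list[Interval]:
    """Locate constant-region exons by fit-aligning known C sequences.

    Each database record is tried on both strands; matches with identity >=
    *min_identity* are reported (best strand per record).
    """
    out = []
    for rec in c_db:
        best = None
        for strand, query in (("+", rec.seq), ("-", revcomp(rec.seq))):
            aln = fit_align(query, seq)
            if aln.identity_pct >= min_identity and (best is None or aln.score > best[0]):
                best = (aln.score, Interval(aln.b_start, aln.b_end, strand))
        if best is not None:
            out.append(best[1])
    return out


def assign_names(
    segments: list[GeneSegment],
    locus_prefix: str,
    families: dict[str, int] | None = None,
    v_keys: list | None = None,
) -> list[GeneSegment]:
    """IMGT-style names by 5'→3' position.

    Non-V segments are numbered ``<prefix><kind>1..n`` in locus order (a
    unique C is left unnumbered). V segments are named
    ``<prefix>V<family>.<member>`` with members numbered 5'→3' within their
    family; *families* maps V index (position among V segments, 5'→3') to a
    family number.
    """
    segments = sorted(segments, key=lambda s: s.ivl.start)
    named: list[GeneSegment] = []
    kind_counts = {"D": 0, "J": 0, "C": 0}
    n_c = sum(1 for s in segments if s.kind == "C")
    member_counts: dict[int, int] = {}
    v_index = 0
    for seg in segments:
        if seg.kind == "V":
            if families is None or v_index not in families:
                raise ValueError(f"no family assignment for V segment at {seg.ivl.start}")
            fam = families[v_index]
            member_counts[fam] = member_counts.get(fam, 0) + 1
            name = f"{locus_prefix}V{fam}.{member_counts[fam]}"
            named.append(replace(seg, name=name, family=str(fam)))
            v_index += 1
        else:
            kind_counts[seg.kind] += 1
            if seg.kind == "C" and n_c == 1:
                name = f"{locus_prefix}C"
            else:
                name = f"{locus_prefix}{seg.kind}{kind_counts[seg.kind]}"
            named.append(replace(seg, name=name))
    return named


def build_locus_map(
    segments: list[GeneSegment],
    locus_name: str = "locus",
    flanking_genes: list[tuple[str, Interval, str]] | None = None,
) -> LocusMap:
    segments = sorted(segments, key=lambda s: s.ivl.start)
    for a, b in zip(segments, segments[1:]):
        if a.ivl.overlaps(b.ivl):
            raise ValueError(
                f"overlapping segments {a.name or a.kind}@[{a.ivl.start},{a.ivl.end}) and "
                f"{b.name or b.kind}@[{b.ivl.start},{b.ivl.end})"
            )
    if not segments:
        raise ValueError("cannot build a locus map from zero segments")
    span = segments[-1].ivl.end - segments[0].ivl.start
    return LocusMap(
        locus_name=locus_name, segments=segments, span_bp=span,
        flanking_genes=flanking_genes or [],
    )


def count_inversions(locus: LocusMap) -> int:
    """Number of V segments transcribed opposite to the locus orientation.

    The locus orientation is the majority strand of C segments; if no C is
    present the majority strand over all segments is used (logged).
    """
    c_strands = [s.strand for s in locus.segments if s.kind == "C"]
    if c_strands:
        ref = max(set(c_strands), key=c_strands.count)
    else:
        logger.warning("no C segment in %s; using majority strand of all segments", locus.locus_name)
        strands = [s.strand for s in locus.segments]
        ref = max(set(strands), key=strands.count)
    return sum(1 for s in locus.segments if s.kind == "V" and s.strand != ref)
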