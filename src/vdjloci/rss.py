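"""Recombination signal sequence (RSS) detection and scoring.

An RSS is a conserved heptamer (consensus ``CACAGTG``) separated from a
conserved nonamer (consensus ``ACAAAAACC``) by a spacer of approximately 12 or
23 bp; the RAG recombinase pairs a 12-spacer RSS with a 23-spacer RSS (the
12/23 rule). Segments are flanked so that the heptamer abuts the coding end,
reading 5'→3' *away* from the segment. Consequences for scanning genomic
forward coordinates:

* a **plus-strand** hit (heptamer ... spacer ... nonamer, left to right)
  flanks a coding segment that ends at the heptamer start (V- or D-3' RSS);
* a **minus-strand** hit (reverse complement of the motif; in forward
  coordinates the nonamer comes first and the heptamer last) flanks a coding
  segment that begins at the heptamer end (J- or D-5' RSS).

Scoring is position-wise log-odds ("information content") against per-position
nucleotide frequency tables, summed over heptamer and nonamer. ``N`` bases
contribute 0 bits. This is a trainable, reproducible stand-in for web-based
RSS information-content scoring tools; only rank behaviour (consensus scores
highest, known functional variants score well above random sequence) is part
of the contract, not any external tool's numeric values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_core import Interval, revcomp

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class RssModel:
    """Position frequency model for heptamer + nonamer with a spacer class.

    ``heptamer_pfm`` and ``nonamer_pfm`` are ``(L, 4)`` row-stochastic arrays
    (columns A, C, G, T). ``spacer_tolerance`` widens the accepted spacer
    lengths to ``spacer_class ± tolerance``.
    """

    heptamer_pfm: np.ndarray
    nonamer_pfm: np.ndarray
    spacer_class: int
    spacer_tolerance: int = 1
    pseudocount: float = 1e-3
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        if self.spacer_class not in (12, 23):
            raise ValueError(f"spacer_class must be 12 or 23, got {self.spacer_class}")
        for name, pfm, L in (("heptamer", self.heptamer_pfm, 7), ("nonamer", self.nonamer_pfm, 9)):
            pfm = np.asarray(pfm, dtype=float)
            if pfm.shape != (L, 4):
                raise ValueError(f"{name} PFM must have shape ({L}, 4)")
            if not np.allclose(pfm.sum(axis=1), 1.0):
                raise ValueError(f"{name} PFM rows must sum to 1")

    def _logodds(self, pfm: np.ndarray) -> np.ndarray:
        """(L, 5) log2 odds table; column 4 (N) is all zeros."""
        lo = np.log2(pfm / self.background[None, :])
        return np.hstack([lo, np.zeros((pfm.shape[0], 1))])

    @property
    def heptamer_logodds(self) -> np.ndarray:
        return self._logodds(self.heptamer_pfm)

    @property
    def nonamer_logodds(self) -> np.ndarray:
        return self._logodds(self.nonamer_pfm)

    def max_score(self) -> float:
        return float(
            self.heptamer_logodds[:, :4].max(axis=1).sum()
            + self.nonamer_logodds[:, :4].max(axis=1).sum()
        )

    def spacer_lengths(self) -> range:
        return range(self.spacer_class - self.spacer_tolerance, self.spacer_class + self.spacer_tolerance + 1)


@dataclass(frozen=True)
class RssHit:
    """A scored heptamer/spacer/nonamer occurrence, in forward coordinates.

    ``heptamer_seq``/``nonamer_seq`` read 5'→3' on the hit's own strand.
    """

    heptamer_ivl: Interval
    nonamer_ivl: Interval
    spacer_len: int
    strand: str
    score: float
    heptamer_seq: str
    nonamer_seq: str
    spacer_class: int

    @property
    def canonical(self) -> bool:
        return self.heptamer_seq == HEPTAMER_CONSENSUS

    @property
    def coding_boundary(self) -> int:
        """Forward coordinate where the flanked coding segment abuts the heptamer:
        segment end for '+' hits, segment start for '-' hits."""
        return self.heptamer_ivl.start if self.strand == "+" else self.heptamer_ivl.end


def _pfm_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = counts + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def default_model(spacer_class: int, spacer_tolerance: int = 1) -> RssModel:
    """Consensus-concentrated model.

    The first three heptamer positions (``CAC``), essential for cleavage, get
    the strongest concentration (0.97 on the consensus base); the remaining
    heptamer and all nonamer positions get 0.85. Under this model the
    consensus is the unique maximum and the functionally tolerated variants
    (e.g. the ``CACAGCA`` heptamer observed in several squamate loci) still
    score far above random sequence.
    """
    hept = np.full((7, 4), np.nan)
    for i, base in enumerate(HEPTAMER_CONSENSUS):
        major = 0.97 if i < 3 else 0.85
        row = np.full(4, (1 - major) / 3)
        row[_BASE_INDEX[base]] = major
        hept[i] = row
    nona = np.full((9, 4), np.nan)
    for i, base in enumerate(NONAMER_CONSENSUS):
        row = np.full(4, 0.05)
        row[_BASE_INDEX[base]] = 0.85
        nona[i] = row
    return RssModel(heptamer_pfm=hept, nonamer_pfm=nona, spacer_class=spacer_class,
                    spacer_tolerance=spacer_tolerance)


def train_model(
    examples: list[tuple[str, str, str]],
    spacer_class: int,
    pseudocount: float = 0.5,
    spacer_tolerance: int = 1,
    background: np.ndarray | None = None,
) -> RssModel:
    """Estimate PFMs from ``(heptamer, spacer, nonamer)`` training triples."""
    if not examples:
        raise ValueError("need at least one training example")
    hept_counts = np.zeros((7, 4))
    nona_counts = np.zeros((9, 4))
    for heptamer, _spacer, nonamer in examples:
        if len(heptamer) != 7 or len(nonamer) != 9:
            raise ValueError(
                f"training example has heptamer length {len(heptamer)} / nonamer length {len(nonamer)}"
            )
        for counts, seq in ((hept_counts, heptamer), (nona_counts, nonamer)):
            for i, base in enumerate(seq):
                if base != "N":
                    counts[i, _BASE_INDEX[base]] += 1
    return RssModel(
        heptamer_pfm=_pfm_from_counts(hept_counts, pseudocount),
        nonamer_pfm=_pfm_from_counts(nona_counts, pseudocount),
        spacer_class=spacer_class,
        spacer_tolerance=spacer_tolerance,
        pseudocount=pseudocount,
        background=np.full(4, 0.25) if background is None else np.asarray(background, float),
    )


def information_content(model: RssModel) -> float:
    """Total information content: sum over positions of 2 - H(position), bits."""
    total = 0.0
    for pfm in (model.heptamer_pfm, model.nonamer_pfm):
        p = np.clip(pfm, 1e-12, 1.0)
        entropy = -(p * np.log2(p)).sum(axis=1)
        total += float((2.0 - entropy).sum())
    return total


def score_window(model: RssModel, heptamer: str, nonamer: str) -> float:
    """Joint log-odds (bits) of a heptamer + nonamer pair under the model."""
    if len(heptamer) != 7 or len(nonamer) != 9:
        raise ValueError("heptamer must be length 7 and nonamer length 9")
    h = model.heptamer_logodds
    n = model.nonamer_logodds
    hi = _encode(heptamer)
    ni = _encode(nonamer)
    return float(h[np.arange(7), hi].sum() + n[np.arange(9), ni].sum())


def _scan_plus(seq: str, model: RssModel, threshold: float) -> list[tuple[int, int, float]]:
    """Plus-strand candidate list as (heptamer_start, spacer_len, score)."""
    idx = _encode(seq)
    L = len(idx)
    h_lo = model.heptamer_logodds
    n_lo = model.nonamer_logodds
    hept_scores = np.full(L, -np.inf)
    if L >= 7:
        win = np.lib.stride_tricks.sliding_window_view(idx, 7)
        hept_scores[: win.shape[0]] = h_lo[np.arange(7)[None, :], win].sum(axis=1)
    nona_scores = np.full(L, -np.inf)
    if L >= 9:
        win = np.lib.stride_tricks.sliding_window_view(idx, 9)
        nona_scores[: win.shape[0]] = n_lo[np.arange(9)[None, :], win].sum(axis=1)
    out = []
    for spacer in model.spacer_lengths():
        offset = 7 + spacer
        n_pos = L - offset - 9 + 1
        if n_pos <= 0:
            continue
        total = hept_scores[:n_pos] + nona_scores[offset : offset + n_pos]
        for i in np.nonzero(total >= threshold)[0]:
            out.append((int(i), spacer, float(total[i])))
    return out


def scan(seq: str, model: RssModel, threshold: float | None = None) -> list[RssHit]:
    """Find RSS on both strands with joint score >= *threshold*.

    The default threshold is 60% of the model's maximum score. Minus-strand
    hits are reported in forward coordinates with ``strand='-'``. Overlapping
    hits are all reported; deduplication is the annotator's concern.
    """
    if threshold is None:
        threshold = 0.6 * model.max_score()
    L = len(seq)
    hits: list[RssHit] = []
    for i, spacer, score in _scan_plus(seq, model, threshold):
        h_ivl = Interval(i, i + 7)
        n_ivl = Interval(i + 7 + spacer, i + 16 + spacer)
        hits.append(
            RssHit(
                heptamer_ivl=h_ivl, nonamer_ivl=n_ivl, spacer_len=spacer, strand="+",
                score=score, heptamer_seq=seq[h_ivl.start : h_ivl.end],
                nonamer_seq=seq[n_ivl.start : n_ivl.end], spacer_class=model.spacer_class,
            )
        )
    rc = revcomp(seq)
    for i, spacer, score in _scan_plus(rc, model, threshold):
        # position i on the reverse strand maps to forward [L - i - 7, L - i)
        h_ivl = Interval(L - i - 7, L - i)
        n_ivl = Interval(L - (i + 16 + spacer), L - (i + 7 + spacer))
        hits.append(
            RssHit(
                heptamer_ivl=h_ivl, nonamer_ivl=n_ivl, spacer_len=spacer, strand="-",
                score=score, heptamer_seq=rc[i : i + 7],
                nonamer_seq=rc[i + 7 + spacer : i + 16 + spacer],
                spacer_class=model.spacer_class,
            )
        )
    hits.sort(key=lambda h: (h.heptamer_ivl.start, h.strand, h.spacer_len))
    return hits
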