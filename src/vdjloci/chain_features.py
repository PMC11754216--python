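"""Transmembrane detection, charged-residue asymmetry, and motif checks.

TCR chains pair as heterodimers whose transmembrane (TM) helices carry a
conserved charge asymmetry: one chain holds both an arginine and a lysine in
the TM (class ``RK``), the partner a single lysine (``K_only``). These basic
residues dock the CD3 signalling modules, so a putative new chain predicted to
be ``K_only`` is expected to pair with an ``RK`` partner (e.g. the α chain).

TM detection is a Kyte–Doolittle sliding-window method: the window (default
19 residues) maximizing mean hydropathy is taken if its mean is at least 1.5,
then extended outward while flanking residues stay hydrophobic, up to 25
residues. This is a deterministic, dependency-free functional stand-in for
neural-network TM predictors, not a parity implementation of any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

TM_MIN_MEAN = 1.5
TM_MAX_LEN = 25

D_CONSERVED_MOTIF = "GGGACAGGGGGC"


@dataclass
class TmAnnotation:
    aa_seq: str
    tm_start: int | None
    tm_end: int | None
    charged_positions: list[tuple[int, str]] = field(default_factory=list)
    chain_class: str = "none"  # RK | K_only | none

    @property
    def tm_seq(self) -> str | None:
        if self.tm_start is None:
            return None
        return self.aa_seq[self.tm_start : self.tm_end]


def _hydropathy(aa_seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in aa_seq])


def find_tm(aa_seq: str, window: int = 19) -> tuple[int, int] | None:
    """Most hydrophobic window, extended while flanks stay hydrophobic.

    Returns the (start, end) half-open interval on *aa_seq*, or ``None`` when
    the best window mean falls below ``TM_MIN_MEAN``. The leftmost maximal
    window wins ties; extension tries the left flank first, then the right,
    up to ``TM_MAX_LEN`` residues total.
    """
    if len(aa_seq) < window:
        raise ValueError(f"sequence shorter than window ({len(aa_seq)} < {window})")
    h = _hydropathy(aa_seq)
    means = np.convolve(h, np.ones(window) / window, mode="valid")
    # leftmost window within float tolerance of the maximum (exact ties are
    # common in designed sequences and must resolve deterministically)
    best = int(np.flatnonzero(means >= means.max() - 1e-9)[0])
    if means[best] < TM_MIN_MEAN:
        return None
    start, end = best, best + window
    while end - start < TM_MAX_LEN and start > 0 and h[start - 1] > 0:
        start -= 1
    while end - start < TM_MAX_LEN and end < len(aa_seq) and h[end] > 0:
        end += 1
    return start, end


def classify_chain(aa_seq: str, window: int = 19) -> TmAnnotation:
    """TM interval plus Arg/Lys content within it, mapped to a chain class."""
    ivl = find_tm(aa_seq, window)
    if ivl is None:
        return TmAnnotation(aa_seq=aa_seq, tm_start=None, tm_end=None, chain_class="none")
    start, end = ivl
    charged = [(i, aa_seq[i]) for i in range(start, end) if aa_seq[i] in "RK"]
    residues = {r for _, r in charged}
    if "R" in residues and "K" in residues:
        chain_class = "RK"
    elif residues == {"K"}:
        chain_class = "K_only"
    else:
        chain_class = "none"
    return TmAnnotation(
        aa_seq=aa_seq, tm_start=start, tm_end=end,
        charged_positions=charged, chain_class=chain_class,
    )


def predict_pairing(a: TmAnnotation, b: TmAnnotation) -> str:
    """Heterodimer compatibility from TM charge asymmetry.

    A pair is ``compatible`` exactly when one chain is ``RK`` and the other
    ``K_only`` — the asymmetric arrangement seen in functional receptor
    heterodimers. Symmetric in its arguments.
    """
    return "compatible" if {a.chain_class, b.chain_class} == {"RK", "K_only"} else "incompatible"


def check_d_motif(d_seq: str) -> bool:
    """True iff the deeply conserved D-segment core occurs as an exact substring."""
    return D_CONSERVED_MOTIF in d_seq


def check_j_motif(j_aa: str) -> bool:
    """True iff the J-region F-G-x-G anchor occurs in the protein sequence."""
    from .seq_core import has_fgxg

    return has_fgxg(j_aa)
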