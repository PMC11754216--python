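"""Ground-truthed synthetic TCR loci and simulated V(D)J-recombined transcripts.

The generator emulates the architecture of a TCR β-like locus: V segments
(ATG-initiated, stop-free ORFs) each followed by a 23-spacer RSS, D segments
framed by a 12-RSS (V-proximal) and a 23-RSS (C-proximal), J segments preceded
by a 12-RSS and followed by a splice-donor GT, a single-exon C region encoding
a transmembrane stretch, and optionally V segments in inverted orientation 3'
of C. Defaults mirror a skink-like TRB architecture (16 V in 8 families, one
3'-inverted V, 3 D, 6 J, 1 C).

Design guarantees used by the annotator's exact-recovery contract:

* a ``TAA`` stop guard is placed immediately 5' of every V ATG, so the
  longest-ORF rule cannot extend a V call beyond its planted start;
* the F-G-x-G anchor occupies the *last* four J codons and occurs nowhere
  else in the J, so the shortest-donor rule ends every J call exactly at the
  planted splice donor;
* D cores contain no stop-codon triplet at any offset, and N regions of
  transcripts forced in-frame are resampled (with an all-C fallback that is
  stop-free across every junction boundary) until the V→J read-through is
  stop-free.

All outputs are bit-reproducible given (config, seed). Truth flags are
computed during construction, never by running the analyzer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rss import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from .seq_core import SeqRecord, revcomp, translate, global_align

NONCANONICAL_HEPTAMER = "CACAGCA"  # functional variant seen in squamate loci
TRBD_CONSERVED_CORE = "GGGACAGGGGGC"  # deeply conserved vertebrate TRBD sequence

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# codons per amino acid, for reverse-translating designed protein stretches
_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "AGA"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC", "ACA"], "V": ["GTT", "GTC", "GTA"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_POLAR = list("DENQSTGHPY")  # negative hydropathy, no charge-pattern confounders
_HYDROPHOBIC = list("LIVF")


@dataclass
class LocusConfig:
    """Architecture and sequence-divergence parameters of a synthetic locus."""

    n_v: int = 16
    n_d: int = 3
    n_j: int = 6
    n_c: int = 1
    n_families: int = 8
    within_family_identity: float = 85.0
    between_family_identity: float = 70.0
    n_inverted_v: int = 1
    gap_range: tuple[int, int] = (200, 800)
    v_len: int = 300
    j_len: int = 48
    locus_prefix: str = "TRB"
    noncanonical_heptamer: bool = False
    tm_chain_class: str = "K_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inverted_v > self.n_v:
            raise ValueError("n_inverted_v cannot exceed n_v")
        if self.n_v and not (1 <= self.n_families <= self.n_v):
            raise ValueError("n_families must be in [1, n_v]")
        for target in (self.within_family_identity, self.between_family_identity):
            if not (0 < target <= 100):
                raise ValueError("identity targets must be in (0, 100]")
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError("within-family identity must exceed between-family identity")
        if self.v_len % 3 or self.j_len % 3:
            raise ValueError("v_len and j_len must be multiples of 3")

    @property
    def heptamer(self) -> str:
        return NONCANONICAL_HEPTAMER if self.noncanonical_heptamer else HEPTAMER_CONSENSUS


@dataclass
class RecombinationConfig:
    """Controls of the V(D)J junction simulator.

    Default fractions reproduce the composition reported for skink TRB
    spleen transcripts: 52.6% of transcripts 5'-complete and 80% of complete
    transcripts productive.
    """

    n_transcripts: int = 38
    trim_max_v: int = 6
    trim_max_d: int = 3  # per D end
    trim_max_j: int = 4
    n_addition_max: int = 6
    target_frame_fraction: float = 0.8
    incomplete_5p_fraction: float = 0.474
    allow_vj_direct: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.target_frame_fraction, self.incomplete_5p_fraction):
            if not (0 <= p <= 1):
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Construction-time truth: segment table and (optionally) transcript table."""

    segments: pd.DataFrame
    transcripts: pd.DataFrame | None = None

    def germline(self, kind: str) -> list[SeqRecord]:
        sub = self.segments[self.segments["kind"] == kind]
        return [SeqRecord(id=r["name"], seq=r["sequence"]) for _, r in sub.iterrows()]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _random_orf(rng: np.random.Generator, n_nt: int) -> str:
    """ATG-initiated open reading frame with no internal stop, length n_nt."""
    codons = ["ATG"]
    while len(codons) < n_nt // 3:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _mutate_member(rng: np.random.Generator, proto: str, n_mut: int) -> str:
    """Substitute n_mut positions (never the ATG, never creating a stop)."""
    seq = list(proto)
    positions = rng.choice(np.arange(3, len(seq)), size=n_mut, replace=False)
    for p in positions:
        for _ in range(20):
            alt = rng.choice([b for b in "ACGT" if b != proto[p]])
            old = seq[p]
            seq[p] = alt
            codon_start = (p // 3) * 3
            if "".join(seq[codon_start : codon_start + 3]) not in _STOPS:
                break
            seq[p] = old
    return "".join(seq)


def _make_v_families(cfg: LocusConfig, rng: np.random.Generator) -> tuple[list[str], list[int]]:
    """Return n_v member sequences and their family group ids (0-based)."""
    if cfg.n_v == 0:
        return [], []
    prototypes: list[str] = []
    for _ in range(cfg.n_families):
        for _attempt in range(60):
            cand = _random_orf(rng, cfg.v_len)
            if all(
                global_align(cand, p).identity_pct <= cfg.between_family_identity
                for p in prototypes
            ):
                prototypes.append(cand)
                break
        else:
            raise RuntimeError("could not generate sufficiently divergent family prototypes")
    # balanced family sizes, then shuffled across locus positions
    group_of: list[int] = [i % cfg.n_families for i in range(cfg.n_v)]
    group_of = list(rng.permutation(group_of))
    n_mut = max(1, round(cfg.v_len * (1 - cfg.within_family_identity / 100.0) / 2))
    members: list[str] = []
    for g in group_of:
        for _attempt in range(60):
            cand = _mutate_member(rng, prototypes[g], n_mut)
            # keep members distinguishable even after 3'-end trimming
            if all(
                sum(a != b for a, b in zip(cand[:280], m[:280])) >= 5 for m in members
            ):
                members.append(cand)
                break
        else:
            raise RuntimeError("could not generate distinct family members")
    return members, [int(g) for g in group_of]


def _make_j(cfg: LocusConfig, rng: np.random.Generator) -> str:
    """J segment: stop-free frame-0 ORF whose last four codons encode F-G-x-G,
    with no other F-G-x-G occurrence."""
    n_codons = cfg.j_len // 3
    while True:
        codons = []
        while len(codons) < n_codons - 4:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                codons.append(c)
        x = rng.choice(list("QSTAVLE"))
        motif = [
            rng.choice(_CODONS["F"]), rng.choice(_CODONS["G"]),
            rng.choice(_CODONS[x]), rng.choice(_CODONS["G"]),
        ]
        seq = "".join(codons + motif)
        aa = translate(seq)
        import re

        if len(re.findall(r"(?=FG.G)", aa)) == 1 and "*" not in aa:
            return seq


def _make_d_core(rng: np.random.Generator, length: int = 12) -> str:
    """Random D core with no stop-codon triplet at any offset."""
    while True:
        cand = _random_seq(rng, length)
        if not any(s in cand for s in _STOPS):
            return cand


def _tm_protein(rng: np.random.Generator, chain_class: str, length: int = 120,
                core_start: int = 60) -> str:
    """Protein with a 19-residue hydrophobic transmembrane core carrying the
    requested charged residues (both R and K, a single K, or neither)."""
    if chain_class not in ("RK", "K_only", "none"):
        raise ValueError(f"unknown chain class {chain_class!r}")
    aa = list(rng.choice(_POLAR, length))
    core = list(rng.choice(_HYDROPHOBIC, 19))
    if chain_class == "RK":
        core[5], core[12] = "R", "K"
    elif chain_class == "K_only":
        core[9] = "K"
    aa[core_start : core_start + 19] = core
    return "".join(aa)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[a]) for a in protein)


def _make_c(cfg: LocusConfig, rng: np.random.Generator) -> str:
    protein = _tm_protein(rng, cfg.tm_chain_class, length=130, core_start=85)
    return _reverse_translate(rng, protein)


def generate_locus(cfg: LocusConfig) -> tuple[SeqRecord, GroundTruth]:
    """Build a synthetic locus sequence plus its construction-time truth table."""
    rng = np.random.default_rng(cfg.seed)
    hept = cfg.heptamer
    hept_rc = revcomp(hept)
    nona = NONAMER_CONSENSUS
    nona_rc = revcomp(nona)

    v_seqs, v_groups = _make_v_families(cfg, rng)
    j_seqs = [_make_j(cfg, rng) for _ in range(cfg.n_j)]
    d_cores = [TRBD_CONSERVED_CORE] + [_make_d_core(rng) for _ in range(max(0, cfg.n_d - 1))]
    d_cores = d_cores[: cfg.n_d]
    c_seqs = [_make_c(cfg, rng) for _ in range(cfg.n_c)]

    parts: list[str] = []
    pos = 0
    rows: list[dict] = []

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    def gap() -> None:
        lo, hi = cfg.gap_range
        emit(_random_seq(rng, int(rng.integers(lo, hi + 1))))

    def spacer(n: int) -> str:
        return _random_seq(rng, n)

    gap()
    n_forward_v = cfg.n_v - cfg.n_inverted_v
    for i in range(n_forward_v):
        emit("TAA")  # ORF guard: blocks any longer V window in frame
        start = pos
        emit(v_seqs[i])
        rows.append(dict(kind="V", start=start, end=pos, strand="+",
                         group=v_groups[i], sequence=v_seqs[i]))
        emit(hept + spacer(23) + nona)
        gap()
    for core in d_cores:
        emit(nona_rc + spacer(12) + hept_rc)
        start = pos
        emit(core)
        rows.append(dict(kind="D", start=start, end=pos, strand="+",
                         group=None, sequence=core))
        emit(hept + spacer(23) + nona)
        gap()
    for j in j_seqs:
        emit(nona_rc + spacer(12) + hept_rc)
        start = pos
        emit(j)
        rows.append(dict(kind="J", start=start, end=pos, strand="+",
                         group=None, sequence=j))
        emit("GT")  # splice donor
        gap()
    for c in c_seqs:
        start = pos
        emit(c)
        rows.append(dict(kind="C", start=start, end=pos, strand="+",
                         group=None, sequence=c))
        gap()
    for i in range(n_forward_v, cfg.n_v):
        # inverted V 3' of C: reverse complement of [TAA][V][hept][spacer][nona]
        emit(nona_rc + spacer(23) + hept_rc)
        start = pos
        emit(revcomp(v_seqs[i]))
        rows.append(dict(kind="V", start=start, end=pos, strand="-",
                         group=v_groups[i], sequence=v_seqs[i]))
        emit("TTA")  # the guard, mirrored
        gap()

    seq = "".join(parts)
    truth = _finalize_truth(rows, cfg.locus_prefix)
    return SeqRecord(id=f"synthetic_{cfg.locus_prefix}_locus", seq=seq), truth


def _finalize_truth(rows: list[dict], prefix: str) -> GroundTruth:
    rows = sorted(rows, key=lambda r: r["start"])
    # family labels: contiguous from 1 in order of each family's 5'-most member
    label_of: dict[int, int] = {}
    for r in rows:
        if r["kind"] == "V" and r["group"] not in label_of:
            label_of[r["group"]] = len(label_of) + 1
    counts = {"D": 0, "J": 0, "C": 0}
    n_c = sum(1 for r in rows if r["kind"] == "C")
    members: dict[int, int] = {}
    out = []
    for r in rows:
        if r["kind"] == "V":
            fam = label_of[r["group"]]
            members[fam] = members.get(fam, 0) + 1
            name = f"{prefix}V{fam}.{members[fam]}"
            family = fam
        else:
            counts[r["kind"]] += 1
            name = f"{prefix}{r['kind']}" + (
                "" if r["kind"] == "C" and n_c == 1 else str(counts[r["kind"]])
            )
            family = None
        out.append(dict(name=name, kind=r["kind"], start=r["start"], end=r["end"],
                        strand=r["strand"], family=family, sequence=r["sequence"]))
    return GroundTruth(segments=pd.DataFrame(out))


# ---------------------------------------------------------------------------
# repertoire simulation


def _stop_free_region(rng: np.random.Generator, pieces: list[str], var_idx: list[int],
                      attempts: int = 40) -> list[str]:
    """Resample the N-region pieces until the concatenation translates without
    a stop; fall back to all-C N regions (stop-free across every boundary by
    construction of the fixed pieces)."""
    for _ in range(attempts):
        if "*" not in translate("".join(pieces)):
            return pieces
        for i in var_idx:
            pieces[i] = _random_seq(rng, len(pieces[i]))
    # Stop codons contain no C, so all-C N regions shield every boundary
    # codon they touch; empty N regions are grown by one frame-neutral codon
    # so that no fixed pieces remain in direct contact.
    for i in var_idx:
        pieces[i] = "C" * (len(pieces[i]) or 3)
    assert "*" not in translate("".join(pieces))
    return pieces


def simulate_repertoire(
    truth: GroundTruth, cfg: RecombinationConfig
) -> tuple[list[SeqRecord], GroundTruth]:
    """Simulate V(D)J-recombined transcripts from a locus truth table.

    Joins follow the 12/23 rule of the planted architecture (V→D via 23↔12,
    D→J via 23↔12; direct V→J joins only when no D exists or explicitly
    allowed). Trims and N-addition lengths are uniform; the junction length is
    adjusted (mod 3) to force the configured fraction of frame-preserving
    joins, and frame-preserving junctions are made stop-free so that
    ``productive`` of complete transcripts equals ``target_frame_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    segs = truth.segments
    vs = segs[segs["kind"] == "V"].reset_index(drop=True)
    ds = segs[segs["kind"] == "D"].reset_index(drop=True)
    js = segs[segs["kind"] == "J"].reset_index(drop=True)
    cs = segs[segs["kind"] == "C"].reset_index(drop=True)
    if len(vs) == 0 or len(js) == 0 or len(cs) == 0:
        raise ValueError("repertoire simulation requires at least one V, J and C")
    use_d = len(ds) > 0 and not cfg.allow_vj_direct

    records: list[SeqRecord] = []
    rows: list[dict] = []
    for t in range(cfg.n_transcripts):
        v = vs.iloc[int(rng.integers(len(vs)))]
        j = js.iloc[int(rng.integers(len(js)))]
        c = cs.iloc[0]
        tv = int(rng.integers(0, cfg.trim_max_v + 1))
        tj = int(rng.integers(0, cfg.trim_max_j + 1))
        vp = v["sequence"][: len(v["sequence"]) - tv]
        jp = j["sequence"][tj:]
        if use_d:
            d = ds.iloc[int(rng.integers(len(ds)))]
            td5 = int(rng.integers(0, cfg.trim_max_d + 1))
            td3 = int(rng.integers(0, cfg.trim_max_d + 1))
            dp = d["sequence"][td5 : len(d["sequence"]) - td3]
            d_name = d["name"]
        else:
            dp, td5, td3, d_name = "", 0, 0, None
        n1 = _random_seq(rng, int(rng.integers(0, cfg.n_addition_max + 1)))
        n2 = _random_seq(rng, int(rng.integers(0, cfg.n_addition_max + 1)))

        in_frame = bool(rng.random() < cfg.target_frame_fraction)
        p_c = len(vp) + len(n1) + len(dp) + len(n2) + len(jp)
        if in_frame:
            delta = (-p_c) % 3
        else:
            want = int(rng.integers(1, 3))
            delta = (want - p_c) % 3
        n2 = n2 + _random_seq(rng, delta)
        pieces = [vp, n1, dp, n2, jp]
        if in_frame:
            pieces = _stop_free_region(rng, pieces, var_idx=[1, 3])
            n1, n2 = pieces[1], pieces[3]
        region = "".join(pieces)
        p_c = len(region)
        has_stop = "*" in translate(region)
        transcript = region + c["sequence"]

        complete = bool(rng.random() >= cfg.incomplete_5p_fraction)
        if not complete:
            lv = len(v["sequence"])
            u = int(rng.integers(math.ceil(0.10 * lv), math.floor(0.80 * lv) + 1))
            transcript = transcript[u:]
        productive = complete and in_frame and not has_stop
        tid = f"tx{t:04d}"
        records.append(SeqRecord(id=tid, seq=transcript))
        rows.append(dict(
            transcript_id=tid, v_name=v["name"], d_name=d_name, j_name=j["name"],
            c_name=c["name"], trim_v=tv, trim_d5=td5, trim_d3=td3, trim_j=tj,
            n1=n1, n2=n2, junction=n1 + dp + n2,
            complete_5p=complete, in_frame=in_frame, has_stop=has_stop,
            productive=productive,
        ))
    return records, GroundTruth(segments=segs, transcripts=pd.DataFrame(rows))


def generate_tm_chain(chain_class: str, seed: int = 0, length: int = 120) -> SeqRecord:
    """A synthetic receptor-chain protein with a planted transmembrane core of
    the requested charge class (``RK``, ``K_only`` or ``none``)."""
    rng = np.random.default_rng(seed)
    return SeqRecord(
        id=f"tm_{chain_class}_{seed}",
        seq=_tm_protein(rng, chain_class, length=length, core_start=(length - 19) // 2),
        moltype="aa",
    )
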