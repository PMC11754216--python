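"""Targeted flanking-gene comparison between two annotated genomic regions.

Loci embedded between conserved flanking genes can be compared across species
by matching the flankers by name (case-insensitive, with an optional alias
table for genes named differently across assemblies, e.g. DBHL/MOXD2/MOXD2P
or EPHB6/EPHB5-like) and measuring the boundary-to-boundary distance between
the designated 5' and 3' flankers in each region. A large gap in one species
and a small one in another flags insertion or loss of the intervening locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq_core import Interval


@dataclass(frozen=True)
class GeneAnnotation:
    gene_name: str
    ivl: Interval
    strand: str = "+"


@dataclass
class SyntenyReport:
    # (canonical name, interval in a, interval in b, same relative order)
    shared_genes: list[tuple[str, Interval, Interval, bool]]
    locus_gap_a: int | None = None
    locus_gap_b: int | None = None
    absent_flankers: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(gene=name, start_a=ia.start, end_a=ia.end,
                     start_b=ib.start, end_b=ib.end, same_order=order)
                for name, ia, ib, order in self.shared_genes
            ]
        )


def _canonical(name: str, aliases: dict[str, str] | None) -> str:
    key = name.upper()
    if aliases:
        key = {k.upper(): v.upper() for k, v in aliases.items()}.get(key, key)
    return key


def gap_between(
    region: list[GeneAnnotation],
    five_prime: str,
    three_prime: str,
    aliases: dict[str, str] | None = None,
) -> int:
    """Distance from the inner boundary of one flanker to the inner boundary
    of the other, orientation-normalized (never negative, 0 when adjacent or
    overlapping)."""
    by_name = {_canonical(g.gene_name, aliases): g for g in region}
    genes = []
    for name in (five_prime, three_prime):
        key = _canonical(name, aliases)
        if key not in by_name:
            raise KeyError(f"gene {name!r} not found in region")
        genes.append(by_name[key])
    left, right = sorted(genes, key=lambda g: g.ivl.start)
    return max(0, right.ivl.start - left.ivl.end)


def shared_flankers(
    a: list[GeneAnnotation],
    b: list[GeneAnnotation],
    five_prime: str | None = None,
    three_prime: str | None = None,
    aliases: dict[str, str] | None = None,
) -> SyntenyReport:
    """Genes present in both regions, their order conservation, and the
    distance between the designated flankers in each region.

    A gene keeps ``same_order=True`` when exactly the same set of shared
    genes precedes it along the chromosome in both regions. Missing
    designated flankers are reported as absent, not raised.
    """
    if not a or not b:
        raise ValueError("both regions must contain at least one gene")
    map_a = {_canonical(g.gene_name, aliases): g for g in a}
    map_b = {_canonical(g.gene_name, aliases): g for g in b}
    shared = sorted(set(map_a) & set(map_b), key=lambda n: map_a[n].ivl.start)

    def predecessors(mapping: dict[str, GeneAnnotation], name: str) -> frozenset:
        me = mapping[name].ivl.start
        return frozenset(n for n in shared if mapping[n].ivl.start < me)

    rows = []
    for name in shared:
        rows.append(
            (
                name, map_a[name].ivl, map_b[name].ivl,
                predecessors(map_a, name) == predecessors(map_b, name),
            )
        )
    report = SyntenyReport(shared_genes=rows)
    if five_prime and three_prime:
        for region, attr in ((a, "locus_gap_a"), (b, "locus_gap_b")):
            try:
                setattr(report, attr, gap_between(region, five_prime, three_prime, aliases))
            except KeyError:
                names = {_canonical(g.gene_name, aliases) for g in region}
                for want in (five_prime, three_prime):
                    if _canonical(want, aliases) not in names:
                        report.absent_flankers.append(want)
    return report


def read_region_tsv(path) -> list[GeneAnnotation]:
    """3/4-column TSV (gene, start, end[, strand]) → gene annotations."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("region TSV needs at least gene, start, end columns")
    out = []
    for row in df.itertuples(index=False):
        strand = row[3] if len(row) > 3 and row[3] in ("+", "-") else "+"
        out.append(GeneAnnotation(str(row[0]), Interval(int(row[1]), int(row[2]), strand), strand))
    return out
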