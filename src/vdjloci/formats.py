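"""Writers for the interchange formats the pipeline emits.

Internally everything is 0-based half-open; GFF3 output is 1-based inclusive
per the format, BED-like TSV stays 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import GeneSegment
from .rss import RssHit

_GFF_TYPE = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}


def write_segments_gff3(segments: list[GeneSegment], seqid: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seg in sorted(segments, key=lambda s: s.ivl.start):
            attrs = f"ID={seg.name};Name={seg.name}"
            if seg.family:
                attrs += f";gene_family={seg.family}"
            fh.write(
                "\t".join(
                    [
                        seqid, "vdjloci", _GFF_TYPE[seg.kind],
                        str(seg.ivl.start + 1), str(seg.ivl.end), ".", seg.strand, ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_rss_gff3(hits: list[RssHit], seqid: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, hit in enumerate(hits):
            start = min(hit.heptamer_ivl.start, hit.nonamer_ivl.start)
            end = max(hit.heptamer_ivl.end, hit.nonamer_ivl.end)
            fh.write(
                "\t".join(
                    [
                        seqid, "vdjloci", "recombination_signal_sequence",
                        str(start + 1), str(end), f"{hit.score:.2f}", hit.strand, ".",
                        f"ID=rss{k};spacer_class={hit.spacer_class};spacer_len={hit.spacer_len}"
                        f";heptamer={hit.heptamer_seq};nonamer={hit.nonamer_seq}",
                    ]
                )
                + "\n"
            )


def rss_to_bed_frame(hits: list[RssHit], seqid: str) -> pd.DataFrame:
    rows = []
    for k, hit in enumerate(hits):
        start = min(hit.heptamer_ivl.start, hit.nonamer_ivl.start)
        end = max(hit.heptamer_ivl.end, hit.nonamer_ivl.end)
        rows.append(
            dict(chrom=seqid, start=start, end=end,
                 name=f"rss{k}_{hit.spacer_class}", score=round(hit.score, 2),
                 strand=hit.strand)
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
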