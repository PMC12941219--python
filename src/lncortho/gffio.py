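"""GFF3 / BED / TSV writers.

Internal coordinates are 0-based half-open; GFF3 output is 1-based inclusive,
BED output 0-based half-open. Conversion happens only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

from .seq import GenomicInterval

GffFeature = Tuple[GenomicInterval, str, str]  # (interval, type, attributes)


def write_gff3(features: Iterable[GffFeature], path, source: str = "lncortho") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates: 1-based inclusive (converted from internal 0-based half-open)\n")
        for iv, ftype, attrs in features:
            fh.write("\t".join([
                iv.seq_id, source, ftype,
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".", attrs,
            ]) + "\n")


def write_bed(intervals: Iterable[Tuple[GenomicInterval, str, float]], path) -> None:
    """BED6; score clipped to [0, 1000]."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for iv, name, score in intervals:
            sc = int(max(0, min(1000, round(score))))
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{sc}\t{iv.strand}\n")


def write_tsv(rows: Iterable[Sequence], path, header: Sequence[str],
              comment: Optional[str] = "coordinates: 0-based half-open") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
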