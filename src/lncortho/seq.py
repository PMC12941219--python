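"""DNA sequence primitives, intervals and k-mer counting.

Coordinates are 0-based half-open throughout the package; BED output keeps
that convention, GFF3 output converts to 1-based inclusive (see
:mod:`lncortho.gffio`).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np

ALPHABET = "ACGTN"
_ALPHABET_SET = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer encoding used by the vectorised k-mer counter (N -> 4)
_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


class SequenceError(ValueError):
    """Raised for inputs violating the DNA alphabet or interval contracts."""


@dataclass
class DnaSequence:
    """A named DNA sequence over {A,C,G,T,N} with free-form metadata."""

    id: str
    residues: str
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, new_id: Optional[str] = None) -> "DnaSequence":
        if not (0 <= start < end <= len(self.residues)):
            raise SequenceError(
                f"slice [{start}, {end}) out of bounds for {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return DnaSequence(new_id or f"{self.id}:{start}-{end}", self.residues[start:end],
                           dict(self.meta))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise SequenceError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise SequenceError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.seq_id == other.seq_id
                and self.start < other.end and other.start < self.end)

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.seq_id, self.start + offset, self.end + offset,
                               self.strand)


@dataclass
class Hsp:
    """One local-alignment high-scoring pair.

    ``pident`` is the percentage of alignment columns that are identical;
    ``aln_length`` counts alignment columns (including gap columns).
    ``weighted_length`` is the identity-weighted length used by the ANI
    statistic (pident/100 x aln_length).
    """

    query_iv: GenomicInterval
    subject_iv: GenomicInterval
    pident: float
    aln_length: int
    strand: str
    score: float
    cigar: Optional[str] = None  # edlib extended cigar ( = / X / I / D ), query-forward frame

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise SequenceError(f"pident {self.pident} outside [0, 100]")
        if self.aln_length < 1:
            raise SequenceError("aln_length must be positive")

    @property
    def weighted_length(self) -> float:
        return self.pident / 100.0 * self.aln_length


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    """Watson-Crick reverse complement; N maps to N."""
    return DnaSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1], dict(seq.meta))


def revcomp(residues: str) -> str:
    """Reverse complement of a raw residue string."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerCounts:
    """Sliding-window k-mer counts with the number of N-containing windows skipped."""

    k: int
    counts: Dict[str, int]
    n_skipped: int

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def total(self) -> int:
        return sum(self.counts.values())


def kmer_counts(seq: DnaSequence, k: int) -> KmerCounts:
    """Count all length-k sliding windows; windows containing N are skipped.

    For an N-free sequence of length L the counts sum to L - k + 1.
    """
    if k < 1:
        raise SequenceError("k must be >= 1")
    s = seq.residues
    if k > len(s):
        import warnings

        warnings.warn(f"k={k} exceeds sequence length {len(s)}; empty counts")
        return KmerCounts(k, {}, 0)
    codes = _ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    n_windows = len(s) - k + 1
    if (codes == 4).any():
        bad = np.convolve((codes == 4).astype(np.int64), np.ones(k, dtype=np.int64),
                          mode="valid") > 0
        n_skipped = int(bad.sum())
        counts = Counter(s[i:i + k] for i in range(n_windows) if not bad[i])
    else:
        n_skipped = 0
        # polynomial rolling encode, vectorised
        val = np.zeros(n_windows, dtype=np.int64)
        for j in range(k):
            val = val * 4 + codes[j:j + n_windows]
        uniq, cnt = np.unique(val, return_counts=True)
        counts = Counter({_decode_kmer(int(u), k): int(c) for u, c in zip(uniq, cnt)})
    return KmerCounts(k, dict(counts), n_skipped)


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def possible_kmers(k: int) -> Iterator[str]:
    """Enumerate the full 4**k key space of DNA k-mers in lexicographic order."""
    for tup in itertools.product("ACGT", repeat=k):
        yield "".join(tup)


def key_space_size(k: int) -> int:
    """Number of distinct possible DNA k-mers (counted by enumeration)."""
    return sum(1 for _ in possible_kmers(k))


# ---------------------------------------------------------------------------
# FASTA and HSP-table I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[DnaSequence]:
    """Read a (multi-record) FASTA file into DnaSequence records.

    Lowercase residues are uppercased; the first whitespace-separated token of
    the header is the id, the remainder is stored under meta['description'].
    """
    records: List[DnaSequence] = []
    seen = set()
    header: Optional[str] = None
    chunks: List[str] = []

    def _flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        sid = parts[0]
        if sid in seen:
            raise SequenceError(f"duplicate FASTA id {sid!r}")
        seen.add(sid)
        meta = {"description": parts[1]} if len(parts) > 1 else {}
        records.append(DnaSequence(sid, "".join(chunks).upper(), meta))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        _flush()
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[DnaSequence], path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in seqs:
            desc = s.meta.get("description", "")
            fh.write(f">{s.id}{' ' + desc if desc else ''}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


HSP_TABLE_COLUMNS = ("qid", "sid", "qstart", "qend", "sstart", "send",
                     "strand", "pident", "length", "score")


def write_hsp_table(hsps: Iterable[Hsp], path) -> None:
    """Write HSPs as a blast outfmt-6-like TSV (0-based half-open coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write("\t".join(HSP_TABLE_COLUMNS) + "\n")
        for h in hsps:
            fh.write("\t".join(str(x) for x in (
                h.query_iv.seq_id, h.subject_iv.seq_id,
                h.query_iv.start, h.query_iv.end,
                h.subject_iv.start, h.subject_iv.end,
                h.strand, f"{h.pident:.2f}", h.aln_length, f"{h.score:.1f}",
            )) + "\n")
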