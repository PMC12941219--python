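"""PWM scanning of promoter windows with exact null p-values.

Matrices are read from JASPAR or MEME minimal text (counts get a 0.1
pseudocount per cell). Windows are scored with log2 odds against the
background; the null distribution of scores is computed exactly by dynamic
programming over the background model on a discretized lattice (1/1000 bit
granularity), so the p-value of a score is the exact tail probability of the
same lattice-rounded score under the background — identical to exhaustive
enumeration over all 4^width words. Hits are windows with p below the
threshold, deduplicated to the better-strand hit per start position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .seq import DnaSequence, GenomicInterval, SequenceError, revcomp

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1
LATTICE = 1000           # lattice steps per bit
DEFAULT_PTHRESH = 1e-4
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class Pwm:
    tf_name: str
    matrix: np.ndarray                   # (width, 4) probabilities, columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise SequenceError("PWM matrix must be (width, 4)")
        if self.width < 4:
            raise SequenceError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise SequenceError("PWM columns must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise SequenceError("background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray,
                    background: Optional[np.ndarray] = None) -> "Pwm":
        counts = np.asarray(counts, dtype=float) + PSEUDOCOUNT
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(tf_name, probs,
                   background if background is not None else np.full(4, 0.25))

    def lattice_scores(self) -> np.ndarray:
        """(width, 4) integer log-odds scores in 1/LATTICE-bit units."""
        lo = np.log2(self.matrix / self.background)
        return np.round(lo * LATTICE).astype(np.int64)


@dataclass
class TfHit:
    tf_name: str
    iv: GenomicInterval
    strand: str
    score: float        # bits
    pvalue: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_pwms(path) -> List[Pwm]:
    """Read JASPAR (>name + 4 count rows) or MEME minimal format.

    Malformed records are skipped with a warning; an empty file is an error.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise SequenceError(f"empty PWM file {path}")
    if "letter-probability matrix" in text or text.lstrip().startswith("MEME"):
        pwms = _read_meme(text)
    else:
        pwms = _read_jaspar(text)
    if not pwms:
        raise SequenceError(f"no usable PWM records in {path}")
    return pwms


def _read_jaspar(text: str) -> List[Pwm]:
    pwms: List[Pwm] = []
    blocks: List[Tuple[str, List[str]]] = []
    name = None
    lines: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                blocks.append((name, lines))
            parts = line[1:].split()
            name = parts[-1] if len(parts) > 1 else parts[0]
            lines = []
        elif name is not None:
            lines.append(line)
    if name is not None:
        blocks.append((name, lines))
    for name, lines in blocks:
        try:
            rows = {}
            for line in lines:
                base = line[0].upper()
                nums = line.split("[")[-1].split("]")[0].split() if "[" in line \
                    else line.split()[1:]
                rows[base] = [float(x) for x in nums]
            counts = np.array([rows[b] for b in "ACGT"]).T
            pwms.append(Pwm.from_counts(name, counts))
        except Exception as exc:  # malformed record
            log.warning("skipping malformed JASPAR record %s: %s", name, exc)
    return pwms


def _read_meme(text: str) -> List[Pwm]:
    pwms: List[Pwm] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            nsites = 20.0
            rows: List[List[float]] = []
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j < len(lines):
                header = lines[j]
                if "nsites=" in header:
                    try:
                        nsites = float(header.split("nsites=")[1].split()[0])
                    except (ValueError, IndexError):
                        pass
                j += 1
                while j < len(lines):
                    vals = lines[j].split()
                    if len(vals) == 4:
                        try:
                            rows.append([float(v) for v in vals])
                        except ValueError:
                            break
                        j += 1
                    else:
                        break
            if rows:
                try:
                    pwms.append(Pwm.from_counts(name, np.array(rows) * nsites))
                except SequenceError as exc:
                    log.warning("skipping malformed MEME record %s: %s", name, exc)
            else:
                log.warning("skipping malformed MEME record %s", name)
            i = j
        else:
            i += 1
    return pwms


def write_jaspar(pwms: Sequence[Pwm], path, nsites: int = 100) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.tf_name} {p.tf_name}\n")
            counts = np.round(p.matrix * nsites, 2)
            for bi, b in enumerate("ACGT"):
                row = " ".join(f"{counts[w, bi]:.2f}" for w in range(p.width))
                fh.write(f"{b} [ {row} ]\n")


# ---------------------------------------------------------------------------
# scanning with exact DP p-values
# ---------------------------------------------------------------------------

def null_distribution(pwm: Pwm) -> Tuple[np.ndarray, int]:
    """Exact null pmf of lattice scores under the background.

    Returns (pmf, offset) where pmf[k] = P(score_int = k + offset).
    """
    scores = pwm.lattice_scores()
    lo = int(scores.min(axis=1).sum())
    hi = int(scores.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    pmf[-lo if lo < 0 else 0] = 0.0
    # start with the first position
    cur = np.zeros(int(scores[0].max() - scores[0].min()) + 1)
    base = int(scores[0].min())
    for b in range(4):
        cur[int(scores[0, b]) - base] += pwm.background[b]
    offset = base
    for w in range(1, pwm.width):
        smin, smax = int(scores[w].min()), int(scores[w].max())
        nxt = np.zeros(cur.size + smax - smin)
        for b in range(4):
            sh = int(scores[w, b]) - smin
            nxt[sh:sh + cur.size] += pwm.background[b] * cur
        cur = nxt
        offset += smin
    return cur, offset


def score_pvalue_fn(pwm: Pwm):
    """Callable mapping a lattice score to its exact tail p-value."""
    pmf, offset = null_distribution(pwm)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(score >= offset + k)

    def pvalue(score_int: int) -> float:
        k = score_int - offset
        if k < 0:
            return 1.0
        if k >= sf.size:
            return float(sf[-1])
        return float(sf[k])

    return pvalue


def _window_scores(residues: str, scores: np.ndarray) -> np.ndarray:
    """Lattice score of every window; N-containing windows get INT_MIN."""
    w = scores.shape[0]
    codes = np.full(len(residues), 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(residues.encode(), dtype=np.uint8) == ord(b)] = i
    n = len(residues) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        c = codes[i:i + n]
        valid &= c != 4
        total += np.where(c != 4, scores[i, np.minimum(c, 3)], 0)
    total[~valid] = np.iinfo(np.int64).min
    return total


def scan_pwm(seq: DnaSequence, pwm: Pwm, pthresh: float = DEFAULT_PTHRESH,
             both_strands: bool = True) -> List[TfHit]:
    """Scan a sequence with one PWM; report hits with exact p < pthresh.

    Minus-strand windows are reported at their forward-frame interval;
    when both strands hit the same start position only the better-scoring
    strand is kept.
    """
    if len(seq) < pwm.width:
        raise SequenceError("sequence shorter than PWM width")
    scores = pwm.lattice_scores()
    pvalue = score_pvalue_fn(pwm)
    w = pwm.width
    L = len(seq)
    best: Dict[int, Tuple[int, str]] = {}

    fwd = _window_scores(seq.residues, scores)
    for pos in np.nonzero(fwd > np.iinfo(np.int64).min)[0]:
        best[int(pos)] = (int(fwd[pos]), "+")
    if both_strands:
        rev = _window_scores(revcomp(seq.residues), scores)
        for pos in np.nonzero(rev > np.iinfo(np.int64).min)[0]:
            fpos = L - int(pos) - w
            sc = int(rev[pos])
            if fpos not in best or sc > best[fpos][0]:
                best[fpos] = (sc, "-")

    hits = []
    for pos, (sc, strand) in sorted(best.items()):
        p = pvalue(sc)
        if p < pthresh:
            hits.append(TfHit(pwm.tf_name,
                              GenomicInterval(seq.id, pos, pos + w, strand),
                              strand, sc / LATTICE, p))
    return hits


def scan_many(seq: DnaSequence, pwms: Sequence[Pwm],
              pthresh: float = DEFAULT_PTHRESH) -> List[TfHit]:
    out: List[TfHit] = []
    for p in pwms:
        out.extend(scan_pwm(seq, p, pthresh))
    return out


# ---------------------------------------------------------------------------
# shared-TF analysis
# ---------------------------------------------------------------------------

def shared_tfs(hits_per_gene: Dict[str, set], fraction: float = 0.65
               ) -> List[str]:
    """TFs with at least one hit in >= fraction of the genes.

    Sorted by prevalence (descending), then name.
    """
    if len(hits_per_gene) < 2:
        raise SequenceError("need at least two genes")
    n = len(hits_per_gene)
    prevalence: Dict[str, int] = {}
    for tf_set in hits_per_gene.values():
        for tf in tf_set:
            prevalence[tf] = prevalence.get(tf, 0) + 1
    return [tf for tf, c in sorted(prevalence.items(), key=lambda t: (-t[1], t[0]))
            if c / n >= fraction]


def shared_between(tfs_a: Iterable[str], tfs_b: Iterable[str]) -> List[str]:
    """Overlap of two shared-TF lists (e.g. the two genes' regulomes)."""
    return sorted(set(tfs_a) & set(tfs_b))


def go_join(tfs: Iterable[str], tf_to_terms: Dict[str, Sequence[str]]
            ) -> List[Tuple[str, int, List[str]]]:
    """Plain join of TFs against a TF->GO-term table with term counting."""
    term_tfs: Dict[str, set] = {}
    for tf in tfs:
        for term in tf_to_terms.get(tf, ()):
            term_tfs.setdefault(term, set()).add(tf)
    return [(term, len(tf_set), sorted(tf_set))
            for term, tf_set in sorted(term_tfs.items(),
                                       key=lambda t: (-len(t[1]), t[0]))]
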