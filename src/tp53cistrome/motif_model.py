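"""Position weight matrix scoring for TP53 response elements.

TP53 binds DNA as a tetramer; the functional recognition sequence is a
duplicated copy of the palindromic half-site RRRCWWGYYY with no spacer,
i.e. a 20-bp full site.  This module provides PWM parsing (JASPAR counts
and Cluster-Buster ``>name`` blocks), log-likelihood-ratio scanning of
both strands, a homotypic cluster (CRM) score that chains multiple
non-overlapping hits, and rank-based ROC/AUC evaluation of motif scores
as classifiers of enhancer responsiveness.

Scores are log2 odds (bits) against a zero-order background model, so a
uniform matrix scores 0 everywhere and windows containing N score -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Per-position nucleotide probability matrix with background model.

    ``matrix`` is L x 4 over A,C,G,T; rows sum to 1.  ``background`` is the
    zero-order base composition used in the log-odds denominator.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p/bg); zero-probability cells map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    def consensus(self) -> str:
        """Most probable base per column (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def truncate(self, length: int, name: str | None = None) -> "PWM":
        """First ``length`` columns, e.g. one half-site of the tetramer."""
        return PWM(name or f"{self.name}_1-{length}",
                   self.matrix[:length].copy(), self.background.copy(),
                   self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    pwm_name: str
    offset: int
    strand: str
    llr_score: float
    length: int = 0

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


# The half-site consensus RRRCWWGYYY (R = A/G, W = A/T, Y = C/T) expressed as
# column probabilities; argmax per column spells GGGCAAGCCC.  The full site is
# this half-site duplicated with zero spacer (the tetramer-bound element).
# The C and G of the CWWG core are treated as near-invariant: functional
# response elements essentially never tolerate substitutions there, so the
# consensus-derived matrix keeps only a 1-2% soft count off-consensus.
_HALF_SITE_COLUMNS = {
    "R": (0.40, 0.01, 0.57, 0.02),
    "C": (0.005, 0.985, 0.005, 0.005),
    "W": (0.52, 0.01, 0.01, 0.46),
    "G": (0.005, 0.005, 0.985, 0.005),
    "Y": (0.01, 0.52, 0.01, 0.46),
}


def tp53_tetramer_pwm(name: str = "TP53_tetramer") -> PWM:
    """Consensus-derived 20-column PWM for the duplicated RRRCWWGYYY element."""
    half = [_HALF_SITE_COLUMNS[c] for c in "RRRCWWGYYY"]
    return PWM(name, np.array(half * 2, dtype=float))


def load_pwm(path, pseudocount: float = 0.0,
             background: np.ndarray | None = None) -> list[PWM]:
    """Parse PWMs from JASPAR counts or Cluster-Buster ``>name`` blocks.

    Counts are converted to probabilities column-wise with ``pseudocount``
    added to every cell.  Returns all matrices found in the file.
    """
    with open(path) as fh:
        lines = fh.readlines()
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)

    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []  # Cluster-Buster: one line per position
    jaspar: dict[str, list[float]] = {}  # JASPAR: one line per base

    def flush(lineno: int) -> None:
        nonlocal rows, jaspar
        if name is None:
            return
        if jaspar:
            if set(jaspar) != set(BASES):
                raise ValueError(f"line {lineno}: incomplete JASPAR matrix for {name}")
            counts = np.array([jaspar[b] for b in BASES], float).T
        elif rows:
            counts = np.array(rows, float)
        else:
            raise ValueError(f"line {lineno}: matrix {name} has no rows")
        counts = counts + pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError(f"matrix {name}: all-zero column and zero pseudocount")
        pwms.append(PWM(name, counts / totals, bg.copy(), pseudocount))
        rows, jaspar = [], {}

    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(i)
            name = line[1:].split()[0]
            continue
        fields = line.replace("[", " ").replace("]", " ").split()
        if fields[0].upper() in _CODE and not _is_number(fields[0]):
            base, vals = fields[0].upper(), fields[1:]
            if not vals or not all(_is_number(v) for v in vals):
                raise ValueError(f"line {i}: non-numeric JASPAR counts")
            jaspar[base] = [float(v) for v in vals]
        else:
            if len(fields) < 4 or not all(_is_number(v) for v in fields[:4]):
                raise ValueError(f"line {i}: expected 4 numeric fields, got {line!r}")
            rows.append([float(v) for v in fields[:4]])
    flush(len(lines))
    if not pwms:
        raise ValueError("no PWM found in file")
    return pwms


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """LLR of every forward-strand window; N-containing windows are -inf."""
    L = len(pwm)
    n = codes.size - L + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than PWM length {L}")
    lo = pwm.log_odds
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        c = codes[i:i + n]
        bad = c >= 4
        valid &= ~bad
        scores += np.where(bad, 0.0, lo[i, np.minimum(c, 3)])
    scores[~valid] = -np.inf
    return scores


def strand_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(plus, minus) window LLRs indexed by 0-based offset in ``seq``.

    The minus-strand score at offset o is the forward score of the reverse
    complement of seq[o:o+L].
    """
    plus = window_scores(pwm, encode(seq))
    minus = window_scores(pwm, encode(reverse_complement(seq)))[::-1]
    return plus, minus


def score_sequence(pwm: PWM, seq: str) -> MotifHit:
    """Best-scoring window over all offsets and both strands.

    Ties break toward the smallest offset, then the + strand.
    """
    plus, minus = strand_scores(pwm, seq)
    best = np.maximum(plus, minus)
    offset = int(best.argmax())  # argmax returns the first (smallest) offset
    strand = "+" if plus[offset] >= minus[offset] else "-"
    return MotifHit(pwm.name, offset, strand, float(best[offset]), len(pwm))


def _positive_hits(pwms: list[PWM], seq: str) -> list[MotifHit]:
    hits = []
    for pwm in pwms:
        plus, minus = strand_scores(pwm, seq)
        for strand, arr in (("+", plus), ("-", minus)):
            for off in np.nonzero(arr > 0)[0]:
                hits.append(MotifHit(pwm.name, int(off), strand,
                                     float(arr[off]), len(pwm)))
    return hits


def crm_score(pwms: list[PWM] | PWM, seq: str, gap_penalty: float = 0.0) -> float:
    """Homotypic cluster score: greedy chain of non-overlapping positive hits.

    Hits are accepted in decreasing score order, skipping overlaps; the chain
    score is the sum of accepted scores minus ``gap_penalty`` per 100 bp of
    inter-hit gap.  With a single positive hit this reduces to the best
    single-site score; with no positive hit the best (non-positive) single
    score is returned so the reduction property holds everywhere.
    """
    if isinstance(pwms, PWM):
        pwms = [pwms]
    if not pwms:
        raise ValueError("at least one PWM required")
    hits = _positive_hits(pwms, seq)
    if not hits:
        return max(score_sequence(p, seq).llr_score for p in pwms)
    hits.sort(key=lambda h: (-h.llr_score, h.offset, h.strand))
    accepted: list[MotifHit] = []
    for h in hits:
        if all(h.end <= a.offset or h.offset >= a.end for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: h.offset)
    total = sum(h.llr_score for h in accepted)
    gaps = sum(max(0, b.offset - a.end)
               for a, b in zip(accepted, accepted[1:]))
    return total - gap_penalty * gaps / 100.0


def feature_vector(pwms: list[PWM], seq: str) -> np.ndarray:
    """Per-PWM best-window LLR, in the order the PWMs are given."""
    return np.array([score_sequence(p, seq).llr_score for p in pwms])


def feature_matrix(pwms: list[PWM], seqs) -> np.ndarray:
    """Stack of feature_vector over sequences (n_seqs x n_pwms)."""
    return np.vstack([feature_vector(pwms, s) for s in seqs])


def roc_auc(scores_pos, scores_neg) -> ROCResult:
    """ROC curve and AUC via the rank (Mann-Whitney) formulation.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), computed from midranks so
    ties are handled exactly; the curve is a sweep over pooled thresholds.
    """
    from scipy.stats import rankdata

    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    auc = (ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2) \
        / (pos.size * neg.size)

    thresholds = np.concatenate([[np.inf], np.unique(pooled)[::-1]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return ROCResult(thresholds, sens, spec, float(auc))
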