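"""PWM scoring and allele-specific TF binding-site prediction.

A candidate regulatory variant is evaluated by scanning the 101-base
per-allele sequence (50 bp of flank either side) against a position weight
matrix on both strands, restricted to windows that overlap the variable
base. Scores are min-max normalized log2-odds ("relative score", in [0,1]);
a match requires relative score >= 0.8, and a *differential* (genotype
sensitive) call additionally requires information content >= 1 bit at the
PWM column aligned to the variable base. Fold-affinity between two alleles
is the ratio of that column's (pseudocounted) base probabilities. Candidate
TFs are finally filtered for logical consistency between their expression
correlation with the target gene and the allele their site prefers.

JASPAR PFM text is parsed and written via Bio.motifs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .simulate import VariantContext

__all__ = [
    "PWM",
    "AlleleBindingCall",
    "TFCandidate",
    "parse_jaspar_pfm",
    "write_jaspar_pfm",
    "relative_score",
    "scan_allele",
    "column_ic",
    "differential_binding",
    "fold_affinity",
    "prioritize_tf",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass
class PWM:
    """Position frequency matrix with pseudocount and background.

    ``counts`` is 4 x L with rows ordered A, C, G, T. The pseudocount is
    distributed in proportion to the background (JASPAR convention):
    p[b, j] = (counts[b, j] + pseudocount * bg[b]) / (colsum[j] + pseudocount).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"counts must be 4 x L with L >= 1, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) == 0).any():
            j = int(np.argmax(self.counts.sum(axis=0) == 0))
            raise ValueError(f"column {j} has all-zero counts")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if (self.background <= 0).any() or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be strictly positive and sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount
        )

    def log_odds(self) -> np.ndarray:
        """Per-base log2-odds versus background; -inf where probability is 0."""
        p = self.probabilities()
        with np.errstate(divide="ignore"):
            return np.log2(p / self.background[:, None])

    def consensus(self) -> str:
        return "".join(BASES[int(i)] for i in np.argmax(self.probabilities(), axis=0))


@dataclass
class AlleleBindingCall:
    motif: str
    allele: str
    best_relative_score: float
    best_offset: int
    strand: str
    is_match: bool
    aligned_column: int | None
    column_ic: float | None


@dataclass
class TFCandidate:
    tf_name: str
    correlation_sign: str  # '+' or '-'
    increased_expression_allele: str
    higher_affinity_allele: str | None
    fold_affinity: float | None
    verdict: str  # retained | inconsistent | not_genotype_sensitive


def parse_jaspar_pfm(text: str) -> PWM:
    """Parse one JASPAR PFM record ('>' header + four base rows).

    Rows may appear in any base order and with or without brackets; they are
    normalized to A, C, G, T.
    """
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("line 1: expected JASPAR header starting with '>'")
    try:
        motif = bio_motifs.read(io.StringIO("\n".join(lines)), "jaspar")
    except Exception as exc:  # re-raise with a parse-error contract
        raise ValueError(f"JASPAR parse failed: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    widths = {len(motif.counts[b]) for b in BASES}
    if len(widths) != 1:
        raise ValueError("ragged PFM rows (unequal column counts)")
    if (counts < 0).any():
        b, j = np.argwhere(counts < 0)[0]
        raise ValueError(f"negative count at base {BASES[b]}, column {j}")
    name = motif.matrix_id or motif.name or lines[0][1:].split()[0]
    return PWM(name=str(name), counts=counts)


def write_jaspar_pfm(pwm: PWM) -> str:
    """Serialize to JASPAR 2016 PFM text (bracketed rows)."""
    lines = [f">{pwm.name} {pwm.name}"]
    for i, b in enumerate(BASES):
        vals = " ".join(
            f"{v:g}" for v in pwm.counts[i]
        )
        lines.append(f"{b}  [ {vals} ]")
    return "\n".join(lines) + "\n"


def _window_scores(pwm: PWM, window: str) -> float:
    lo = pwm.log_odds()
    idx = [_BASE_INDEX[c] for c in window]
    return float(lo[idx, range(len(window))].sum())


def relative_score(pwm: PWM, window: str) -> float:
    """Min-max normalized log2-odds score of one window, in [0, 1]."""
    window = window.upper()
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    bad = set(window) - set(BASES)
    if bad:
        raise ValueError(f"ambiguous/invalid base(s) {sorted(bad)} in window")
    lo = pwm.log_odds()
    s = _window_scores(pwm, window)
    smin = lo.min(axis=0).sum()
    smax = lo.max(axis=0).sum()
    if smax == smin:
        return 1.0
    if not np.isfinite(s):
        return 0.0  # a zero-probability base with zero pseudocount
    return float((s - smin) / (smax - smin))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def column_ic(pwm: PWM, column: int) -> float:
    """Information content of one column: 2 + sum_b p log2 p (bits)."""
    if not (0 <= column < pwm.length):
        raise ValueError(f"column {column} out of range for length {pwm.length}")
    p = pwm.probabilities()[:, column]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float(2.0 + terms.sum())


def scan_allele(
    pwm: PWM,
    context: VariantContext,
    allele: str,
    threshold: float = 0.8,
    strands: str = "both",
) -> AlleleBindingCall:
    """Best-scoring window overlapping the variant for one allele.

    All length-L windows that overlap the variant's base(s) are scored on the
    requested strands; ties prefer the forward strand, then the lower offset.
    ``aligned_column`` is the PWM column sitting on the (first base of the)
    variant at the best window; on the reverse strand column indices are
    mirrored accordingly.
    """
    seq = context.sequence(allele).upper()
    L = pwm.length
    if L > len(seq):
        raise ValueError(f"motif length {L} exceeds sequence length {len(seq)}")
    var_start = len(context.flank_5p)
    var_end = var_start + len(allele)
    lo = max(0, var_start - L + 1)
    hi = min(len(seq) - L, var_end - 1)

    best_key = (-np.inf, -2, 1)
    best_call = None
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}[strands]
    for off in range(lo, hi + 1):
        window = seq[off : off + L]
        if set(window) - set(BASES):
            continue
        for strand in strand_list:
            w = window if strand == "+" else reverse_complement(window)
            s = relative_score(pwm, w)
            key = (s, 0 if strand == "+" else -1, -off)
            if key > best_key:
                best_key = key
                best_call = (s, strand, off)
    if best_call is None:
        raise ValueError("no scoreable window overlaps the variant")
    score, strand, offset = best_call
    col_fwd = var_start - offset
    aligned = col_fwd if strand == "+" else L - 1 - col_fwd
    aligned = aligned if 0 <= aligned < L else None
    return AlleleBindingCall(
        motif=pwm.name, allele=allele, best_relative_score=float(score),
        best_offset=int(offset), strand=strand,
        is_match=bool(score >= threshold), aligned_column=aligned,
        column_ic=column_ic(pwm, aligned) if aligned is not None else None,
    )


def differential_binding(
    pwm: PWM,
    context: VariantContext,
    threshold: float = 0.8,
    ic_min: float = 1.0,
) -> tuple[AlleleBindingCall, AlleleBindingCall, bool]:
    """Paired per-allele calls plus the genotype-sensitivity flag.

    The flag is True iff some allele's best variant-overlapping window is a
    match (relative score >= threshold) and, for single-base alleles, the PWM
    column aligned to the variable base at that window has IC >= ic_min.
    For indel alleles the IC-at-a-column rule is undefined and the flag falls
    back to the match condition alone.
    """
    a, b = context.alleles
    call_a = scan_allele(pwm, context, a, threshold=threshold)
    call_b = scan_allele(pwm, context, b, threshold=threshold)
    best = max((call_a, call_b), key=lambda c: c.best_relative_score)
    is_snv = len(a) == 1 and len(b) == 1
    if not best.is_match:
        flag = False
    elif is_snv:
        flag = best.aligned_column is not None and best.column_ic >= ic_min
    else:
        flag = True
    return call_a, call_b, flag


def fold_affinity(
    pwm: PWM, aligned_column: int, allele_a: str, allele_b: str
) -> tuple[float, str]:
    """Predicted affinity ratio between two single-base alleles.

    Ratio of the aligned column's pseudocounted probabilities,
    p(allele_a) / p(allele_b); also returns the favored allele. With zero
    pseudocount a zero denominator yields inf with a warning.
    """
    for al in (allele_a, allele_b):
        if len(al) != 1 or al not in BASES:
            raise ValueError(f"fold affinity requires single-base alleles, got {al!r}")
    p = pwm.probabilities()[:, aligned_column]
    pa, pb = p[_BASE_INDEX[allele_a]], p[_BASE_INDEX[allele_b]]
    if pb == 0:
        warnings.warn("zero probability for denominator allele; fold affinity infinite")
        ratio = np.inf
    else:
        ratio = pa / pb
    favored = allele_a if ratio >= 1 else allele_b
    return float(ratio), favored


def prioritize_tf(
    tf_name: str,
    correlation_sign: str,
    increased_expression_allele: str,
    call_a: AlleleBindingCall,
    call_b: AlleleBindingCall,
    differential: bool,
    fold: float | None = None,
) -> TFCandidate:
    """Logical-consistency verdict for one candidate TF at one variant.

    Order of rules: a TF whose binding is not genotype sensitive is dropped
    first (``not_genotype_sensitive``); then a positively correlated TF must
    prefer the allele associated with increased target expression (and a
    negatively correlated TF must prefer the other allele) or it is
    ``inconsistent``; otherwise ``retained``.
    """
    if correlation_sign not in ("+", "-"):
        raise ValueError(f"correlation_sign must be '+' or '-', got {correlation_sign!r}")
    if not increased_expression_allele:
        raise ValueError("increased_expression_allele is required")
    if not differential:
        return TFCandidate(tf_name, correlation_sign, increased_expression_allele,
                           None, fold, "not_genotype_sensitive")
    higher = max((call_a, call_b), key=lambda c: c.best_relative_score).allele
    agree = higher == increased_expression_allele
    if (correlation_sign == "+" and not agree) or (correlation_sign == "-" and agree):
        verdict = "inconsistent"
    else:
        verdict = "retained"
    return TFCandidate(tf_name, correlation_sign, increased_expression_allele,
                       higher, fold, verdict)
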