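"""LTR-pair detection, LTR similarity, TSD detection and element QC.

The pair finder is a deliberately simple seeded aligner: exact 20-mer matches
between the head and tail of the sequence define candidate diagonals, each
diagonal is extended by X-drop and the boundaries snapped to TG...CA termini.
It enforces the published structural constraints (length, distance, 95%
similarity, termini) but does not reproduce LTR-FINDER's full scoring model;
pre-delimited elements are equally accepted by the downstream modules.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from Bio import Align

from .core_io import GenomicSequence, Interval, PipelineConfig, QCFlag

_SEED_K = 20
_EDGE_REGION = 8000
_XDROP = 12
_SNAP_WINDOW = 24


@dataclass
class LTRPair:
    five_ltr: Interval
    three_ltr: Interval
    similarity: float  # percent identity of the aligned LTR copies
    termini_ok: bool  # 5' LTR starts TG and 3' LTR ends CA


@dataclass
class TSDCall:
    length: int
    left_seq: str
    right_seq: str
    exact: bool = True


def tsd_sequence_space(length: int, alphabet_size: int = 4) -> int:
    """Number of distinct TSD sequences of the given length (4**L for DNA).

    For the dominant 5 bp duplications this is the 1024-sequence space a
    random-integration model would sample from.
    """
    if length < 1:
        raise ValueError("TSD length must be positive")
    return alphabet_size ** length


_dna_aligner: Align.PairwiseAligner | None = None


def _get_dna_aligner() -> Align.PairwiseAligner:
    global _dna_aligner
    if _dna_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -4
        a.extend_gap_score = -1
        _dna_aligner = a
    return _dna_aligner


def ltr_similarity(a: str, b: str) -> float:
    """Percent identity of a global alignment of the two LTR copies.

    Scoring: match +1, mismatch -1, gap open -4, gap extend -1 (a gap of
    length k costs 4 + (k-1)). Identity = identical columns / alignment
    columns * 100, gaps counted as columns.
    """
    if not a or not b:
        raise ValueError("ltr_similarity requires non-empty sequences")
    aligner = _get_dna_aligner()
    aln = aligner.align(a, b)[0]
    matches = 0
    columns = 0
    pa, pb = 0, 0
    for (qa, qb), (ra, rb) in zip(*aln.aligned):
        columns += (qa - pa) + (ra - pb)  # gap columns before this block
        for i in range(qb - qa):
            columns += 1
            if a[qa + i] == b[ra + i]:
                matches += 1
        pa, pb = qb, rb
    columns += (len(a) - pa) + (len(b) - pb)  # trailing gap columns
    return 100.0 * matches / columns if columns else 0.0


def find_ltr_pair(seq: GenomicSequence, config: PipelineConfig | None = None) -> Optional[LTRPair]:
    """Locate the best 5'/3' LTR pair under the configured constraints.

    Returns the highest-similarity qualifying pair (ties broken by longer
    LTR, then leftmost 5' start) or None.
    """
    config = config or PipelineConfig()
    s = seq.residues
    n = len(s)
    if n < config.inter_ltr_min + 2 * config.ltr_min_len:
        return None

    head_end = min(n, _EDGE_REGION)
    tail_start = max(0, n - _EDGE_REGION)
    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(head_end - _SEED_K + 1):
        kmer_pos[s[i : i + _SEED_K]].append(i)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for j in range(tail_start, n - _SEED_K + 1):
        for i in kmer_pos.get(s[j : j + _SEED_K], ()):
            d = j - i
            if config.inter_ltr_min <= d <= config.inter_ltr_max:
                diagonals[d].append(i)

    best: tuple[float, int, int] | None = None  # (similarity, length, -start)
    best_pair: Optional[LTRPair] = None
    # richest diagonals first; a modest cap keeps pathological inputs cheap
    for d in sorted(diagonals, key=lambda d: -len(diagonals[d]))[:50]:
        seeds = diagonals[d]
        lo, hi = min(seeds), max(seeds) + _SEED_K
        lo, hi = _xdrop_extend(s, lo, hi, d)
        a, b = _snap_termini(s, lo, hi, d, config.require_tg_ca)
        if a is None:
            continue
        length = b - a
        if not (config.ltr_min_len <= length <= config.ltr_max_len):
            continue
        if d < length:  # copies would overlap
            continue
        five, three = s[a:b], s[a + d : b + d]
        sim = ltr_similarity(five, three)
        if sim < config.ltr_min_similarity:
            continue
        termini_ok = five.startswith("TG") and three.endswith("CA")
        if config.require_tg_ca and not termini_ok:
            continue
        key = (sim, length, -a)
        if best is None or key > best:
            best = key
            best_pair = LTRPair((a, b), (a + d, b + d), sim, termini_ok)
    return best_pair


def _xdrop_extend(s: str, lo: int, hi: int, d: int) -> tuple[int, int]:
    """Greedy ungapped extension of a seed span on diagonal d (match +1,
    mismatch -2, stop when the running score drops _XDROP below its max)."""
    n = len(s)
    score = best = 0
    i = lo - 1
    new_lo = lo
    while i >= 0 and i + d >= 0:
        score += 1 if s[i] == s[i + d] else -2
        if score > best:
            best, new_lo = score, i
        if score < best - _XDROP:
            break
        i -= 1
    score = best = 0
    i = hi
    new_hi = hi
    while i < n and i + d < n:
        score += 1 if s[i] == s[i + d] else -2
        if score > best:
            best, new_hi = score, i + 1
        if score < best - _XDROP:
            break
        i += 1
    return new_lo, new_hi


def _snap_termini(
    s: str, lo: int, hi: int, d: int, require: bool
) -> tuple[Optional[int], Optional[int]]:
    """Snap the extended span to TG starts / CA ends present in BOTH copies."""
    if not require:
        return lo, hi
    a = None
    for cand in range(lo, min(lo + _SNAP_WINDOW, hi - 2)):
        if s[cand : cand + 2] == "TG" and s[cand + d : cand + d + 2] == "TG":
            a = cand
            break
    b = None
    for cand in range(hi, max(hi - _SNAP_WINDOW, lo + 2), -1):
        if s[cand - 2 : cand] == "CA" and s[cand + d - 2 : cand + d] == "CA":
            b = cand
            break
    if a is None or b is None or b - a < 3:
        return None, None
    return a, b


def detect_tsd(
    left_flank: str, right_flank: str, config: PipelineConfig | None = None
) -> Optional[TSDCall]:
    """Exact target-site duplication at the element boundaries.

    Tries lengths longest-first (default 6, 5, 4): the last L bases of the
    left flank must equal the first L bases of the right flank.
    """
    config = config or PipelineConfig()
    for L in sorted(config.tsd_lengths, reverse=True):
        if len(left_flank) < L or len(right_flank) < L:
            continue
        left = left_flank[-L:]
        right = right_flank[:L]
        if left == right:
            return TSDCall(L, left, right, exact=True)
    return None


def validate_element(record, config: PipelineConfig | None = None) -> set[QCFlag]:
    """Apply the element-level filters; flags are appended to the record.

    ambiguous_bases if the N count exceeds max_n (strictly more than ten by
    default); bad_termini if the located LTRs lack TG/CA ends; no_polyprotein
    if no domain architecture was found; nested_insertion_suspect if a second
    LTR-like pair lies strictly inside the internal region. An element is
    accepted iff no flags are raised.
    """
    config = config or PipelineConfig()
    flags: set[QCFlag] = set()
    s = record.seq.residues
    if s.count("N") > config.max_n:
        flags.add(QCFlag.AMBIGUOUS_BASES)
    if record.ltr is not None:
        (a, b), (c, e) = record.ltr.five_ltr, record.ltr.three_ltr
        if not (s[a : a + 2] == "TG" and s[e - 2 : e] == "CA"):
            flags.add(QCFlag.BAD_TERMINI)
        internal = record.seq.residues[b:c]
        if len(internal) >= config.inter_ltr_min + 2 * config.ltr_min_len:
            inner = find_ltr_pair(
                GenomicSequence(record.seq.id + "_internal", internal), config
            )
            if inner is not None:
                flags.add(QCFlag.NESTED_INSERTION_SUSPECT)
    if record.architecture is None or not getattr(record.architecture, "calls", []):
        flags.add(QCFlag.NO_POLYPROTEIN)
    else:
        flags |= {QCFlag(f) for f in record.architecture.flags if f in
                  (QCFlag.BAD_ORDER.value, QCFlag.DUPLICATE_DOMAIN.value, QCFlag.CHIMERA.value)}
    record.qc_flags |= flags
    return flags
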