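"""Primer-binding-site typing.

A PBS sits immediately downstream of the 5' LTR and is complementary to the
3' end of the primer that initiates minus-strand synthesis: a complete
mature tRNA, a tRNA half-molecule cleaved in the anticodon stem, or a
self-primer released from the element's own 5' LTR. Detection follows the
published rules: exact complementarity of at least 12 bp to a tRNA 3' end
within the 50 bp downstream window; a fuzzy match seeded at a TGG located
0-5 bp downstream allowing at most two differences of which at most one may
be an indel; half-molecule matches ending in a window around the anticodon;
and self-primers of at least 10 bp whose complement occurs inside the 5'
LTR. When several rules fire the precedence is
full > half > fuzzy > self > none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_io import Interval, PipelineConfig, TRNAEntry, TRNALibrary, revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PrimerCall:
    mode: str  # full_tRNA | half_tRNA | fuzzy_tRNA | self | none
    trna_id: Optional[str] = None
    isoacceptor: Optional[str] = None
    match_len: int = 0
    diffs: int = 0
    indels: int = 0
    pbs_interval: Optional[Interval] = None
    offset_from_ltr: Optional[int] = None


def prepare_trnas(library: TRNALibrary) -> TRNALibrary:
    """Ensure every tRNA ends with exactly one terminal CCA.

    Mature tRNAs carry a post-transcriptionally added 3' CCA which genomic
    predictions lack; idempotent (an existing terminal CCA is kept, never
    duplicated). Anticodon indices are untouched.
    """
    out = []
    for e in library.entries:
        res = e.residues
        if not res.endswith("CCA"):
            res = res + "CCA"
        out.append(TRNAEntry(e.id, e.isoacceptor, res, e.anticodon_start, list(e.edited_positions)))
    return TRNALibrary(out)


def _window(element, config: PipelineConfig) -> tuple[str, int]:
    if element.ltr is None:
        raise ValueError("PBS requires 5' LTR")
    ltr_end = element.ltr.five_ltr[1]
    return element.seq.residues[ltr_end : ltr_end + config.pbs_window], ltr_end


def _pairs(window_base: str, trna: TRNAEntry, t_idx: int) -> bool:
    """Can the element base pair with tRNA position t_idx?

    Normally this requires Watson-Crick complementarity; at an annotated
    edited position (e.g. inosine at an anticodon wobble) any of the listed
    element-strand bases is accepted.
    """
    for idx, allowed in trna.edited_positions:
        if idx == t_idx:
            return window_base in allowed
    return window_base == _COMPLEMENT.get(trna.residues[t_idx], "N")


def _longest_pair_match(
    window: str, trna: TRNAEntry, end_idx: int
) -> tuple[int, int]:
    """Longest run in the window complementary to the tRNA subsequence ending
    at end_idx (exclusive), read 3'->5'. Returns (length, window offset)."""
    best_len, best_off = 0, -1
    for s in range(len(window)):
        m = 0
        while s + m < len(window) and end_idx - 1 - m >= 0 and _pairs(
            window[s + m], trna, end_idx - 1 - m
        ):
            m += 1
        if m > best_len:
            best_len, best_off = m, s
    return best_len, best_off


def find_exact_pbs(
    element, trnas: TRNALibrary, config: PipelineConfig | None = None
) -> Optional[PrimerCall]:
    """Longest exact complementary match (>= pbs_min_exact bp) between the
    downstream window and a 3'-terminal tRNA suffix (the suffix must include
    the tRNA's final base). Ties: smallest offset, then tRNA id."""
    config = config or PipelineConfig()
    window, ltr_end = _window(element, config)
    best: tuple[int, int, str] | None = None  # (-len, offset, id)
    best_call = None
    for t in trnas:
        m, off = _longest_pair_match(window, t, len(t.residues))
        if m < config.pbs_min_exact:
            continue
        key = (-m, off, t.id)
        if best is None or key < best:
            best = key
            best_call = PrimerCall(
                "full_tRNA", t.id, t.isoacceptor, m, 0, 0,
                (ltr_end + off, ltr_end + off + m), off,
            )
    return best_call


def find_half_trna_pbs(
    element, trnas: TRNALibrary, config: PipelineConfig | None = None
) -> Optional[PrimerCall]:
    """Exact match to the 3' end of a tRNA 5'-half-molecule.

    The half-molecule arises from cleavage in the anticodon stem, so the
    match must end within the cleavage window anticodon_start-3 ..
    anticodon_start+5 of the tRNA. Annotated edited positions (the inosine
    rule of the Bianca-type 1/2tRNA-Ile primer) accept any of A, T or C on
    the element strand.
    """
    config = config or PipelineConfig()
    window, ltr_end = _window(element, config)
    best: tuple[int, int, str] | None = None
    best_call = None
    for t in trnas:
        if t.anticodon_start is None:  # pragma: no cover - loader requires it
            continue
        lo = max(1, t.anticodon_start - 3)
        hi = min(len(t.residues), t.anticodon_start + 5)
        for end_idx in range(lo, hi + 1):
            m, off = _longest_pair_match(window, t, end_idx)
            if m < config.pbs_min_exact:
                continue
            key = (-m, off, t.id)
            if best is None or key < best:
                best = key
                best_call = PrimerCall(
                    "half_tRNA", t.id, t.isoacceptor, m, 0, 0,
                    (ltr_end + off, ltr_end + off + m), off,
                )
    return best_call


def _edit_costs(query: str, ref: str, max_total: int) -> tuple[int, int]:
    """Edit distance of query vs ref with free trailing gaps, tracked as
    (substitutions, indels); minimises total edits, then indels."""
    INF = (99, 99)

    def add(cost, ds, di):
        return (cost[0] + ds, cost[1] + di)

    def total(c):
        return c[0] + c[1]

    prev = [(0, i) for i in range(len(ref) + 1)]  # leading ref gaps = indels
    best_last_col = prev[len(ref)]
    for i in range(1, len(query) + 1):
        cur = [(0, i)] + [INF] * len(ref)
        for j in range(1, len(ref) + 1):
            sub = add(prev[j - 1], 0 if query[i - 1] == ref[j - 1] else 1, 0)
            ins = add(prev[j], 0, 1)
            dele = add(cur[j - 1], 0, 1)
            cur[j] = min(sub, ins, dele, key=lambda c: (total(c), c[1]))
        best_last_col = min(best_last_col, cur[len(ref)], key=lambda c: (total(c), c[1]))
        prev = cur
    # free trailing gaps: best over the last row (unmatched ref suffix) and
    # the last column (unmatched query suffix)
    best = min(prev + [best_last_col], key=lambda c: (total(c), c[1]))
    return best


def find_fuzzy_pbs(
    element, trnas: TRNALibrary, config: PipelineConfig | None = None
) -> Optional[PrimerCall]:
    """Degenerate tRNA match seeded at a TGG 0-5 bp downstream of the LTR.

    The fuzzy_window bp starting at the TGG are compared (unit-cost edit
    distance, trailing gaps free) with the reverse complement of each tRNA's
    3'-terminal fuzzy_window bp; accepted with at most fuzzy_max_diffs total
    differences of which at most fuzzy_max_indels may be indels.
    """
    config = config or PipelineConfig()
    window, ltr_end = _window(element, config)
    w = config.fuzzy_window
    best: tuple[int, int, int, str] | None = None  # (total, indels, offset, id)
    best_call = None
    for off in range(0, config.tgg_max_offset + 1):
        if window[off : off + 3] != "TGG":
            continue
        query = window[off : off + w]
        if len(query) < config.pbs_min_exact:
            continue
        for t in trnas:
            ref = revcomp(t.residues[-w:])
            subs, indels = _edit_costs(query, ref, config.fuzzy_max_diffs)
            total = subs + indels
            if total > config.fuzzy_max_diffs or indels > config.fuzzy_max_indels:
                continue
            key = (total, indels, off, t.id)
            if best is None or key < best:
                best = key
                best_call = PrimerCall(
                    "fuzzy_tRNA", t.id, t.isoacceptor, len(query), subs, indels,
                    (ltr_end + off, ltr_end + off + len(query)), off,
                )
    return best_call


def find_self_primer(element, config: PipelineConfig | None = None) -> Optional[PrimerCall]:
    """Self-primer: the reverse complement of a >= self_primer_min bp region
    starting 0-5 bp downstream of the 5' LTR occurs inside the 5' LTR."""
    config = config or PipelineConfig()
    if element.ltr is None:
        raise ValueError("PBS requires 5' LTR")
    a, b = element.ltr.five_ltr
    ltr_seq = element.seq.residues[a:b]
    ltr_end = b
    best_call = None
    best: tuple[int, int] | None = None  # (-len, offset)
    for off in range(0, config.tgg_max_offset + 1):
        down = element.seq.residues[ltr_end + off : ltr_end + off + config.self_primer_max]
        for L in range(len(down), config.self_primer_min - 1, -1):
            if revcomp(down[:L]) in ltr_seq:
                key = (-L, off)
                if best is None or key < best:
                    best = key
                    best_call = PrimerCall(
                        "self", None, None, L, 0, 0,
                        (ltr_end + off, ltr_end + off + L), off,
                    )
                break
    return best_call


def call_pbs(
    element, trnas: TRNALibrary, config: PipelineConfig | None = None
) -> PrimerCall:
    """Run the detectors with precedence full > half > fuzzy > self > none
    and store the result on the record."""
    config = config or PipelineConfig()
    call = (
        find_exact_pbs(element, trnas, config)
        or find_half_trna_pbs(element, trnas, config)
        or find_fuzzy_pbs(element, trnas, config)
        or find_self_primer(element, config)
        or PrimerCall("none")
    )
    element.pbs = call
    return call
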