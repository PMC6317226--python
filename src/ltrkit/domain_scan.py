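"""Six-frame translated search against the reference domain database.

Element DNA is translated in all six frames, split into stop-free peptide
segments, and each segment is aligned (Smith-Waterman, BLOSUM62, affine
gaps) against the classified reference proteins. Hits are mapped back to DNA
coordinates, chained across frames to tolerate frameshift mutations in the
coding region, and the resulting domain calls are validated against the two
superfamily templates: GAG-PROT-INT-RT-RH (Ty1/copia) and GAG-PROT-RT-RH-INT
(Ty3/gypsy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import (
    CORE_DOMAINS,
    GenomicSequence,
    Interval,
    PipelineConfig,
    ReferenceDomainDB,
    revcomp,
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

FRAMES = (1, 2, 3, -1, -2, -3)


def translate(dna: str) -> str:
    """Standard-code translation; codons containing N (or other ambiguity)
    become X, stops are '*'. Trailing partial codons are dropped."""
    out = []
    for i in range(0, len(dna) - 2, 3):
        out.append(_CODON_TABLE.get(dna[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translations keyed by frame (+1..+3 forward, -1..-3 on the reverse
    complement)."""
    rc = revcomp(dna)
    return {
        1: translate(dna), 2: translate(dna[1:]), 3: translate(dna[2:]),
        -1: translate(rc), -2: translate(rc[1:]), -3: translate(rc[2:]),
    }


# ---------------------------------------------------------------------------
# local protein alignment


def make_protein_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -gap_open
    a.extend_gap_score = -gap_extend
    return a


_default_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _default_aligner
    if _default_aligner is None:
        _default_aligner = make_protein_aligner()
    return _default_aligner


def local_align(
    query: str, ref: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[float, float, Interval, Interval]:
    """Smith-Waterman optimum: (score, percent identity, query interval,
    ref interval). A pair with no positive-scoring alignment returns score 0
    and empty intervals.
    """
    if not query or not ref:
        raise ValueError("local_align requires non-empty sequences")
    aligner = aligner or _get_aligner()
    score = aligner.score(query, ref)
    if score <= 0:
        return 0.0, 0.0, (0, 0), (0, 0)
    aln = aligner.align(query, ref)[0]
    identity, q_iv, r_iv = _alignment_stats(aln, query, ref)
    return float(score), identity, q_iv, r_iv


def _alignment_stats(aln, query: str, ref: str) -> tuple[float, Interval, Interval]:
    """Percent identity over aligned columns (gaps included) plus the query
    and reference intervals covered by a local alignment."""
    blocks_q, blocks_r = aln.aligned
    matches = 0
    columns = 0
    prev_q, prev_r = None, None
    for (qa, qb), (ra, rb) in zip(blocks_q, blocks_r):
        if prev_q is not None:
            columns += (qa - prev_q) + (ra - prev_r)  # internal gap columns
        for i in range(qb - qa):
            columns += 1
            if query[qa + i] == ref[ra + i]:
                matches += 1
        prev_q, prev_r = qb, rb
    identity = 100.0 * matches / columns if columns else 0.0
    q_iv = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    r_iv = (int(blocks_r[0][0]), int(blocks_r[-1][1]))
    return identity, q_iv, r_iv


# ---------------------------------------------------------------------------
# scanning


@dataclass
class ProteinHit:
    ref_entry: str
    domain_type: str
    lineage: str
    dna_interval: Interval
    frame: int
    score: float
    identity: float
    ref_interval: Interval
    protein: str  # aligned query residues (element-encoded peptide)


@dataclass
class DomainCall:
    domain_type: str
    dna_interval: Interval
    strand: str
    best_ref: str
    lineage: str
    score: float
    identity: float
    support: int  # number of chained hits
    protein: str = ""


@dataclass
class DomainArchitecture:
    calls: list[DomainCall]
    superfamily: str  # Ty1/copia | Ty3/gypsy | undetermined
    arh_position: Optional[str]  # None | PROT_RT | RH_INT | after_INT
    flags: set[str] = field(default_factory=set)

    def calls_of_type(self, domain_type: str) -> list[DomainCall]:
        return [c for c in self.calls if c.domain_type == domain_type]


def _segments(aa: str, min_len: int) -> Iterable[tuple[int, str]]:
    """Stop-free segments of a frame translation as (aa offset, peptide)."""
    start = 0
    for i, ch in enumerate(aa):
        if ch == "*":
            if i - start >= min_len:
                yield start, aa[start:i]
            start = i + 1
    if len(aa) - start >= min_len:
        yield start, aa[start:]


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _map_to_dna(frame: int, n: int, seg_off: int, q_iv: Interval) -> Interval:
    """Map a protein-coordinate interval inside a frame translation back to
    forward-strand DNA coordinates (frame-aware, reverse frames flipped)."""
    aa_start = seg_off + q_iv[0]
    aa_end = seg_off + q_iv[1]
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return n - (off + 3 * aa_end), n - (off + 3 * aa_start)


def scan_domains(
    element: GenomicSequence,
    refdb: ReferenceDomainDB,
    config: PipelineConfig | None = None,
) -> list[ProteinHit]:
    """Align every stop-free six-frame peptide segment against the reference
    database (with a shared-4-mer prefilter) and return hits above the score
    and identity thresholds, in DNA coordinates."""
    config = config or PipelineConfig()
    if not refdb.entries:
        raise ValueError("empty reference database")
    aligner = make_protein_aligner(config.scan_gap_open, config.scan_gap_extend)
    ref_kmers = getattr(refdb, "_kmer_cache", None)
    if ref_kmers is None:
        ref_kmers = {e.name: _kmers(e.protein) for e in refdb.entries}
        refdb._kmer_cache = ref_kmers  # type: ignore[attr-defined]

    n = len(element.residues)
    hits: list[ProteinHit] = []
    for frame, aa in six_frame_translate(element.residues).items():
        for seg_off, peptide in _segments(aa, config.min_segment_aa):
            pep_kmers = _kmers(peptide)
            for entry in refdb.entries:
                if not (pep_kmers & ref_kmers[entry.name]):
                    continue
                score = aligner.score(peptide, entry.protein)
                if score < config.scan_min_score:
                    continue
                aln = aligner.align(peptide, entry.protein)[0]
                identity, q_iv, r_iv = _alignment_stats(aln, peptide, entry.protein)
                if identity < config.scan_min_identity:
                    continue
                hits.append(
                    ProteinHit(
                        ref_entry=entry.name,
                        domain_type=entry.domain_type,
                        lineage=refdb.lineage_of(entry.element_name),
                        dna_interval=_map_to_dna(frame, n, seg_off, q_iv),
                        frame=frame,
                        score=score,
                        identity=identity,
                        ref_interval=r_iv,
                        protein=peptide[q_iv[0] : q_iv[1]],
                    )
                )
    hits.sort(key=lambda h: h.dna_interval)
    return hits


# ---------------------------------------------------------------------------
# chaining and architecture validation


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def chain_hits(hits: list[ProteinHit], max_gap: int = 300) -> list[DomainCall]:
    """Merge frameshift-split hits into domain calls and resolve overlaps.

    Colinear hits (DNA and reference coordinates both increasing, gap at most
    max_gap bp) to the same reference on the same strand are merged into one
    call whose score is the sum and whose reference is the highest-scoring
    constituent. Overlapping calls (any type) are then resolved keeping the
    higher score when the lower-scoring call is covered by at least half.
    """
    by_group: dict[tuple[str, int, str], list[ProteinHit]] = {}
    for h in hits:
        strand = 1 if h.frame > 0 else -1
        by_group.setdefault((h.domain_type, strand, h.ref_entry), []).append(h)

    candidates: list[DomainCall] = []
    for (dtype, strand, _ref), group in by_group.items():
        group.sort(key=lambda h: (h.dna_interval, h.ref_interval))
        chains: list[list[ProteinHit]] = []
        for h in group:
            placed = False
            for chain in chains:
                last = chain[-1]
                gap = h.dna_interval[0] - last.dna_interval[1]
                # progression (partial overlap allowed: local alignments of
                # frameshift-split hits extend past the break)
                colinear_dna = (
                    h.dna_interval[0] > last.dna_interval[0]
                    and h.dna_interval[1] > last.dna_interval[1]
                    and gap <= max_gap
                )
                if strand > 0:
                    colinear_ref = h.ref_interval[1] > last.ref_interval[1]
                else:  # reverse strand: later DNA = earlier protein
                    colinear_ref = h.ref_interval[0] < last.ref_interval[0]
                if colinear_dna and colinear_ref:
                    chain.append(h)
                    placed = True
                    break
            if not placed:
                chains.append([h])
        for chain in chains:
            best = max(chain, key=lambda h: h.score)
            start = min(h.dna_interval[0] for h in chain)
            end = max(h.dna_interval[1] for h in chain)
            parts = chain if strand > 0 else chain[::-1]
            candidates.append(
                DomainCall(
                    domain_type=dtype,
                    dna_interval=(start, end),
                    strand="+" if strand > 0 else "-",
                    best_ref=best.ref_entry,
                    lineage=best.lineage,
                    score=sum(h.score for h in chain),
                    identity=best.identity,
                    support=len(chain),
                    protein="".join(h.protein for h in parts),
                )
            )

    # overlap resolution: dominant (higher-scoring) call wins when it covers
    # >=50% of the weaker call
    candidates.sort(key=lambda c: -c.score)
    kept: list[DomainCall] = []
    for cand in candidates:
        length = cand.dna_interval[1] - cand.dna_interval[0]
        if any(_overlap(cand.dna_interval, k.dna_interval) >= 0.5 * length for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c.dna_interval)
    return kept


_TEMPLATES = {
    "Ty1/copia": ("PROT", "INT", "RT", "RH"),
    "Ty3/gypsy": ("PROT", "RT", "RH", "INT"),
}


def validate_architecture(calls: list[DomainCall]) -> DomainArchitecture:
    """Check domain order against the superfamily templates and derive flags.

    The order of {GAG, PROT, INT, RT, RH} calls (GAG optional, noted as
    missing_GAG but not fatal) must match GAG-PROT-INT-RT-RH (Ty1/copia) or
    GAG-PROT-RT-RH-INT (Ty3/gypsy); anything else is undetermined with
    bad_order. A repeated domain type raises duplicate_domain; disagreement
    of the best-hit superfamilies of the PROT/INT/RT/RH calls raises chimera.
    The aRH position is read off its neighbours (PROT_RT, RH_INT, after_INT).
    """
    calls = sorted(calls, key=lambda c: c.dna_interval)
    flags: set[str] = set()
    if not calls:
        return DomainArchitecture([], "undetermined", None, {"no_polyprotein"})

    counts: dict[str, int] = {}
    for c in calls:
        counts[c.domain_type] = counts.get(c.domain_type, 0) + 1
    if any(v > 1 for v in counts.values()):
        flags.add("duplicate_domain")

    core_seq = tuple(c.domain_type for c in calls if c.domain_type in CORE_DOMAINS)
    superfamily = "undetermined"
    for sf, template in _TEMPLATES.items():
        if core_seq == template:
            superfamily = sf
            flags.add("missing_GAG")
            break
        if core_seq == ("GAG",) + template:
            superfamily = sf
            break
    if superfamily == "undetermined":
        flags.add("bad_order")

    vote_sfs = {
        c.best_ref.split("-", 1)[0]
        for c in calls
        if c.domain_type in ("PROT", "INT", "RT", "RH")
    }
    if len(vote_sfs) > 1:
        flags.add("chimera")

    arh_position = None
    arh_calls = [c for c in calls if c.domain_type == "aRH"]
    if arh_calls:
        arh = arh_calls[0]
        core_calls = [c for c in calls if c.domain_type in CORE_DOMAINS]
        prev = next((c for c in reversed(core_calls) if c.dna_interval[1] <= arh.dna_interval[0] + 15), None)
        nxt = next((c for c in core_calls if c.dna_interval[0] >= arh.dna_interval[1] - 15), None)
        if prev is not None and prev.domain_type == "PROT" and nxt is not None and nxt.domain_type == "RT":
            arh_position = "PROT_RT"
        elif prev is not None and prev.domain_type == "RH" and nxt is not None and nxt.domain_type == "INT":
            arh_position = "RH_INT"
        elif prev is not None and prev.domain_type == "INT" and nxt is None:
            arh_position = "after_INT"

    return DomainArchitecture(calls, superfamily, arh_position, flags)


def polyprotein_interval(architecture: DomainArchitecture) -> Optional[Interval]:
    """Span of the first to last domain call (the polyprotein coding region)."""
    if not architecture.calls:
        return None
    return (
        min(c.dna_interval[0] for c in architecture.calls),
        max(c.dna_interval[1] for c in architecture.calls),
    )
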