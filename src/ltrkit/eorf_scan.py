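"""Extra-ORF detection, positional labelling and tandem-repeat filtering.

eORFs are open reading frames of at least 250 codons lying outside the
polyprotein coding region, labelled by position (5'/3' of the polyprotein)
and orientation (F/R relative to it). ORFs arising inside tandem-repeat
arrays (at least three monomers spanning more than 150 bp in total) are
excluded: low-complexity repeats often simply lack stop codons. eORF
proteins are finally grouped by mutual similarity (Karlin-Altschul E-value
below a threshold) into connected components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import Interval, PipelineConfig, revcomp
from .domain_scan import local_align, translate

EORF_LABELS = ("eORF-5'F", "eORF-5'R", "eORF-3'F", "eORF-3'R")

# standard ungapped Karlin-Altschul parameters for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134


@dataclass
class ORFCall:
    dna_interval: Interval  # forward-strand coordinates, stop codon included
    strand: str
    codons: int  # excluding the stop codon
    label: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    protein: str = ""


@dataclass
class TandemArray:
    dna_interval: Interval
    period: int
    copies: float
    consensus: str

    @property
    def span(self) -> int:
        return self.dna_interval[1] - self.dna_interval[0]


def find_orfs(
    dna: str, min_codons: int = 250, require_atg: bool = True
) -> list[ORFCall]:
    """Maximal ATG-to-stop ORFs of at least min_codons codons, both strands,
    all three frames; coordinates always on the forward strand. An ORF
    running into the sequence end without a stop is reported open-ended.
    The codon count excludes the stop codon."""
    if not dna:
        raise ValueError("find_orfs requires a non-empty sequence")
    n = len(dna)
    out: list[ORFCall] = []
    for strand, s in (("+", dna), ("-", revcomp(dna))):
        for frame in range(3):
            start: Optional[int] = None  # codon index of first usable start
            for ci in range(frame, n - 2, 3):
                codon = s[ci : ci + 3]
                aa = translate(codon)
                if aa == "*":
                    if start is not None:
                        _emit(out, s, n, strand, start, ci, ci + 3, min_codons)
                    start = None
                elif start is None and (codon == "ATG" or not require_atg):
                    start = ci
            if start is not None:  # open-ended at the sequence edge
                end = frame + 3 * ((n - frame) // 3)
                _emit(out, s, n, strand, start, end, end, min_codons)
    out.sort(key=lambda o: o.dna_interval)
    return out


def _emit(out, s, n, strand, start, cds_end, full_end, min_codons):
    codons = (cds_end - start) // 3
    if codons < min_codons:
        return
    protein = translate(s[start:cds_end])
    if strand == "+":
        iv = (start, full_end)
    else:
        iv = (n - full_end, n - start)
    out.append(ORFCall(iv, strand, codons, protein=protein))


def label_eorf(
    orf: ORFCall, polyprotein_interval: Interval, polyprotein_strand: str = "+"
) -> Optional[str]:
    """Label an ORF relative to the polyprotein, or None if it overlaps it
    (such an ORF is not an eORF). 5'/3' by position, F/R by orientation."""
    if polyprotein_interval is None:
        raise ValueError("cannot label eORFs without a polyprotein interval")
    ps, pe = polyprotein_interval
    s, e = orf.dna_interval
    if min(e, pe) - max(s, ps) > 0:  # any overlap disqualifies
        return None
    side = "5" if e <= ps else "3"
    orient = "F" if orf.strand == polyprotein_strand else "R"
    return f"eORF-{side}'{orient}"


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem_arrays(
    dna: str, max_period: int = 200, config: PipelineConfig | None = None,
    min_monomers: int | None = None, min_span: int | None = None,
) -> list[TandemArray]:
    """Period-p self-agreement scan for tandem arrays.

    For each candidate period the sequence is compared against itself shifted
    by p; seed runs of perfect agreement are extended over neighbouring runs
    while overall agreement stays >= 80%. Arrays below the monomer-count or
    total-span thresholds are dropped; overlapping arrays at different
    periods are merged keeping the higher copy number.
    """
    config = config or PipelineConfig()
    min_monomers = config.tandem_min_monomers if min_monomers is None else min_monomers
    min_span = config.tandem_min_span if min_span is None else min_span
    n = len(dna)
    if n == 0:
        raise ValueError("empty sequence")
    arr = np.frombuffer(dna.encode(), dtype=np.uint8)
    found: list[TandemArray] = []
    for p in range(1, min(max_period, n - 1) + 1):
        m = arr[p:] == arr[:-p]  # m[i]: dna[i+p] == dna[i]
        if not m.any():
            continue
        mis = np.flatnonzero(~m)
        # pure-run lengths; only periods with a seed run worth a monomer are
        # examined further (random sequence almost never produces one)
        bounds = np.concatenate(([-1], mis, [len(m)]))
        runs = np.diff(bounds) - 1
        seed_min = max(p, 16)
        if runs.max() < seed_min:
            continue
        for k in np.flatnonzero(runs >= seed_min):
            lo = int(bounds[k] + 1)
            hi = int(bounds[k + 1])  # exclusive end of pure run in m-space
            matches = hi - lo
            length = hi - lo
            # greedy extension over following mismatches while agreement >= 0.8
            j = hi
            while j < len(m):
                nxt = length + 1
                if (matches + (1 if m[j] else 0)) / nxt < 0.8:
                    break
                matches += 1 if m[j] else 0
                length += 1
                j += 1
            hi = j
            start = lo  # array region includes the template monomer
            end = hi + p
            span = end - start
            copies = span / p
            if copies >= min_monomers and span > min_span:
                found.append(TandemArray((start, end), p, round(copies, 3), dna[start : start + p]))
    # merge overlaps, higher copy number wins
    found.sort(key=lambda a: (-a.copies, a.period))
    kept: list[TandemArray] = []
    for cand in found:
        if any(
            min(cand.dna_interval[1], k.dna_interval[1]) - max(cand.dna_interval[0], k.dna_interval[0]) > 0
            for k in kept
        ):
            continue
        kept.append(cand)
    kept.sort(key=lambda a: a.dna_interval)
    return kept


def filter_eorfs(
    orfs: Sequence[ORFCall], arrays: Sequence[TandemArray],
    config: PipelineConfig | None = None,
) -> list[ORFCall]:
    """Mark eORFs overlapping a qualifying tandem array by at least half of
    their length as excluded (reason: tandem_repeat)."""
    config = config or PipelineConfig()
    qualifying = [
        a for a in arrays
        if a.copies >= config.tandem_min_monomers and a.span > config.tandem_min_span
    ]
    out = []
    for orf in orfs:
        s, e = orf.dna_interval
        cover = sum(
            max(0, min(e, a.dna_interval[1]) - max(s, a.dna_interval[0]))
            for a in qualifying
        )
        if cover >= 0.5 * (e - s):
            orf = ORFCall(orf.dna_interval, orf.strand, orf.codons, orf.label,
                          True, "tandem_repeat", orf.protein)
        out.append(orf)
    return out


# ---------------------------------------------------------------------------
# eORF protein grouping


def karlin_altschul_evalue(score: float, len_a: int, len_b: int, n_pairs: int) -> float:
    """Ungapped Karlin-Altschul E-value for a BLOSUM62 local alignment score
    over a search space of len_a * len_b * n_pairs."""
    return KA_K * len_a * len_b * n_pairs * math.exp(-KA_LAMBDA * score)


def group_eorf_proteins(
    proteins: dict[str, str], evalue_threshold: float = 1e-10
) -> list[set[str]]:
    """Partition eORF proteins into connected components of pairwise
    similarity (E-value below threshold); singletons are groups of one.
    The partition is invariant to input order."""
    ids = sorted(proteins)
    n_pairs = len(ids) * (len(ids) - 1) // 2
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            score, _ident, _qi, _ri = local_align(proteins[a], proteins[b])
            if score <= 0:
                continue
            ev = karlin_altschul_evalue(score, len(proteins[a]), len(proteins[b]), n_pairs)
            if ev < evalue_threshold:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])
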