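"""Hierarchical lineage assignment and structural-feature consistency.

Classification-by-best-hit: each core domain call (PROT, INT, RT, RH) votes
for the lineage path of its best reference, weighted by alignment score; GAG
and the chromodomains are excluded from voting (they are too variable or are
lineage evidence in their own right) but chromodomain type, aRH position and
PBS type are checked afterwards against per-lineage expectations shipped as
an editable rules table: chromodomains belong to chromoviruses (CHDCR only
to the CRM clade), aRH between PROT and RT marks TatI/TatII, after INT
TatIII, and between RH and INT Ogre/Retand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .core_io import ElementRecord, PipelineConfig
from .domain_scan import DomainArchitecture, make_protein_aligner

VOTING_DOMAINS = ("PROT", "INT", "RT", "RH")


@dataclass
class LineageCall:
    superfamily: str
    lineage_path: str
    vote_share: float
    consistency_flags: set[str] = field(default_factory=set)
    low_confidence: bool = False


@dataclass
class FeatureProfile:
    """Structural features of one element, derived from upstream modules."""

    chromodomain: str  # CHD | CHDCR | none
    arh_position: Optional[str]
    pbs_mode: str
    pbs_isoacceptor: Optional[str]
    eorf_labels: Counter
    tsd_len: Optional[int]
    element_len: int


def build_feature_profile(record: ElementRecord) -> FeatureProfile:
    arch = record.architecture
    chromo = "none"
    arh = None
    if arch is not None:
        if arch.calls_of_type("CHDCR"):
            chromo = "CHDCR"
        elif arch.calls_of_type("CHD"):
            chromo = "CHD"
        arh = arch.arh_position
    pbs_mode = record.pbs.mode if record.pbs is not None else "none"
    iso = record.pbs.isoacceptor if record.pbs is not None else None
    labels = Counter(o.label for o in record.eorfs if o.label and not o.excluded)
    tsd_len = record.tsd.length if record.tsd is not None else None
    return FeatureProfile(chromo, arh, pbs_mode, iso, labels, tsd_len, len(record.seq))


# ---------------------------------------------------------------------------
# voting


def vote_lineage(
    architecture: DomainArchitecture, config: PipelineConfig | None = None
) -> LineageCall:
    """Score-weighted vote of the core domain calls over reference lineage
    paths; the winning path takes the maximal summed weight (ties broken by
    deeper path, then lexicographically). vote_share is the winner's fraction
    of the total weight; disagreement between vote superfamilies, or between
    the winner and the architecture template, raises the chimera flag."""
    config = config or PipelineConfig()
    votes = [c for c in architecture.calls if c.domain_type in VOTING_DOMAINS]
    if not votes:
        raise ValueError("unclassifiable: no core domain calls to vote with")
    weights: dict[str, float] = {}
    for c in votes:
        weights[c.lineage] = weights.get(c.lineage, 0.0) + c.score
    total = sum(weights.values())
    winner = max(weights, key=lambda p: (weights[p], p.count("|"), p))
    share = weights[winner] / total
    flags: set[str] = set()
    vote_sfs = {p.split("|")[0] for p in weights}
    superfamily = winner.split("|")[0]
    if len(vote_sfs) > 1:
        flags.add("chimera")
    if architecture.superfamily not in ("undetermined", superfamily):
        flags.add("chimera")
    return LineageCall(
        superfamily, winner, share, flags,
        low_confidence=share < config.vote_confidence,
    )


# ---------------------------------------------------------------------------
# consistency rules


@dataclass
class LineageRule:
    chromodomain: set[str]
    arh_position: set[str]
    pbs: set[str]


def load_rules(path: str | Path | None = None) -> dict[str, LineageRule]:
    """Load the per-lineage expectation table (default: the shipped one)."""
    if path is None:
        text = resources.files("ltrkit.data").joinpath("lineage_rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules: dict[str, LineageRule] = {}
    for raw in text.splitlines():
        if not raw.strip() or raw.startswith("#") or raw.startswith("lineage\t"):
            continue
        lineage, chromo, arh, pbs = raw.rstrip("\n").split("\t")
        rules[lineage] = LineageRule(
            set(chromo.split(",")), set(arh.split(",")), set(pbs.split(","))
        )
    return rules


def check_consistency(
    lineage: LineageCall,
    features: FeatureProfile,
    rules: dict[str, LineageRule] | None = None,
) -> set[str]:
    """Flag violations of the lineage's expected structural features.

    chromodomain_mismatch when the chromodomain type is outside the lineage's
    allowed set (chromodomains are confined to chromoviruses, CHDCR to CRM);
    arh_position_mismatch when the aRH position contradicts the Tat-subclade
    expectation; pbs_unexpected when a positive PBS call is outside the
    lineage's primer repertoire (mode none never flags; a fuzzy call counts
    as its full-tRNA token). A lineage absent from the table skips all checks
    with a warning flag. Flags are added to the LineageCall.
    """
    if rules is None:
        rules = load_rules()
    rule = rules.get(lineage.lineage_path)
    flags: set[str] = set()
    if rule is None:
        flags.add("rules_missing")
        lineage.consistency_flags |= flags
        return flags
    if "any" not in rule.chromodomain and features.chromodomain not in rule.chromodomain:
        flags.add("chromodomain_mismatch")
    arh = features.arh_position or "none"
    if "any" not in rule.arh_position and arh not in rule.arh_position:
        flags.add("arh_position_mismatch")
    if features.pbs_mode != "none" and "any" not in rule.pbs:
        mode = {"full_tRNA": "full", "half_tRNA": "half", "fuzzy_tRNA": "full",
                "self": "self"}.get(features.pbs_mode, features.pbs_mode)
        token = mode if mode == "self" else f"{mode}:{features.pbs_isoacceptor}"
        wildcard = f"{mode}:*"
        if token not in rule.pbs and wildcard not in rule.pbs:
            flags.add("pbs_unexpected")
    lineage.consistency_flags |= flags
    return flags


# ---------------------------------------------------------------------------
# aromatic cage


def detect_aromatic_cage(chd_protein: str, refdb) -> dict:
    """Check the three aromatic-cage sites of a chromodomain.

    The query is aligned locally to the best-matching CHD reference that has
    annotated cage columns; the residues mapped to the three columns must be
    aromatic (F, Y or W). A column not covered by the alignment is reported
    as 'unknown'; the cage is present only if all three sites are.
    """
    refs = [e for e in refdb.entries if e.name in refdb.cage_columns]
    if not refs:
        raise ValueError("reference database has no CHD entries with cage columns")
    aligner = make_protein_aligner()
    best_entry, best_aln, best_score = None, None, -1.0
    for entry in refs:
        score = aligner.score(chd_protein, entry.protein)
        if score > best_score:
            best_entry, best_score = entry, score
    best_aln = aligner.align(chd_protein, best_entry.protein)[0]
    q_blocks, r_blocks = best_aln.aligned
    ref_to_query = {}
    for (qa, qb), (ra, rb) in zip(q_blocks, r_blocks):
        for i in range(qb - qa):
            ref_to_query[ra + i] = qa + i
    sites = []
    for col in refdb.cage_columns[best_entry.name]:
        qpos = ref_to_query.get(col)
        if qpos is None:
            sites.append("unknown")
        else:
            sites.append("present" if chd_protein[qpos] in "FYW" else "absent")
    return {
        "site1": sites[0], "site2": sites[1], "site3": sites[2],
        "cage": all(s == "present" for s in sites),
        "reference": best_entry.name,
    }


# ---------------------------------------------------------------------------
# reporting


REPORT_COLUMNS = [
    "element", "superfamily", "lineage", "ltr_similarity", "tsd_len", "tsd_seq",
    "pbs_mode", "pbs_trna", "domains_in_order", "eorf_labels", "qc_flags",
]


def format_report(elements: list[ElementRecord]) -> tuple[pd.DataFrame, dict]:
    """Per-element table plus summary frequency tables (lineage counts, PBS
    mode frequencies, TSD length frequencies, eORF label frequencies)."""
    rows = []
    for el in elements:
        lineage = el.lineage.lineage_path if el.lineage is not None else ""
        sf = el.lineage.superfamily if el.lineage is not None else (
            el.architecture.superfamily if el.architecture is not None else ""
        )
        rows.append(
            {
                "element": el.seq.id,
                "superfamily": sf,
                "lineage": lineage,
                "ltr_similarity": round(el.ltr.similarity, 2) if el.ltr else "",
                "tsd_len": el.tsd.length if el.tsd else "",
                "tsd_seq": el.tsd.left_seq if el.tsd else "",
                "pbs_mode": el.pbs.mode if el.pbs else "none",
                "pbs_trna": (el.pbs.isoacceptor or "") if el.pbs else "",
                "domains_in_order": "-".join(
                    c.domain_type for c in el.architecture.calls
                ) if el.architecture else "",
                "eorf_labels": ",".join(
                    sorted(o.label for o in el.eorfs if o.label and not o.excluded)
                ),
                "qc_flags": ",".join(sorted(str(f) for f in el.qc_flags)),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    n = len(df)
    summary = {
        "n_elements": n,
        "lineage_counts": dict(Counter(r["lineage"] for r in rows)),
        "pbs_mode_freq": {k: v / n for k, v in Counter(r["pbs_mode"] for r in rows).items()} if n else {},
        "tsd_len_freq": {str(k): v / n for k, v in Counter(r["tsd_len"] for r in rows).items()} if n else {},
        "eorf_label_freq": dict(
            Counter(l for r in rows for l in r["eorf_labels"].split(",") if l)
        ),
    }
    return df, summary
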