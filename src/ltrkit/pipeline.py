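"""End-to-end annotation of element sequences.

Composes the stage modules: structural parsing (LTR pair, TSD), translated
domain search and architecture validation, PBS typing, eORF detection with
tandem-repeat filtering, lineage voting and feature-consistency checks.
Per-element failures never abort a batch: they are recorded as qc_flags.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .core_io import ElementRecord, GenomicSequence, PipelineConfig, ReferenceDomainDB, TRNALibrary
from .domain_scan import chain_hits, polyprotein_interval, scan_domains, validate_architecture
from .eorf_scan import filter_eorfs, find_orfs, find_tandem_arrays, label_eorf
from .lineage_classify import (
    build_feature_profile,
    check_consistency,
    load_rules,
    vote_lineage,
)
from .ltr_struct import detect_tsd, find_ltr_pair, validate_element
from .pbs_typing import call_pbs


def annotate_element(
    seq: GenomicSequence,
    refdb: ReferenceDomainDB,
    trnas: TRNALibrary,
    config: PipelineConfig | None = None,
    rules: Optional[dict] = None,
    predelimited: bool = False,
) -> ElementRecord:
    """Run the full annotation chain on one element sequence.

    With predelimited=True the sequence is taken to span exactly the element
    (5' LTR start to 3' LTR end); the LTR pair is still located to measure
    similarity and anchor the PBS window.
    """
    config = config or PipelineConfig()
    record = ElementRecord(seq)
    record.ltr = find_ltr_pair(seq, config)
    if seq.left_flank and seq.right_flank:
        record.tsd = detect_tsd(seq.left_flank, seq.right_flank, config)

    hits = scan_domains(seq, refdb, config)
    record.architecture = validate_architecture(chain_hits(hits, config.chain_max_gap))

    if record.ltr is not None:
        call_pbs(record, trnas, config)

    poly_iv = polyprotein_interval(record.architecture)
    if poly_iv is not None:
        orfs = find_orfs(seq.residues, config.eorf_min_codons, config.eorf_require_atg)
        arrays = find_tandem_arrays(seq.residues, config.tandem_max_period, config)
        labelled = []
        for orf in orfs:
            label = label_eorf(orf, poly_iv)
            if label is not None:
                orf.label = label
                labelled.append(orf)
        record.eorfs = filter_eorfs(labelled, arrays, config)

    validate_element(record, config)

    if record.architecture is not None and any(
        c.domain_type in ("PROT", "INT", "RT", "RH") for c in record.architecture.calls
    ):
        record.lineage = vote_lineage(record.architecture, config)
        profile = build_feature_profile(record)
        check_consistency(record.lineage, profile, rules)
    return record


def annotate(
    seqs: Iterable[GenomicSequence],
    refdb: ReferenceDomainDB,
    trnas: TRNALibrary,
    config: PipelineConfig | None = None,
    predelimited: bool = False,
) -> list[ElementRecord]:
    """Annotate a batch of sequences; rules are loaded once."""
    config = config or PipelineConfig()
    rules = load_rules()
    return [
        annotate_element(s, refdb, trnas, config, rules, predelimited) for s in seqs
    ]
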