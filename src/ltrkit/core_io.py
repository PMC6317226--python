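"""Shared domain types, configuration and file I/O.

Coordinates are 0-based half-open everywhere inside the package; GFF3 output
converts to 1-based inclusive. Elements are assumed to be oriented 5' LTR
first; the toolkit never reverse-complements an input element.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: domain types recognised in reference protein names
DOMAIN_TYPES = ("GAG", "PROT", "INT", "RT", "RH", "aRH", "CHD", "CHDCR")

#: the five domains whose genomic order defines the superfamily
CORE_DOMAINS = ("GAG", "PROT", "INT", "RT", "RH")

SUPERFAMILY_BY_PREFIX = {"Ty1": "Ty1/copia", "Ty3": "Ty3/gypsy"}

#: level tokens accepted by the lineage-path grammar (Tables 1-2 vocabulary);
#: extensible through PipelineConfig.extra_lineage_levels
KNOWN_LINEAGE_LEVELS = frozenset(
    {
        "Ty1/copia", "Ty3/gypsy",
        # Ty1/copia lineages
        "Ale", "Alesia", "Angela", "Bianca", "Bryco", "Lyco",
        "Gymco-I", "Gymco-II", "Gymco-III", "Gymco-IV",
        "Ikeros", "Ivana", "Osser", "SIRE", "TAR", "Tork",
        # Ty3/gypsy structure
        "chromovirus", "non-chromovirus",
        "CRM", "Chlamyvir", "Galadriel", "Tcn1", "Reina", "Tekay",
        "OTA", "Athila", "Tat", "TatI", "TatII", "TatIII", "Ogre", "Retand",
        "Phygy", "Selgy",
    }
)


class QCFlag(str, enum.Enum):
    """Reasons an element is rejected or flagged during validation."""

    AMBIGUOUS_BASES = "ambiguous_bases"
    NESTED_INSERTION_SUSPECT = "nested_insertion_suspect"
    NO_POLYPROTEIN = "no_polyprotein"
    BAD_TERMINI = "bad_termini"
    BAD_ORDER = "bad_order"
    DUPLICATE_DOMAIN = "duplicate_domain"
    CHIMERA = "chimera"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


Interval = tuple[int, int]


def revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


@dataclass
class GenomicSequence:
    """One element (or genomic) DNA sequence with optional flanking context."""

    id: str
    residues: str
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        for name in ("residues", "left_flank", "right_flank"):
            s = getattr(self, name)
            bad = set(s) - DNA_ALPHABET
            if bad:
                raise ValueError(f"{self.id}: non-DNA characters {sorted(bad)} in {name}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PipelineConfig:
    """Every numeric threshold of the annotation pipeline.

    Defaults are the published prediction/filter settings: LTR length
    100-6000 bp, inter-LTR distance 1000-20000 bp, >=95% LTR similarity,
    TG..CA termini, <=10 ambiguous bases, exact PBS >=12 bp within a 50 bp
    window, fuzzy PBS (TGG at 0-5 bp) with <=2 differences of which <=1 an
    indel, self-primer >=10 bp, eORFs >=250 codons, tandem-repeat exclusion
    at >=3 monomers spanning >150 bp, clustering at 80% identity over 90%
    length, CD-HIT-style representative selection at 0.90.
    """

    ltr_min_len: int = 100
    ltr_max_len: int = 6000
    inter_ltr_min: int = 1000
    inter_ltr_max: int = 20000
    ltr_min_similarity: float = 95.0  # percent
    require_tg_ca: bool = True
    max_n: int = 10
    pbs_window: int = 50
    pbs_min_exact: int = 12
    tgg_max_offset: int = 5
    fuzzy_max_diffs: int = 2
    fuzzy_max_indels: int = 1
    fuzzy_window: int = 18
    self_primer_min: int = 10
    self_primer_max: int = 20
    eorf_min_codons: int = 250
    eorf_require_atg: bool = True
    tandem_min_monomers: int = 3
    tandem_min_span: int = 150
    tandem_max_period: int = 200
    cluster_min_identity: float = 80.0  # percent
    cluster_min_coverage: float = 90.0  # percent of the shorter sequence
    rep_identity: float = 0.90
    eorf_group_evalue: float = 1e-10
    tsd_lengths: tuple[int, ...] = (4, 5, 6)
    # domain-scan scoring (implementation choices, documented in docs/methods.md)
    scan_min_score: float = 80.0
    scan_min_identity: float = 25.0
    scan_gap_open: float = 10.0
    scan_gap_extend: float = 1.0
    chain_max_gap: int = 300
    min_segment_aa: int = 20
    # lineage voting
    vote_confidence: float = 0.5
    extra_lineage_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"config field {f.name} must be non-negative")
        for name in ("ltr_min_similarity", "cluster_min_identity", "cluster_min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} is on the percent scale, got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``key=value`` config file; unknown keys are errors."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, known[key].type)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str, typ: object) -> object:
    t = str(typ)
    if "bool" in t:
        return value.lower() in ("1", "true", "yes")
    if "tuple[int" in t:
        return tuple(int(x) for x in value.split(",") if x)
    if "tuple[str" in t:
        return tuple(x for x in value.split(",") if x)
    if "int" in t:
        return int(value)
    if "float" in t:
        return float(value)
    return value


@dataclass
class RefEntry:
    """One classified reference protein (a REXdb-style database entry)."""

    name: str
    superfamily: str
    domain_type: str
    element_name: str
    protein: str

    def __post_init__(self) -> None:
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-amino-acid characters {sorted(bad)}")


@dataclass
class ReferenceDomainDB:
    """Reference protein-domain database plus element classification table."""

    entries: list[RefEntry]
    lineage_table: dict[str, str]
    #: per CHD entry name: three 0-based reference columns of the aromatic cage
    cage_columns: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {e.element_name for e in self.entries} - set(self.lineage_table)
        if missing:
            raise ValueError(f"entries without lineage classification: {sorted(missing)[:5]}")

    def lineage_of(self, element_name: str) -> str:
        return self.lineage_table[element_name]

    def entries_of_type(self, domain_type: str) -> list[RefEntry]:
        return [e for e in self.entries if e.domain_type == domain_type]

    @classmethod
    def from_files(cls, protein_fasta: str | Path, lineage_tsv: str | Path) -> "ReferenceDomainDB":
        table = read_lineage_table(lineage_tsv)
        entries = []
        for rec in read_fasta_protein(protein_fasta):
            sf, dt, el = parse_rexdb_name(rec[0])
            entries.append(RefEntry(rec[0], SUPERFAMILY_BY_PREFIX.get(sf, sf), dt, el, rec[1]))
        return cls(entries, table)


@dataclass
class TRNAEntry:
    id: str
    isoacceptor: str  # e.g. "tRNA-Met"
    residues: str  # DNA alphabet; U mapped to T on load
    anticodon_start: int
    #: (0-based tRNA index, element-strand bases that can pair at this position)
    edited_positions: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.anticodon_start < len(self.residues):
            raise ValueError(f"{self.id}: anticodon_start out of range")
        for idx, _bases in self.edited_positions:
            if not 0 <= idx < len(self.residues):
                raise ValueError(f"{self.id}: edited position {idx} out of range")


@dataclass
class TRNALibrary:
    entries: list[TRNAEntry]

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_files(cls, fasta: str | Path, meta_tsv: str | Path) -> "TRNALibrary":
        """Load tRNAs from FASTA plus a sidecar TSV.

        The TSV columns are: id, isoacceptor, anticodon_start (0-based) and an
        optional ``edited_positions`` column encoded as ``idx:bases`` items
        separated by ';' (e.g. ``34:ATC``).
        """
        seqs = {s.id: s.residues for s in read_fasta(fasta)}
        entries = []
        for lineno, raw in enumerate(Path(meta_tsv).read_text().splitlines(), 1):
            if not raw.strip() or raw.startswith("#") or raw.startswith("id\t"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{meta_tsv}:{lineno}: expected >=3 columns")
            tid, iso, ac = parts[0], parts[1], int(parts[2])
            edits = []
            if len(parts) > 3 and parts[3]:
                for item in parts[3].split(";"):
                    idx, bases = item.split(":")
                    edits.append((int(idx), bases))
            if tid not in seqs:
                raise ValueError(f"{meta_tsv}:{lineno}: {tid} not in FASTA")
            entries.append(TRNAEntry(tid, iso, seqs[tid], ac, edits))
        return cls(entries)


# Annotation result types live with the modules that produce them
# (ltr_struct.LTRPair/TSDCall, domain_scan.DomainArchitecture, ...); the
# record below aggregates them.


@dataclass
class ElementRecord:
    """One candidate LTR-retrotransposon with all annotations collected."""

    seq: GenomicSequence
    ltr: Optional["object"] = None  # ltr_struct.LTRPair
    tsd: Optional["object"] = None  # ltr_struct.TSDCall
    architecture: Optional["object"] = None  # domain_scan.DomainArchitecture
    pbs: Optional["object"] = None  # pbs_typing.PrimerCall
    eorfs: list = field(default_factory=list)  # eorf_scan.ORFCall
    lineage: Optional["object"] = None  # lineage_classify.LineageCall
    qc_flags: set[QCFlag] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read DNA FASTA; upper-cases and maps RNA U to T.

    Order is preserved; an empty file yields an empty list.
    """
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: malformed header for record #{len(out) + 1}")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T")
        out.append(GenomicSequence(rec.id, residues))
    return out


def read_fasta_protein(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str] | GenomicSequence], path: str | Path) -> None:
    seqrecs = []
    for r in records:
        if isinstance(r, GenomicSequence):
            seqrecs.append(SeqRecord(Seq(r.residues), id=r.id, description=""))
        else:
            seqrecs.append(SeqRecord(Seq(r[1]), id=r[0], description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# REXdb naming scheme


def parse_rexdb_name(name: str) -> tuple[str, str, str]:
    """Split ``Ty1-RT__REXdb_ID3879`` into ``(Ty1, RT, REXdb_ID3879)``.

    The prefix before the double underscore is split on its first '-' into a
    superfamily token and a domain-type token; the remainder is the element
    name the lineage table is keyed by.
    """
    if "__" not in name:
        raise ValueError(f"unparseable reference name {name!r} (missing '__')")
    prefix, element_name = name.split("__", 1)
    if "-" not in prefix:
        raise ValueError(f"unparseable reference name {name!r} (prefix lacks '-')")
    superfamily, domain_type = prefix.split("-", 1)
    return superfamily, domain_type, element_name


def format_rexdb_name(superfamily: str, domain_type: str, element_name: str) -> str:
    return f"{superfamily}-{domain_type}__{element_name}"


# ---------------------------------------------------------------------------
# lineage table


def read_lineage_table(
    path: str | Path, extra_levels: Sequence[str] = ()
) -> dict[str, str]:
    """Read a TSV of (element_name, lineage_path) rows.

    Paths follow the pipe-delimited grammar ``superfamily|level1|...|levelN``;
    a level outside the known vocabulary raises a warning flag (stored on the
    function as ``read_lineage_table.warnings``), a duplicate element name is
    an error.
    """
    vocab = KNOWN_LINEAGE_LEVELS | set(extra_levels)
    table: dict[str, str] = {}
    warnings: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#") or raw.startswith("element_name\t"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        name, lineage = parts[0], parts[1]
        if name in table:
            raise ValueError(f"{path}:{lineno}: duplicate element_name {name!r}")
        levels = lineage.split("|")
        if levels[0] not in ("Ty1/copia", "Ty3/gypsy"):
            warnings.append(f"{name}: unknown superfamily {levels[0]!r}")
        for lv in levels[1:]:
            if lv not in vocab:
                warnings.append(f"{name}: unknown level {lv!r}")
        table[name] = lineage
    read_lineage_table.warnings = warnings  # type: ignore[attr-defined]
    return table


def write_lineage_table(table: dict[str, str], path: str | Path) -> None:
    lines = ["element_name\tlineage_path"]
    lines += [f"{k}\t{v}" for k, v in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_VERSION = "##gff-version 3"


def write_gff3(elements: Iterable[ElementRecord], path: str | Path) -> int:
    """Write annotations as GFF3 (1-based inclusive coordinates).

    Feature types: LTR_retrotransposon (parent), long_terminal_repeat,
    primer_binding_site, protein_match, ORF, target_site_duplication.
    When flanks are present all coordinates are offset by the left-flank
    length so TSD rows (which live in the flanks) stay within the padded
    sequence region. Returns the number of feature rows written.
    """
    lines = [_GFF_VERSION]
    n_rows = 0

    def row(seqid, ftype, start0, end0, strand, attrs, offset):
        nonlocal n_rows
        s, e = start0 + offset + 1, end0 + offset
        if s > e:
            raise ValueError(f"{seqid}: empty/inverted interval for {ftype}")
        lines.append(
            "\t".join(
                [seqid, "ltrkit", ftype, str(s), str(e), ".", strand, ".",
                 ";".join(f"{k}={v}" for k, v in attrs)]
            )
        )
        n_rows += 1

    for el in elements:
        seqid = el.seq.id
        off = len(el.seq.left_flank)
        n = len(el.seq.residues)
        parent = f"{seqid}_elem"
        attrs = [("ID", parent)]
        if el.lineage is not None:
            attrs.append(("lineage", el.lineage.lineage_path))
        if el.tsd is not None:
            attrs.append(("tsd_len", el.tsd.length))
            attrs.append(("tsd_seq", el.tsd.left_seq))
        if el.qc_flags:
            attrs.append(("qc", ",".join(sorted(str(f) for f in el.qc_flags))))
        row(seqid, "LTR_retrotransposon", 0, n, "+", attrs, off)
        if el.ltr is not None:
            for tag, (s, e) in (("five", el.ltr.five_ltr), ("three", el.ltr.three_ltr)):
                row(seqid, "long_terminal_repeat", s, e, "+",
                    [("ID", f"{seqid}_{tag}_ltr"), ("Parent", parent),
                     ("similarity", f"{el.ltr.similarity:.1f}")], off)
        if el.tsd is not None and off >= el.tsd.length and el.seq.right_flank:
            L = el.tsd.length
            row(seqid, "target_site_duplication", -L, 0, "+",
                [("Parent", parent), ("side", "left")], off)
            row(seqid, "target_site_duplication", n, n + L, "+",
                [("Parent", parent), ("side", "right")], off)
        if el.pbs is not None and el.pbs.mode != "none":
            s, e = el.pbs.pbs_interval
            row(seqid, "primer_binding_site", s, e, "+",
                [("Parent", parent), ("mode", el.pbs.mode),
                 ("trna", el.pbs.trna_id or "."),
                 ("match_len", el.pbs.match_len)], off)
        if el.architecture is not None:
            for call in el.architecture.calls:
                s, e = call.dna_interval
                row(seqid, "protein_match", s, e, call.strand,
                    [("Parent", parent), ("domain_type", call.domain_type),
                     ("best_ref", call.best_ref), ("lineage", call.lineage),
                     ("identity", f"{call.identity:.1f}")], off)
        for orf in el.eorfs:
            s, e = orf.dna_interval
            attrs = [("Parent", parent), ("label", orf.label or ".")]
            if orf.excluded:
                attrs.append(("excluded", orf.exclusion_reason))
            row(seqid, "ORF", s, e, orf.strand, attrs, off)

    Path(path).write_text("\n".join(lines) + "\n")
    return n_rows
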