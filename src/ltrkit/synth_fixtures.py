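"""Deterministic synthetic fixtures: toy reference database, tRNA library
and ground-truth LTR-retrotransposon elements.

Every element is assembled from explicit parts (flank + TSD + 5' LTR with
TG..CA termini + PBS + eORFs + in-frame polyprotein cassette + optional
tandem-array decoys + mutated 3' LTR + TSD + flank) and shipped with a
manifest of everything a detector should recover. Domain cassettes are
reverse-translated reference proteins with no mutation, so domain recovery
at identity 100 is exact by construction; random filler is resampled at
generation time if it accidentally contains a competing signal (manifests
are verified against the emitted sequence before an element is released).

The built-in lineage roster mirrors the characteristic feature combinations
of the classification: chromoviruses with CHD/CHDCR chromodomains (CHDCR
only in CRM), Tat subclades distinguished by aRH position, half-molecule
tRNA primers for Osser (1/2tRNA-Met) and Bianca (edited 1/2tRNA-Ile),
self-priming for TAR and Tcn1, and lineage-typical eORFs.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass
from typing import Optional

from .core_io import (
    ElementRecord,
    GenomicSequence,
    RefEntry,
    ReferenceDomainDB,
    TRNAEntry,
    TRNALibrary,
    PipelineConfig,
    format_rexdb_name,
    revcomp,
)
from .domain_scan import _CODON_TABLE, scan_domains
from .eorf_scan import filter_eorfs, find_orfs, find_tandem_arrays, label_eorf
from .ltr_struct import detect_tsd, find_ltr_pair
from .pbs_typing import call_pbs

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    if aa != "*":
        _CODONS_BY_AA.setdefault(aa, []).append(codon)
for v in _CODONS_BY_AA.values():
    v.sort()

DOMAIN_LENGTHS = {
    "GAG": 400, "PROT": 130, "RT": 260, "RH": 130,
    "INT": 280, "aRH": 130, "CHD": 60, "CHDCR": 60,
}

CAGE_COLUMNS = (10, 25, 40)


@dataclass(frozen=True)
class LineageProfile:
    short: str
    path: str
    superfamily: str  # Ty1/copia | Ty3/gypsy
    chromodomain: Optional[str] = None  # CHD | CHDCR
    cage: bool = False  # aromatic cage planted in the CHD
    arh_position: Optional[str] = None  # PROT_RT | RH_INT | after_INT
    pbs_mode: str = "full"  # full | half | self
    trna: Optional[str] = "tRNA-Met"
    eorf_label: Optional[str] = None


#: default roster; the first eight already span both superfamilies and all
#: structural feature classes
ROSTER: tuple[LineageProfile, ...] = (
    LineageProfile("Ale", "Ty1/copia|Ale", "Ty1/copia"),
    LineageProfile("CRM", "Ty3/gypsy|chromovirus|CRM", "Ty3/gypsy", chromodomain="CHDCR"),
    LineageProfile("Ogre", "Ty3/gypsy|non-chromovirus|OTA|Tat|Ogre", "Ty3/gypsy",
                   arh_position="RH_INT", trna="tRNA-Arg", eorf_label="eORF-5'F"),
    LineageProfile("Bianca", "Ty1/copia|Bianca", "Ty1/copia", pbs_mode="half", trna="tRNA-Ile"),
    LineageProfile("TAR", "Ty1/copia|TAR", "Ty1/copia", pbs_mode="self", trna=None),
    LineageProfile("Tekay", "Ty3/gypsy|chromovirus|Tekay", "Ty3/gypsy", chromodomain="CHD"),
    LineageProfile("Athila", "Ty3/gypsy|non-chromovirus|OTA|Athila", "Ty3/gypsy",
                   trna="tRNA-Asp", eorf_label="eORF-3'F"),
    LineageProfile("TatI", "Ty3/gypsy|non-chromovirus|OTA|Tat|TatI", "Ty3/gypsy",
                   arh_position="PROT_RT", trna="tRNA-Lys", eorf_label="eORF-3'R"),
    LineageProfile("Osser", "Ty1/copia|Osser", "Ty1/copia", pbs_mode="half", trna="tRNA-Met"),
    LineageProfile("Tcn1", "Ty3/gypsy|chromovirus|Tcn1", "Ty3/gypsy",
                   chromodomain="CHD", cage=True, pbs_mode="self", trna=None),
    LineageProfile("SIRE", "Ty1/copia|SIRE", "Ty1/copia", eorf_label="eORF-3'F"),
    LineageProfile("Tork", "Ty1/copia|Tork", "Ty1/copia"),
    LineageProfile("TatIII", "Ty3/gypsy|non-chromovirus|OTA|Tat|TatIII", "Ty3/gypsy",
                   arh_position="after_INT", trna="tRNA-Trp", eorf_label="eORF-5'R"),
)

PROFILE_BY_SHORT = {p.short: p for p in ROSTER}


# ---------------------------------------------------------------------------
# random sequence helpers


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def reverse_translate(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def mutate_protein(
    rng: random.Random, protein: str, n_subs: int, frozen: frozenset[int] = frozenset()
) -> str:
    """Substitute n_subs distinct non-frozen positions with a different
    residue (substitution-only, so identity to the parent is analytic)."""
    positions = [i for i in range(len(protein)) if i not in frozen]
    if n_subs > len(positions):
        raise ValueError("more substitutions requested than mutable positions")
    out = list(protein)
    for i in rng.sample(positions, n_subs):
        out[i] = rng.choice([a for a in AMINO_ACIDS if a != out[i]])
    return "".join(out)


def mutate_dna(
    rng: random.Random, dna: str, n_subs: int, frozen: frozenset[int] = frozenset()
) -> str:
    positions = [i for i in range(len(dna)) if i not in frozen]
    out = list(dna)
    for i in rng.sample(positions, n_subs):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def branch_identity(pairwise_target: float, n_states: int = 20) -> float:
    """Per-branch identity q to a common ancestor such that two independent
    descendants share approximately the pairwise_target identity
    (t = q^2 + (1-q)^2/(n_states-1), coincidental re-substitutions counted)."""
    if not 0 < pairwise_target <= 1:
        raise ValueError("identity target must be in (0, 1]")
    k = n_states - 1
    # k*t = k*q^2 + (1-q)^2  ->  (k+1) q^2 - 2 q + 1 - k t = 0
    disc = 4 - 4 * (k + 1) * (1 - k * pairwise_target)
    if disc < 0:
        raise ValueError(f"identity target {pairwise_target} infeasible")
    return (2 + disc ** 0.5) / (2 * (k + 1))


# ---------------------------------------------------------------------------
# reference database and tRNA library


def make_toy_refdb(
    n_lineages: int = len(ROSTER),
    intra_identity: float = 0.95,
    inter_identity: float = 0.5,
    seed: int = 0,
    variants: int = 2,
) -> ReferenceDomainDB:
    """Toy REXdb-style reference: per lineage, one protein per required
    domain type plus close variants.

    Ancestral proteins are drawn per (superfamily, domain type); lineages
    diverge from the ancestor so that measured between-lineage identity
    (within a superfamily) approximates inter_identity, and variants within
    a lineage approximate intra_identity. CHD entries carry aromatic-cage
    columns; cage residues are planted (F/Y/W) for cage lineages and forced
    non-aromatic otherwise.
    """
    if not 0 < inter_identity < intra_identity <= 1:
        raise ValueError("need 0 < inter_identity < intra_identity <= 1")
    if not 1 <= n_lineages <= len(ROSTER):
        raise ValueError(f"n_lineages must be in 1..{len(ROSTER)}")
    rng = random.Random(seed)
    roster = ROSTER[:n_lineages]
    q_inter = branch_identity(inter_identity)
    q_intra = branch_identity(intra_identity)

    ancestors: dict[tuple[str, str], str] = {}
    for sf in ("Ty1/copia", "Ty3/gypsy"):
        for dtype, length in DOMAIN_LENGTHS.items():
            if sf == "Ty1/copia" and dtype in ("aRH", "CHD", "CHDCR"):
                continue
            prot = random_protein(rng, length)
            if dtype == "CHD":
                prot = list(prot)
                for col in CAGE_COLUMNS:
                    prot[col] = rng.choice("FYW")
                prot = "".join(prot)
            ancestors[(sf, dtype)] = prot

    entries: list[RefEntry] = []
    lineage_table: dict[str, str] = {}
    cage_columns: dict[str, tuple[int, int, int]] = {}
    for profile in roster:
        dtypes = ["GAG", "PROT", "RT", "RH", "INT"]
        if profile.arh_position is not None:
            dtypes.append("aRH")
        if profile.chromodomain is not None:
            dtypes.append(profile.chromodomain)
        for dtype in dtypes:
            anc = ancestors[(profile.superfamily, dtype)]
            frozen = frozenset(CAGE_COLUMNS) if dtype == "CHD" else frozenset()
            n_subs = round((1 - q_inter) * (len(anc) - len(frozen)))
            lin_prot = mutate_protein(rng, anc, n_subs, frozen)
            if dtype == "CHD" and not profile.cage:
                chars = list(lin_prot)
                for col in CAGE_COLUMNS:
                    chars[col] = rng.choice([a for a in AMINO_ACIDS if a not in "FYW"])
                lin_prot = "".join(chars)
            n_var_subs = round((1 - q_intra) * (len(lin_prot) - len(frozen)))
            for v in range(1, variants + 1):
                prot = mutate_protein(rng, lin_prot, n_var_subs, frozen)
                element_name = f"{profile.short}_v{v}"
                prefix = "Ty1" if profile.superfamily == "Ty1/copia" else "Ty3"
                name = format_rexdb_name(prefix, dtype, element_name)
                entries.append(RefEntry(name, profile.superfamily, dtype, element_name, prot))
                lineage_table[element_name] = profile.path
                if dtype == "CHD":
                    cage_columns[name] = CAGE_COLUMNS
    return ReferenceDomainDB(entries, lineage_table, cage_columns)


_TRNA_ROSTER = ("tRNA-Met", "tRNA-Ile", "tRNA-Arg", "tRNA-Lys",
                "tRNA-Asp", "tRNA-Trp", "tRNA-Ala", "tRNA-Asn")


def make_toy_trnas(seed: int = 0, prepared: bool = True) -> TRNALibrary:
    """Toy tRNA library (72 nt bodies, anticodon at 34; CCA appended when
    prepared=True). tRNA-Ile carries the inosine-edited wobble position
    (first anticodon base) able to pair with A, T or C on the element
    strand."""
    rng = random.Random(seed)
    entries = []
    for iso in _TRNA_ROSTER:
        body = random_dna(rng, 72)
        edits = []
        if iso == "tRNA-Ile":
            body = body[:34] + "A" + body[35:]  # A-to-I edited wobble base
            edits = [(34, "ATC")]
        entries.append(TRNAEntry(f"{iso}_1", iso, body, 34, edits))
    lib = TRNALibrary(entries)
    if prepared:
        from .pbs_typing import prepare_trnas

        lib = prepare_trnas(lib)
    return lib


# ---------------------------------------------------------------------------
# element construction


@dataclass
class EORFSpec:
    label: str  # eORF-5'F | eORF-5'R | eORF-3'F | eORF-3'R
    codons: int = 260
    decoy_tandem: bool = False  # build from a tandem array (to be excluded)


@dataclass
class ElementSpec:
    element_id: str
    lineage: str  # short roster name (e.g. "CRM")
    pbs_mode: str = "profile"  # profile | full | half | fuzzy | self | none
    trna_id: Optional[str] = None
    eorfs: tuple[EORFSpec, ...] = ()
    ltr_len: int = 300
    target_ltr_similarity: float = 97.0
    tsd_len: int = 5
    flank_len: int = 30
    seed: int = 0

    def resolve(self) -> tuple[LineageProfile, str, Optional[str]]:
        if self.lineage not in PROFILE_BY_SHORT:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        profile = PROFILE_BY_SHORT[self.lineage]
        mode = self.pbs_mode
        trna = self.trna_id
        if mode == "profile":
            mode = profile.pbs_mode
        if trna is None and profile.trna is not None:
            trna = f"{profile.trna}_1"
        if mode in ("full", "half", "fuzzy") and trna is None:
            raise ValueError(f"{self.element_id}: mode {mode} requires a tRNA")
        return profile, mode, trna


@dataclass
class TruthManifest:
    """Ground truth for one generated element, verified against the emitted
    sequence at generation time."""

    element_id: str
    lineage_path: str
    superfamily: str
    chromodomain: Optional[str]
    cage: Optional[bool]
    arh_position: Optional[str]
    five_ltr: tuple[int, int]
    three_ltr: tuple[int, int]
    ltr_similarity: float
    tsd_len: int
    tsd_seq: str
    pbs_mode: str  # detector vocabulary: full_tRNA | half_tRNA | ...
    trna_id: Optional[str]
    isoacceptor: Optional[str]
    domains: list[tuple[str, int, int]]
    polyprotein_interval: tuple[int, int]
    eorf_labels: list[str]  # retained labels, sorted
    n_excluded_eorfs: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_MODE_NAMES = {"full": "full_tRNA", "half": "half_tRNA", "fuzzy": "fuzzy_tRNA",
               "self": "self", "none": "none"}


def _cassette_types(profile: LineageProfile) -> list[str]:
    if profile.superfamily == "Ty1/copia":
        order = ["GAG", "PROT", "INT", "RT", "RH"]
    else:
        order = ["GAG", "PROT", "RT", "RH", "INT"]
    if profile.arh_position == "PROT_RT":
        order.insert(order.index("RT"), "aRH")
    elif profile.arh_position == "RH_INT":
        order.insert(order.index("INT"), "aRH")
    elif profile.arh_position == "after_INT":
        order.append("aRH")
    if profile.chromodomain is not None:
        order.append(profile.chromodomain)
    return order


def _build_pbs(rng, mode, trna, ltr_len):
    """Return (pbs_block, ltr_plant) where ltr_plant is the complement to be
    embedded inside the 5' LTR for self-priming."""
    if mode == "full":
        return revcomp(trna.residues[-14:]), None
    if mode == "half":
        c = trna.anticodon_start + 1
        pbs = list(revcomp(trna.residues[c - 13 : c]))
        for idx, allowed in trna.edited_positions:
            m = c - 1 - idx
            if 0 <= m < len(pbs):
                pbs[m] = rng.choice(allowed)
        return "".join(pbs), None
    if mode == "fuzzy":
        pbs = list(revcomp(trna.residues[-18:]))
        p1 = rng.randrange(3, 12)  # breaks the exact >=12 bp prefix
        p2 = rng.choice([p for p in range(3, 18) if p != p1])
        for p in (p1, p2):
            pbs[p] = rng.choice([b for b in "ACGT" if b != pbs[p]])
        return "".join(pbs), None
    if mode == "self":
        pbs = random_dna(rng, 12)
        return pbs, revcomp(pbs)
    return random_dna(rng, 12), None  # none


def _build_eorf_block(rng, spec: EORFSpec) -> tuple[str, bool]:
    """In-frame guarded ORF block; returns (dna, is_decoy)."""
    if spec.decoy_tandem:
        monomer = reverse_translate(rng, random_protein(rng, 21))  # 63 bp, stop-free
        copies = max(13, (spec.codons * 3) // len(monomer) + 2)
        core = "ATG" + monomer * copies + "TAA"
    else:
        core = "ATG" + reverse_translate(rng, random_protein(rng, spec.codons - 1)) + "TAA"
    block = "TAA" + core  # in-frame guard stop right before the ATG
    if spec.label.endswith("R"):
        block = revcomp(block)
    return block, spec.decoy_tandem


def build_element(
    spec: ElementSpec,
    refdb: ReferenceDomainDB,
    trnas: TRNALibrary,
    config: PipelineConfig | None = None,
) -> tuple[GenomicSequence, TruthManifest]:
    """Assemble one element and its verified truth manifest.

    The manifest is checked against the emitted sequence by running the
    cheap detectors (TSD, LTR pair, PBS, ORF labelling + tandem filtering);
    if random filler accidentally produces a competing signal the filler is
    resampled under a derived sub-seed.
    """
    config = config or PipelineConfig()
    profile, mode, trna_id = spec.resolve()
    if mode in ("self", "none"):
        trna_id = None
    trna = None
    if trna_id is not None:
        by_id = {t.id: t for t in trnas}
        if trna_id not in by_id:
            raise ValueError(f"{spec.element_id}: tRNA {trna_id!r} not in library")
        trna = by_id[trna_id]

    proteins = {}
    for dtype in _cassette_types(profile):
        name = f"{profile.short}_v1"
        entry = next(
            (e for e in refdb.entries if e.element_name == name and e.domain_type == dtype),
            None,
        )
        if entry is None:
            raise ValueError(
                f"{spec.element_id}: reference database lacks {dtype} for lineage {profile.short}"
            )
        proteins[dtype] = entry.protein

    last_error = "no attempt"
    for attempt in range(30):
        rng = random.Random((spec.seed * 1009 + attempt * 7919) % (2**31))
        result = _assemble_once(spec, profile, mode, trna, proteins, rng, trnas, refdb, config)
        if isinstance(result, tuple):
            return result
        last_error = result
    raise RuntimeError(
        f"{spec.element_id}: could not generate a verifiable element ({last_error})"
    )


def _assemble_once(spec, profile, mode, trna, proteins, rng, trnas, refdb, config):
    """One assembly attempt; returns (seq, manifest) or a failure reason."""
    pbs_block, ltr_plant = _build_pbs(rng, mode, trna, spec.ltr_len)

    ltr5 = "TG" + random_dna(rng, spec.ltr_len - 4) + "CA"
    if ltr_plant is not None:
        mid = spec.ltr_len // 2
        ltr5 = ltr5[:mid] + ltr_plant + ltr5[mid + len(ltr_plant):]
    n_subs = round((1 - spec.target_ltr_similarity / 100.0) * spec.ltr_len)
    frozen = frozenset({0, 1, spec.ltr_len - 2, spec.ltr_len - 1})
    ltr3 = mutate_dna(rng, ltr5, n_subs, frozen)

    five_eorfs = [e for e in spec.eorfs if e.label.startswith("eORF-5")]
    three_eorfs = [e for e in spec.eorfs if e.label.startswith("eORF-3")]

    parts: list[str] = [ltr5, pbs_block, random_dna(rng, 40)]
    pos = sum(len(p) for p in parts)
    expected_excluded = 0
    for e in five_eorfs:
        block, decoy = _build_eorf_block(rng, e)
        parts.append(block)
        parts.append(random_dna(rng, 30))
        expected_excluded += decoy

    # polyprotein cassette: one in-frame ORF, domains in profile order
    cassette_protein = "".join(proteins[d] for d in _cassette_types(profile))
    cassette_start = sum(len(p) for p in parts)
    parts.append("ATG")
    domains: list[tuple[str, int, int]] = []
    off = cassette_start + 3
    for dtype in _cassette_types(profile):
        dna = reverse_translate(rng, proteins[dtype])
        parts.append(dna)
        domains.append((dtype, off, off + len(dna)))
        off += len(dna)
    parts.append("TAA")
    cassette_end = off + 3

    for e in three_eorfs:
        parts.append(random_dna(rng, 30))
        block, decoy = _build_eorf_block(rng, e)
        parts.append(block)
        expected_excluded += decoy
    parts.append(random_dna(rng, 80))
    parts.append(ltr3)
    residues = "".join(parts)

    tsd = random_dna(rng, spec.tsd_len)
    left_flank = random_dna(rng, spec.flank_len - spec.tsd_len) + tsd
    right_flank = tsd + random_dna(rng, spec.flank_len - spec.tsd_len)
    seq = GenomicSequence(spec.element_id, residues, left_flank, right_flank)

    # --- verification against the emitted sequence ---
    tsd_call = detect_tsd(left_flank, right_flank, config)
    if tsd_call is None or tsd_call.length != spec.tsd_len:
        return "TSD not recovered as generated"

    pair = find_ltr_pair(seq, config)
    d = len(residues) - spec.ltr_len
    if pair is None or pair.five_ltr != (0, spec.ltr_len) or pair.three_ltr != (d, len(residues)):
        return "LTR pair not recovered at the generated coordinates"
    if abs(pair.similarity - spec.target_ltr_similarity) > 1.0:
        return "LTR similarity off target"

    record = ElementRecord(seq, ltr=pair, tsd=tsd_call)
    pbs = call_pbs(record, trnas, config)
    if pbs.mode != _MODE_NAMES[mode]:
        return f"PBS mode {pbs.mode} != expected {_MODE_NAMES[mode]}"
    if trna is not None and pbs.isoacceptor != trna.isoacceptor:
        return "PBS matched the wrong tRNA"

    poly_iv = (domains[0][1], domains[-1][2])
    orfs = find_orfs(residues, config.eorf_min_codons, config.eorf_require_atg)
    arrays = find_tandem_arrays(residues, config.tandem_max_period, config)
    labelled = []
    for o in orfs:
        label = label_eorf(o, poly_iv)
        if label is not None:
            o.label = label
            labelled.append(o)
    labelled = filter_eorfs(labelled, arrays, config)
    got = sorted(o.label for o in labelled if not o.excluded)
    expected_labels = sorted(e.label for e in spec.eorfs if not e.decoy_tandem)
    if got != expected_labels:
        return f"eORF labels {got} != expected {expected_labels}"
    n_excluded = sum(1 for o in labelled if o.excluded)
    if n_excluded < expected_excluded:
        return "tandem-array decoy ORF not excluded"

    # random filler must not resemble any reference domain: a chance local
    # hit outside the cassette would fake a duplicate domain downstream
    for sub in (residues[: domains[0][1]], residues[domains[-1][2] :]):
        if len(sub) >= 100 and scan_domains(GenomicSequence("chk", sub), refdb, config):
            return "spurious domain similarity in non-coding region"

    manifest = TruthManifest(
        element_id=spec.element_id,
        lineage_path=profile.path,
        superfamily=profile.superfamily,
        chromodomain=profile.chromodomain,
        cage=profile.cage if profile.chromodomain == "CHD" else None,
        arh_position=profile.arh_position,
        five_ltr=(0, spec.ltr_len),
        three_ltr=(d, len(residues)),
        ltr_similarity=pair.similarity,
        tsd_len=spec.tsd_len,
        tsd_seq=tsd,
        pbs_mode=_MODE_NAMES[mode],
        trna_id=trna.id if trna else None,
        isoacceptor=trna.isoacceptor if trna else None,
        domains=domains,
        polyprotein_interval=poly_iv,
        eorf_labels=expected_labels,
        n_excluded_eorfs=n_excluded,
    )
    return seq, manifest


# ---------------------------------------------------------------------------
# corpus generation


_TSD_CYCLE = (5, 4, 5, 6, 5)  # 5 bp dominant, as observed in real elements
_SIM_CYCLE = (97.0, 98.0, 96.5, 99.0, 100.0)


def make_corpus(
    n: int,
    lineage_mix: dict[str, float] | None = None,
    seed: int = 0,
    refdb: ReferenceDomainDB | None = None,
    trnas: TRNALibrary | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[GenomicSequence], list[TruthManifest], ReferenceDomainDB, TRNALibrary]:
    """Reproducible stratified corpus.

    Lineages follow lineage_mix (largest-remainder allocation, interleaved)
    or cycle through the full roster; TSD lengths and LTR similarities cycle
    through fixed schedules; every 11th element gets PBS mode none and every
    7th full-tRNA element a fuzzy PBS, so all PBS modes appear; Ogre
    elements additionally carry a tandem-array decoy ORF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if refdb is None:
        refdb = make_toy_refdb(seed=seed)
    if trnas is None:
        trnas = make_toy_trnas(seed=seed)
    available = sorted({refdb.lineage_table[e.element_name] for e in refdb.entries})
    roster = [p for p in ROSTER if p.path in available]
    if lineage_mix is None:
        order = [roster[i % len(roster)].short for i in range(n)]
    else:
        unknown = set(lineage_mix) - {p.short for p in roster}
        if unknown:
            raise ValueError(f"lineage_mix references unavailable lineages: {sorted(unknown)}")
        quotas = {k: n * v for k, v in lineage_mix.items()}
        counts = {k: int(q) for k, q in quotas.items()}
        short = n - sum(counts.values())
        for k in sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))[:short]:
            counts[k] += 1
        order = []
        pools = {k: counts[k] for k in sorted(counts)}
        while len(order) < n:
            for k in sorted(pools):
                if pools[k] > 0:
                    order.append(k)
                    pools[k] -= 1

    elements, manifests = [], []
    for i, short in enumerate(order):
        profile = PROFILE_BY_SHORT[short]
        pbs_mode = "profile"
        if i % 11 == 10:
            pbs_mode = "none"
        elif i % 7 == 6 and profile.pbs_mode == "full":
            pbs_mode = "fuzzy"
        eorfs = []
        if profile.eorf_label is not None:
            eorfs.append(EORFSpec(profile.eorf_label))
        if short == "Ogre":
            eorfs.append(EORFSpec("eORF-3'F", decoy_tandem=True))
        spec = ElementSpec(
            element_id=f"elem_{i:04d}_{short}",
            lineage=short,
            pbs_mode=pbs_mode,
            eorfs=tuple(eorfs),
            tsd_len=_TSD_CYCLE[i % len(_TSD_CYCLE)],
            target_ltr_similarity=_SIM_CYCLE[i % len(_SIM_CYCLE)],
            seed=(seed * 69061 + i * 181081) % (2**31),
        )
        seq, manifest = build_element(spec, refdb, trnas, config)
        elements.append(seq)
        manifests.append(manifest)
    return elements, manifests, refdb, trnas
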