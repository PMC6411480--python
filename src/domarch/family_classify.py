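"""Rule-based classification of PDZ-positive proteins into 12 families.

Eight protease families (HtrA, Ctp, RseP, APN, Lon, SpoIVB, AP, ZEP) and
four nonprotease families (GspC, Fe-S oxidoreductase, Haem-binding uptake,
ComP) are recognized from the non-PDZ domains accompanying the PDZ domain,
with conserved sequence motifs (HExGH / NxxPxxxLDG for RseP, CxxxCxxC for
the Fe-S oxidoreductases) as corroboration when sequences are available.
Architectures matching no signature are left Unclassified.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .architecture import ProteinArchitecture
from .io_formats import GenomeMetadata, Kingdom

__all__ = [
    "Family",
    "UNCLASSIFIED",
    "PROTEASE_FAMILIES",
    "Region",
    "MotifPattern",
    "FamilySignature",
    "FamilyAssignment",
    "DEFAULT_SYNONYMS",
    "default_signatures",
    "signatures_to_yaml",
    "signatures_from_yaml",
    "match_motif",
    "classify_protein",
    "classify_cohort",
    "summarize_families",
    "FamilyMatrix",
    "protease_fraction",
    "write_assignments",
    "read_assignments",
]


class Family(enum.Enum):
    HTRA = "HTRA"
    CTP = "CTP"
    RSEP = "RSEP"
    APN = "APN"
    LON = "LON"
    SPOIVB = "SPOIVB"
    AP = "AP"
    ZEP = "ZEP"
    GSPC = "GSPC"
    FESO = "FESO"
    HAEM = "HAEM"
    COMP = "COMP"


UNCLASSIFIED = "UNCLASSIFIED"

#: The eight families combining PDZ with a protease domain.
PROTEASE_FAMILIES = frozenset(
    {Family.HTRA, Family.CTP, Family.RSEP, Family.APN, Family.LON,
     Family.SPOIVB, Family.AP, Family.ZEP}
)


class Region(enum.Enum):
    ANY = "ANY"
    N_TERMINAL_HALF = "N_TERMINAL_HALF"
    C_TERMINAL_HALF = "C_TERMINAL_HALF"


_AA = "ACDEFGHIKLMNPQRSTVWY"
_PATTERN_ALPHABET = frozenset(_AA + "x")


@dataclass(frozen=True)
class MotifPattern:
    """A short conserved-motif pattern; ``x`` matches any residue."""

    name: str
    pattern: str
    region: Region = Region.ANY

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"motif {self.name}: pattern must be at least 3 residues")
        bad = set(self.pattern) - _PATTERN_ALPHABET
        if bad:
            raise ValueError(f"motif {self.name}: invalid pattern characters {sorted(bad)}")


@dataclass(frozen=True)
class FamilySignature:
    """Domain-architecture rule for one family.

    ``required`` is a conjunction of alternative sets: each inner set must be
    matched by at least one non-PDZ domain of the architecture.  ``motifs``
    corroborate; when ``motifs_mandatory`` and a sequence is available, all
    motifs must match.  ``pdz_n_terminal_of`` optionally demands the PDZ
    domain precede the named domain along the sequence.
    """

    family_id: Family
    required: tuple[frozenset[str], ...]
    optional: frozenset[str] = frozenset()
    motifs: tuple[MotifPattern, ...] = ()
    motifs_mandatory: bool = False
    pdz_n_terminal_of: str | None = None

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError(f"{self.family_id}: signature needs at least one required group")


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family_id: Family | str  # Family or UNCLASSIFIED
    matched_domains: tuple[str, ...] = ()
    matched_motifs: tuple[str, ...] = ()
    confidence_note: str = ""

    @property
    def is_classified(self) -> bool:
        return self.family_id != UNCLASSIFIED


#: Domain-id synonyms; Pfam names/accessions drift across releases.
DEFAULT_SYNONYMS: dict[str, str] = {
    "PF00089": "Trypsin",
    "Peptidase_S1": "Trypsin",
    "PF03572": "Peptidase_S41",
    "PF02163": "Peptidase_M50",
    "PF05299": "Peptidase_M61",
    "PF05362": "Lon_C",
    "PF05579": "Peptidase_S55",
    "Asp": "Asp_protease",
    "PF13975": "Asp_protease",
    "PF04389": "Peptidase_M28",
    "Pilus_Pil": "Pilus_P",
    "T2SSC": "Pilus_P",
    "PF04074": "Radical_SAM",  # placeholder accession synonym
    "Haem_bd": "ChaN",
    "Haem_binding_uptake": "ChaN",
    "PG_b": "PG_binding_1",
    "Tr_C1": "Tricorn_C1",
    "Tr_PDZ": "Tricorn_PDZ",
    "PS41": "Peptidase_S41",
    "PM50": "Peptidase_M50",
    "PM61": "Peptidase_M61",
    "PS55": "Peptidase_S55",
    "PM28": "Peptidase_M28",
    "Asp_prt": "Asp_protease",
}


def canonical_domain_id(domain_id: str, synonyms: Mapping[str, str] | None = None) -> str:
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    return table.get(domain_id, domain_id)


# Motifs of the RseP intramembrane metalloproteases: a zinc-binding HExGH near
# the N-terminus and an NxxPxxxLDG motif near the C-terminus.
RSEP_MOTIF_N = MotifPattern("HExGH", "HExGH", Region.N_TERMINAL_HALF)
RSEP_MOTIF_C = MotifPattern("NxxPxxxLDG", "NxxPxxxLDG", Region.C_TERMINAL_HALF)
# Iron-sulfur cluster motif of the radical SAM domain.
FESO_MOTIF = MotifPattern("CxxxCxxC", "CxxxCxxC", Region.ANY)


def default_signatures() -> list[FamilySignature]:
    """The 12 family signatures, in fixed precedence order.

    Precedence (HtrA first, ComP last) doubles as the tie-break when an
    architecture satisfies more than one signature.
    """
    return [
        FamilySignature(Family.HTRA, required=(frozenset({"Trypsin"}),)),
        FamilySignature(
            Family.CTP,
            required=(frozenset({"Peptidase_S41"}),),
            optional=frozenset({"DUF3340", "PG_binding_1", "Tricorn", "Tricorn_C1", "PD40"}),
        ),
        FamilySignature(
            Family.RSEP,
            required=(frozenset({"Peptidase_M50"}),),
            motifs=(RSEP_MOTIF_N, RSEP_MOTIF_C),
            motifs_mandatory=True,
        ),
        FamilySignature(Family.APN, required=(frozenset({"Peptidase_M61"}),)),
        FamilySignature(Family.LON, required=(frozenset({"Lon_C"}),)),
        FamilySignature(Family.SPOIVB, required=(frozenset({"Peptidase_S55"}),)),
        FamilySignature(Family.AP, required=(frozenset({"Asp_protease"}),)),
        FamilySignature(Family.ZEP, required=(frozenset({"Peptidase_M28"}),)),
        FamilySignature(Family.GSPC, required=(frozenset({"Pilus_P"}),)),
        FamilySignature(
            Family.FESO,
            required=(frozenset({"Radical_SAM"}),),
            motifs=(FESO_MOTIF,),
            motifs_mandatory=True,
            pdz_n_terminal_of="Radical_SAM",
        ),
        FamilySignature(Family.HAEM, required=(frozenset({"ChaN"}),)),
        FamilySignature(
            Family.COMP,
            required=(frozenset({"HisKA_3"}), frozenset({"HATPase_c"})),
        ),
    ]


def signatures_to_yaml(signatures: Sequence[FamilySignature], path: str | Path) -> None:
    """Persist signatures as an editable structured config file."""
    data = [
        {
            "family": s.family_id.value,
            "required": [sorted(group) for group in s.required],
            "optional": sorted(s.optional),
            "motifs": [
                {"name": m.name, "pattern": m.pattern, "region": m.region.value}
                for m in s.motifs
            ],
            "motifs_mandatory": s.motifs_mandatory,
            "pdz_n_terminal_of": s.pdz_n_terminal_of,
        }
        for s in signatures
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def signatures_from_yaml(path: str | Path) -> list[FamilySignature]:
    data = yaml.safe_load(Path(path).read_text())
    out = []
    for rec in data:
        out.append(
            FamilySignature(
                family_id=Family(rec["family"]),
                required=tuple(frozenset(g) for g in rec["required"]),
                optional=frozenset(rec.get("optional", ())),
                motifs=tuple(
                    MotifPattern(m["name"], m["pattern"], Region(m["region"]))
                    for m in rec.get("motifs", ())
                ),
                motifs_mandatory=rec.get("motifs_mandatory", False),
                pdz_n_terminal_of=rec.get("pdz_n_terminal_of"),
            )
        )
    return out


def match_motif(sequence: str, pattern: MotifPattern) -> list[int]:
    """All 1-based start positions where the pattern matches the sequence.

    ``x`` matches any residue; other pattern letters must match exactly
    (case-insensitive).  A region constraint restricts matches to lie fully
    within the stated half of the sequence.  Overlapping matches are all
    reported.
    """
    seq = sequence.upper()
    regex = re.compile("(?=(" + pattern.pattern.upper().replace("X", ".") + "))")
    positions = [m.start() + 1 for m in regex.finditer(seq)]
    if pattern.region is Region.ANY:
        return positions
    half = len(seq) // 2
    plen = len(pattern.pattern)
    if pattern.region is Region.N_TERMINAL_HALF:
        # match must end within the first half (rounded up)
        bound = (len(seq) + 1) // 2
        return [p for p in positions if p + plen - 1 <= bound]
    return [p for p in positions if p > half]


def _signature_satisfied(
    sig: FamilySignature,
    arch: ProteinArchitecture,
    sequence: str | None,
    synonyms: Mapping[str, str] | None,
) -> FamilyAssignment | None:
    canon_ids = {canonical_domain_id(d, synonyms) for d in arch.non_pdz_domain_ids}
    matched: list[str] = []
    for group in sig.required:
        found = sorted(canon_ids & group)
        if not found:
            return None
        matched.extend(found)
    if sig.pdz_n_terminal_of is not None:
        target = canonical_domain_id(sig.pdz_n_terminal_of, synonyms)
        pdz_starts = [d.start for d in arch.domains if d.is_pdz]
        target_starts = [
            d.start
            for d in arch.domains
            if canonical_domain_id(d.domain_id, synonyms) == target
        ]
        if not pdz_starts or not target_starts or min(pdz_starts) >= min(target_starts):
            return None
    matched.extend(sorted(canon_ids & sig.optional))
    matched_motifs: list[str] = []
    note = ""
    if sig.motifs:
        if sequence is None:
            note = "motif unchecked"
        else:
            for motif in sig.motifs:
                if match_motif(sequence, motif):
                    matched_motifs.append(motif.name)
            if sig.motifs_mandatory and len(matched_motifs) < len(sig.motifs):
                return None
    return FamilyAssignment(
        protein_id=arch.protein_id,
        family_id=sig.family_id,
        matched_domains=tuple(matched),
        matched_motifs=tuple(matched_motifs),
        confidence_note=note,
    )


def classify_protein(
    arch: ProteinArchitecture,
    sequence: str | None = None,
    signatures: Sequence[FamilySignature] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> FamilyAssignment:
    """Assign a PDZ-positive architecture to the first satisfied signature.

    Signatures are evaluated in precedence order; domain evidence alone
    suffices when no sequence is given (motif checks then carry a
    "motif unchecked" note).  With a sequence, mandatory motifs must match.
    """
    if not arch.has_pdz:
        raise ValueError(f"{arch.protein_id}: classification requires a PDZ-positive architecture")
    for sig in signatures or default_signatures():
        assignment = _signature_satisfied(sig, arch, sequence, synonyms)
        if assignment is not None:
            return assignment
    return FamilyAssignment(
        protein_id=arch.protein_id,
        family_id=UNCLASSIFIED,
        confidence_note="no signature satisfied; possibly divergent or rare architecture",
    )


def classify_cohort(
    architectures: Mapping[str, ProteinArchitecture],
    sequences: Mapping[str, str] | None = None,
    signatures: Sequence[FamilySignature] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> dict[str, FamilyAssignment]:
    sigs = list(signatures or default_signatures())
    return {
        pid: classify_protein(
            architectures[pid],
            (sequences or {}).get(pid),
            sigs,
            synonyms,
        )
        for pid in sorted(architectures)
    }


# ---------------------------------------------------------------------------
# Table-1-style family x taxon summaries
# ---------------------------------------------------------------------------


@dataclass
class FamilyMatrix:
    """Family-by-phylum member/organism counts, with kingdom totals.

    Both frames are indexed by (kingdom, phylum) — phylum ``"ALL"`` rows are
    kingdom totals — with one column per family.  A cell holds the member
    count (``members``) and the number of organisms with at least one member
    (``organisms``).
    """

    members: pd.DataFrame
    organisms: pd.DataFrame

    def to_table1(self) -> pd.DataFrame:
        """Cells formatted ``members/organisms`` as in the survey table."""
        out = self.members.astype(str).copy()
        for col in out.columns:
            for idx in out.index:
                m = self.members.loc[idx, col]
                o = self.organisms.loc[idx, col]
                out.loc[idx, col] = f"{m}/{o}" if m else ""
        return out


def summarize_families(
    assignments: Iterable[FamilyAssignment],
    metadata: Sequence[GenomeMetadata],
    protein_to_genome: Mapping[str, str],
    phylum_buckets: Mapping[str, str] | None = None,
) -> FamilyMatrix:
    """Build the family-by-phylum member/organism count matrix.

    ``phylum_buckets`` optionally maps rare phyla to aggregate rows (e.g.
    "Other bacteria"); unmapped phyla keep their own row.  Proteins mapping
    to genomes absent from ``metadata`` raise with the offending ids.
    """
    assignments = list(assignments)
    meta_by_taxon = {m.taxon_id: m for m in metadata}
    orphans = sorted(
        {
            a.protein_id
            for a in assignments
            if protein_to_genome.get(a.protein_id) not in meta_by_taxon
        }
    )
    if orphans:
        raise ValueError(f"proteins mapped to no known genome: {orphans}")

    families = [f.value for f in Family]
    rows: dict[tuple[str, str], dict[str, set | int]] = {}

    def bucket(m: GenomeMetadata) -> str:
        if phylum_buckets and m.phylum in phylum_buckets:
            return phylum_buckets[m.phylum]
        return m.phylum

    member_counts: dict[tuple[str, str, str], int] = {}
    member_orgs: dict[tuple[str, str, str], set[str]] = {}
    for a in assignments:
        if not a.is_classified:
            continue
        meta = meta_by_taxon[protein_to_genome[a.protein_id]]
        fam = a.family_id.value
        for phylum in (bucket(meta), "ALL"):
            key = (meta.kingdom.value, phylum, fam)
            member_counts[key] = member_counts.get(key, 0) + 1
            member_orgs.setdefault(key, set()).add(meta.taxon_id)

    index = sorted({(k, p) for (k, p, _f) in member_counts})
    members = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(index or [("NONE", "ALL")],
                                                              names=["kingdom", "phylum"]),
                           columns=families, dtype=int)
    organisms = members.copy()
    for (k, p, f), count in member_counts.items():
        members.loc[(k, p), f] = count
        organisms.loc[(k, p), f] = len(member_orgs[(k, p, f)])
    return FamilyMatrix(members=members, organisms=organisms)


def protease_fraction(assignments: Iterable[FamilyAssignment]) -> float:
    """Fraction of classified proteins whose family combines PDZ with a
    protease domain (HtrA, Ctp, RseP, APN, Lon, SpoIVB, AP, ZEP)."""
    classified = [a for a in assignments if a.is_classified]
    if not classified:
        raise ValueError("no classified proteins")
    n_protease = sum(1 for a in classified if a.family_id in PROTEASE_FAMILIES)
    return n_protease / len(classified)


def write_assignments(assignments: Mapping[str, FamilyAssignment], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\tfamily\tmatched_domains\tmatched_motifs\tconfidence_note\n")
        for pid in sorted(assignments):
            a = assignments[pid]
            fam = a.family_id.value if isinstance(a.family_id, Family) else a.family_id
            fh.write(
                f"{pid}\t{fam}\t{','.join(a.matched_domains)}\t"
                f"{','.join(a.matched_motifs)}\t{a.confidence_note}\n"
            )


def read_assignments(path: str | Path) -> dict[str, FamilyAssignment]:
    out: dict[str, FamilyAssignment] = {}
    with Path(path).open() as fh:
        fh.readline()
        for raw in fh:
            if not raw.strip():
                continue
            pid, fam, doms, motifs, note = raw.rstrip("\n").split("\t")
            out[pid] = FamilyAssignment(
                protein_id=pid,
                family_id=UNCLASSIFIED if fam == UNCLASSIFIED else Family(fam),
                matched_domains=tuple(d for d in doms.split(",") if d),
                matched_motifs=tuple(m for m in motifs.split(",") if m),
                confidence_note=note,
            )
    return out
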