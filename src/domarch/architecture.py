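"""Per-protein domain architectures from raw HMM hits.

The pipeline mirrors the two-pass survey design: a PDZ-HMM *search* pass
(sequence E-value <= 0.01, hit E-value <= 0.03) selects candidate proteins,
and a whole-database *scan* pass (0.01 / 0.01) annotates all their domains.
Hits passing the thresholds are merged across Pfam and Superfamily, reduced
to a non-overlapping set by maximum total bit score, and ordered along the
sequence.  Multiple PDZ hits within one protein count as tandem repeats.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, Source

__all__ = [
    "PDZ_DOMAIN_IDS",
    "CANONICAL_PDZ_IDS",
    "ThresholdPolicy",
    "PdzFlavor",
    "DomainSegment",
    "ProteinArchitecture",
    "filter_hits",
    "resolve_overlaps",
    "merge_cross_db",
    "build_architecture",
    "build_proteome_architectures",
    "write_architectures",
    "read_architectures",
]

#: Identifiers recognized as PDZ domains: the Pfam families/accessions and
#: the Superfamily PDZ accession.
PDZ_DOMAIN_IDS = frozenset(
    {"PDZ", "PDZ_1", "PDZ_2", "PF00595", "PF13180", "PF12812", "50156"}
)

#: The metazoan canonical Pfam family.
CANONICAL_PDZ_IDS = frozenset({"PDZ", "PF00595"})


class Mode(enum.Enum):
    SEARCH = "SEARCH"
    SCAN = "SCAN"


@dataclass(frozen=True)
class ThresholdPolicy:
    """Inclusion thresholds for one HMMER pass.

    ``seq_evalue_max`` bounds the full-sequence E-value, ``dom_evalue_max``
    the per-hit (independent) E-value; both bounds are inclusive.
    """

    mode: Mode
    seq_evalue_max: float
    dom_evalue_max: float

    def __post_init__(self) -> None:
        if self.seq_evalue_max <= 0 or self.dom_evalue_max <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def search(cls) -> "ThresholdPolicy":
        return cls(Mode.SEARCH, 0.01, 0.03)

    @classmethod
    def scan(cls) -> "ThresholdPolicy":
        return cls(Mode.SCAN, 0.01, 0.01)

    def keeps(self, hit: DomainHit) -> bool:
        return hit.seq_evalue <= self.seq_evalue_max and hit.dom_evalue <= self.dom_evalue_max


class PdzFlavor(enum.Enum):
    CANONICAL = "CANONICAL"
    NONCANONICAL = "NONCANONICAL"
    MIXED = "MIXED"
    NONE = "NONE"


@dataclass(frozen=True)
class DomainSegment:
    domain_id: str
    source: Source
    start: int
    end: int
    bit_score: float
    corroborated: bool = False

    @property
    def is_pdz(self) -> bool:
        return self.domain_id in PDZ_DOMAIN_IDS


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered, non-overlapping domain string of one protein."""

    protein_id: str
    domains: tuple[DomainSegment, ...]
    tandem_pdz_count: int
    has_pdz: bool
    pdz_flavor: PdzFlavor

    @property
    def architecture_string(self) -> str:
        return "-".join(d.domain_id for d in self.domains)

    @property
    def non_pdz_domain_ids(self) -> tuple[str, ...]:
        return tuple(d.domain_id for d in self.domains if not d.is_pdz)


def filter_hits(hits: Iterable[DomainHit], policy: ThresholdPolicy) -> list[DomainHit]:
    """Keep hits passing both inclusive E-value thresholds; order preserved."""
    return [h for h in hits if policy.keeps(h)]


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _compatible(a: DomainHit, b: DomainHit, tolerance: float) -> bool:
    return _overlap_len(a, b) <= tolerance * min(a.length, b.length)


def resolve_overlaps(
    hits: Sequence[DomainHit],
    overlap_tolerance: float = 0.2,
    exact_limit: int = 16,
) -> list[DomainHit]:
    """Reduce one protein's hits to a non-overlapping set of maximum total
    bit score.

    Two hits are considered compatible when their overlap is at most
    ``overlap_tolerance`` of the shorter hit's length — a small tolerance
    preserves adjacent tandem repeats while removing duplicate calls on the
    same region.  For up to ``exact_limit`` hits the maximum-score subset is
    found by pruned exhaustive search (hit counts per protein are small in
    practice); beyond that a greedy descending-score pass is used.  Ties on
    total score prefer more domains, then the lexicographically smallest
    (start, end, domain_id) tuple sequence, making the result deterministic.
    The result is sorted by start.
    """
    hits = list(hits)
    if len(hits) <= 1:
        return sorted(hits, key=lambda h: (h.start, h.end, h.domain_id))
    order = sorted(
        range(len(hits)),
        key=lambda i: (-hits[i].bit_score, hits[i].start, hits[i].domain_id),
    )
    if len(hits) > exact_limit:
        kept: list[DomainHit] = []
        for i in order:
            if all(_compatible(hits[i], k, overlap_tolerance) for k in kept):
                kept.append(hits[i])
        return sorted(kept, key=lambda h: (h.start, h.end, h.domain_id))

    # Exact: depth-first over inclusion decisions in descending-score order,
    # pruning branches whose optimistic remaining score cannot beat the best.
    suffix = [0.0] * (len(order) + 1)
    for pos in range(len(order) - 1, -1, -1):
        suffix[pos] = suffix[pos + 1] + hits[order[pos]].bit_score

    best_key: tuple | None = None
    best_sel: list[int] = []

    def sel_key(sel: list[int]) -> tuple:
        score = sum(hits[i].bit_score for i in sel)
        coords = tuple(sorted((hits[i].start, hits[i].end, hits[i].domain_id) for i in sel))
        # maximize score, then count; minimize coords lexicographically
        return (-score, -len(sel), coords)

    def dfs(pos: int, sel: list[int], score: float) -> None:
        nonlocal best_key, best_sel
        if best_key is not None and score + suffix[pos] < -best_key[0]:
            return
        if pos == len(order):
            key = sel_key(sel)
            if best_key is None or key < best_key:
                best_key, best_sel = key, list(sel)
            return
        i = order[pos]
        if all(_compatible(hits[i], hits[j], overlap_tolerance) for j in sel):
            sel.append(i)
            dfs(pos + 1, sel, score + hits[i].bit_score)
            sel.pop()
        dfs(pos + 1, sel, score)

    dfs(0, [], 0.0)
    return sorted((hits[i] for i in best_sel), key=lambda h: (h.start, h.end, h.domain_id))


def merge_cross_db(
    pfam: Sequence[DomainHit],
    superfam: Sequence[DomainHit],
    absorb_threshold: float = 0.5,
) -> list[DomainHit]:
    """Merge threshold-filtered Pfam and Superfamily hits for one protein.

    Pfam is the reference: a Superfamily hit overlapping some Pfam hit by at
    least ``absorb_threshold`` of either extent corroborates it (the Pfam
    record is kept, flagged) and is absorbed, so a nested Superfamily PDZ
    never double-counts a tandem repeat.  Superfamily hits with no such
    Pfam counterpart survive as independent domains — this is how PDZ
    domains detected only by the Superfamily model are retained.
    """
    merged = list(pfam)
    for sf in superfam:
        absorbed = False
        for i, pf in enumerate(merged):
            if pf.source is not Source.PFAM:
                continue
            ov = _overlap_len(sf, pf)
            if ov >= absorb_threshold * sf.length or ov >= absorb_threshold * pf.length:
                merged[i] = replace(pf, corroborated=True)
                absorbed = True
                break
        if not absorbed:
            merged.append(sf)
    return sorted(merged, key=lambda h: (h.start, h.end, h.domain_id))


def build_architecture(protein_id: str, hits: Sequence[DomainHit]) -> ProteinArchitecture:
    """Assemble the ordered architecture from filtered, merged, resolved hits.

    ``tandem_pdz_count`` is the number of kept PDZ hits; two or more count
    as tandem repeats of the domain.  The flavor is CANONICAL when every
    PDZ hit is the metazoan canonical Pfam family, NONCANONICAL when none
    is, MIXED otherwise.
    """
    segments = tuple(
        DomainSegment(
            domain_id=h.domain_id,
            source=h.source,
            start=h.start,
            end=h.end,
            bit_score=h.bit_score,
            corroborated=h.corroborated,
        )
        for h in sorted(hits, key=lambda h: (h.start, h.end, h.domain_id))
    )
    pdz = [s for s in segments if s.is_pdz]
    if not pdz:
        flavor = PdzFlavor.NONE
    else:
        canonical = [s.domain_id in CANONICAL_PDZ_IDS and s.source is Source.PFAM for s in pdz]
        if all(canonical):
            flavor = PdzFlavor.CANONICAL
        elif not any(canonical):
            flavor = PdzFlavor.NONCANONICAL
        else:
            flavor = PdzFlavor.MIXED
    return ProteinArchitecture(
        protein_id=protein_id,
        domains=segments,
        tandem_pdz_count=len(pdz),
        has_pdz=bool(pdz),
        pdz_flavor=flavor,
    )


def build_proteome_architectures(
    search_hits: Sequence[DomainHit],
    scan_hits: Sequence[DomainHit],
    superfamily_hits: Sequence[DomainHit],
    search_policy: ThresholdPolicy | None = None,
    scan_policy: ThresholdPolicy | None = None,
    overlap_tolerance: float = 0.2,
    absorb_threshold: float = 0.5,
) -> dict[str, ProteinArchitecture]:
    """Full per-proteome pass: select PDZ-positive proteins from the search
    table, then annotate each from the scan + Superfamily tables.

    Returns architectures keyed by protein id, for proteins whose final
    resolved architecture retains at least one PDZ domain.
    """
    search_policy = search_policy or ThresholdPolicy.search()
    scan_policy = scan_policy or ThresholdPolicy.scan()

    candidates = {
        h.protein_id
        for h in filter_hits(search_hits, search_policy)
        if h.domain_id in PDZ_DOMAIN_IDS
    }
    scan_by_prot: dict[str, list[DomainHit]] = {}
    for h in filter_hits(scan_hits, scan_policy):
        scan_by_prot.setdefault(h.protein_id, []).append(h)
    sf_by_prot: dict[str, list[DomainHit]] = {}
    for h in filter_hits(superfamily_hits, scan_policy):
        sf_by_prot.setdefault(h.protein_id, []).append(h)

    out: dict[str, ProteinArchitecture] = {}
    for pid in sorted(candidates):
        merged = merge_cross_db(
            scan_by_prot.get(pid, []), sf_by_prot.get(pid, []), absorb_threshold
        )
        resolved = resolve_overlaps(merged, overlap_tolerance)
        arch = build_architecture(pid, resolved)
        if arch.has_pdz:
            out[pid] = arch
    return out


# ---------------------------------------------------------------------------
# TSV persistence of architectures (pipeline stage artifact)
# ---------------------------------------------------------------------------


def write_architectures(
    architectures: Mapping[str, ProteinArchitecture],
    protein_to_genome: Mapping[str, str],
    path: str | Path,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\ttaxon_id\tdomains\ttandem_pdz_count\tpdz_flavor\n")
        for pid in sorted(architectures):
            arch = architectures[pid]
            dom = ";".join(
                f"{d.domain_id}:{d.source.value}:{d.start}:{d.end}:{d.bit_score:.6g}:{int(d.corroborated)}"
                for d in arch.domains
            )
            fh.write(
                f"{pid}\t{protein_to_genome[pid]}\t{dom}\t{arch.tandem_pdz_count}\t{arch.pdz_flavor.value}\n"
            )


def read_architectures(path: str | Path) -> tuple[dict[str, ProteinArchitecture], dict[str, str]]:
    path = Path(path)
    archs: dict[str, ProteinArchitecture] = {}
    mapping: dict[str, str] = {}
    with path.open() as fh:
        fh.readline()
        for raw in fh:
            if not raw.strip():
                continue
            pid, taxon, dom_s, _count, _flavor = raw.rstrip("\n").split("\t")
            segments = []
            if dom_s:
                for part in dom_s.split(";"):
                    did, src, start, end, score, corr = part.rsplit(":", 5)
                    segments.append(
                        DomainHit(
                            protein_id=pid,
                            domain_id=did,
                            source=Source(src),
                            seq_evalue=0.0,
                            dom_evalue=0.0,
                            start=int(start),
                            end=int(end),
                            bit_score=float(score),
                            corroborated=bool(int(corr)),
                        )
                    )
            archs[pid] = build_architecture(pid, segments)
            mapping[pid] = taxon
    return archs, mapping
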