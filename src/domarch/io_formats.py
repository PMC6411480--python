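"""Readers and writers for the external formats the survey pipeline touches.

Every downstream module consumes only the domain types defined here:
HMM per-domain hit tables (HMMER3 ``domtblout`` dialect), Superfamily-style
assignment tables, NCBI PTT gene annotation tables, genome phenotype metadata
tables (emulating the retired NCBI lproks files), per-protein subcellular
localization tables (emulating Phobius category output), and iTOL multi-value
bar annotation files.

All coordinates are 1-based inclusive residue/nucleotide positions, the
convention shared by HMMER and PTT.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "Strand",
    "Kingdom",
    "Gram",
    "Habitat",
    "Oxygen",
    "Localization",
    "DomainHit",
    "GeneRecord",
    "GenomeMetadata",
    "LocalizationRecord",
    "FormatError",
    "read_domtblout",
    "write_domtblout",
    "read_superfamily_table",
    "write_superfamily_table",
    "read_ptt",
    "write_ptt",
    "read_metadata",
    "write_metadata",
    "read_localization",
    "write_localization",
    "read_fasta",
    "write_fasta",
    "write_itol_bars",
]


class FormatError(ValueError):
    """A malformed input row; message names the file and line number."""


class Source(enum.Enum):
    PFAM = "PFAM"
    SUPERFAMILY = "SUPERFAMILY"


class Strand(enum.Enum):
    PLUS = "+"
    MINUS = "-"


class Kingdom(enum.Enum):
    EUBACTERIA = "EUBACTERIA"
    ARCHAEA = "ARCHAEA"
    FUNGI = "FUNGI"


class Gram(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NA = "NA"


class Habitat(enum.Enum):
    AQUATIC = "AQUATIC"
    TERRESTRIAL = "TERRESTRIAL"
    MULTIPLE = "MULTIPLE"
    HOST_ASSOCIATED = "HOST_ASSOCIATED"
    SPECIALIZED = "SPECIALIZED"
    NA = "NA"


class Oxygen(enum.Enum):
    AEROBIC = "AEROBIC"
    ANAEROBIC = "ANAEROBIC"
    FACULTATIVE = "FACULTATIVE"
    NA = "NA"


class Localization(enum.Enum):
    """Phobius-style category: transmembrane helix, signal peptide, both,
    cytoplasmic, or no information available."""

    TM = "TM"
    SP = "SP"
    TMSP = "TMSP"
    CYT = "CYT"
    NAN = "NAN"


@dataclass(frozen=True)
class DomainHit:
    """One HMM match on one protein.

    ``start``/``end`` are 1-based inclusive envelope coordinates.
    Superfamily assignment rows carry a single E-value; it is stored in both
    ``seq_evalue`` and ``dom_evalue`` so one threshold policy applies
    uniformly across sources.
    """

    protein_id: str
    domain_id: str
    source: Source
    seq_evalue: float
    dom_evalue: float
    start: int
    end: int
    bit_score: float
    corroborated: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid hit coordinates {self.start}..{self.end} "
                f"for {self.protein_id}/{self.domain_id}"
            )
        if self.seq_evalue < 0 or self.dom_evalue < 0:
            raise ValueError("E-values must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    """One gene from a PTT annotation table (1-based inclusive coordinates).

    ``start > end`` never encodes strand in PTT (strand has its own column);
    such rows are rejected as malformed.
    """

    replicon_id: str
    start: int
    end: int
    strand: Strand
    locus_tag: str
    gene_name: str = ""
    product: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.locus_tag}: start {self.start} > end {self.end}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeMetadata:
    """Phenotype and taxonomy metadata for one genome (lproks-style)."""

    taxon_id: str
    organism: str
    kingdom: Kingdom
    phylum: str
    gram: Gram
    habitat: Habitat
    oxygen: Oxygen
    genome_size_mb: float

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValueError(f"{self.taxon_id}: genome size must be positive")


@dataclass(frozen=True)
class LocalizationRecord:
    protein_id: str
    category: Localization


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

# Column indices in HMMER3 --domtblout (0-based).  The final "description of
# target" column may contain spaces, hence maxsplit below.
_DTBL_NCOL = 23
_DTBL_SEQ_EVALUE = 6
_DTBL_DOM_IEVALUE = 12
_DTBL_DOM_SCORE = 13
_DTBL_ENV_FROM = 19
_DTBL_ENV_TO = 20


def read_domtblout(path: str | Path, orientation: str = "search") -> list[DomainHit]:
    """Parse a HMMER3 per-domain hit table into :class:`DomainHit` records.

    ``orientation`` follows the tool that wrote the file: ``"search"``
    (hmmsearch; the target column is the protein, the query is the HMM) or
    ``"scan"`` (hmmscan; roles swapped).  Envelope coordinates define the
    domain extent; the independent (i-) E-value is taken as the per-hit
    E-value.  Lines beginning ``#`` are comments.
    """
    if orientation not in ("search", "scan"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split(None, _DTBL_NCOL - 1)
            if len(cols) < _DTBL_NCOL - 1:
                raise FormatError(f"{path}:{lineno}: expected {_DTBL_NCOL} columns, got {len(cols)}")
            target, query = cols[0], cols[3]
            protein_id, domain_id = (target, query) if orientation == "search" else (query, target)
            try:
                seq_ev = float(cols[_DTBL_SEQ_EVALUE])
                dom_ev = float(cols[_DTBL_DOM_IEVALUE])
                score = float(cols[_DTBL_DOM_SCORE])
                start = int(cols[_DTBL_ENV_FROM])
                end = int(cols[_DTBL_ENV_TO])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            try:
                hits.append(
                    DomainHit(
                        protein_id=protein_id,
                        domain_id=domain_id,
                        source=Source.PFAM,
                        seq_evalue=seq_ev,
                        dom_evalue=dom_ev,
                        start=start,
                        end=end,
                        bit_score=score,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_domtblout(hits: Sequence[DomainHit], path: str | Path, orientation: str = "search") -> None:
    """Write hits in the HMMER3 per-domain table dialect (inverse of
    :func:`read_domtblout`; unknown columns are filled with placeholders)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# target name        accession   tlen query name           accession   qlen"
                 "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
                 "  from    to  from    to  acc description of target\n")
        fh.write("#" + "-" * 40 + "\n")
        for h in hits:
            target, query = (
                (h.protein_id, h.domain_id) if orientation == "search" else (h.domain_id, h.protein_id)
            )
            fh.write(
                f"{target} - 0 {query} - 0 {h.seq_evalue:.3g} {h.bit_score:.1f} 0.0 1 1 "
                f"{h.dom_evalue:.3g} {h.dom_evalue:.3g} {h.bit_score:.1f} 0.0 "
                f"{h.start} {h.end} {h.start} {h.end} {h.start} {h.end} 0.90 -\n"
            )


# ---------------------------------------------------------------------------
# Superfamily assignment table
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(\d+)-(\d+)$")


def read_superfamily_table(path: str | Path) -> list[DomainHit]:
    """Parse a Superfamily-style assignment TSV.

    Expected columns (header required): ``protein_id``, ``superfamily_id``,
    ``region`` (``"start-end"``), ``evalue``.  The single E-value is stored
    in both E-value slots of the resulting :class:`DomainHit`.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["protein_id", "superfamily_id", "region", "evalue"]
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        idx = {c: header.index(c) for c in required}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            m = _REGION_RE.match(cols[idx["region"]].strip())
            if m is None:
                raise FormatError(f"{path}:{lineno}: region {cols[idx['region']]!r} is not 'start-end'")
            start, end = int(m.group(1)), int(m.group(2))
            if start > end:
                raise FormatError(f"{path}:{lineno}: region start {start} > end {end}")
            try:
                evalue = float(cols[idx["evalue"]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric E-value {cols[idx['evalue']]!r}") from None
            hits.append(
                DomainHit(
                    protein_id=cols[idx["protein_id"]],
                    domain_id=cols[idx["superfamily_id"]],
                    source=Source.SUPERFAMILY,
                    seq_evalue=evalue,
                    dom_evalue=evalue,
                    start=start,
                    end=end,
                    bit_score=0.0,
                )
            )
    return hits


def write_superfamily_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\tsuperfamily_id\tregion\tevalue\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_id}\t{h.start}-{h.end}\t{h.dom_evalue:.6g}\n")


# ---------------------------------------------------------------------------
# NCBI PTT
# ---------------------------------------------------------------------------


def read_ptt(path: str | Path, replicon_id: str | None = None) -> list[GeneRecord]:
    """Parse an NCBI PTT gene table; records are returned sorted by start.

    The title line and the protein-count line are skipped, as is an optional
    ``Location``-prefixed column-header line.  ``replicon_id`` defaults to
    the file stem.
    """
    path = Path(path)
    if replicon_id is None:
        replicon_id = path.stem
    records: list[GeneRecord] = []
    with path.open() as fh:
        lines = fh.readlines()
    body = lines[2:]
    if body and body[0].startswith("Location"):
        body = body[1:]
    offset = len(lines) - len(body)
    for lineno, raw in enumerate(body, start=offset + 1):
        if not raw.strip():
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
        loc, strand_s, _length, pid, gene, synonym, _code, _cog, product = cols[:9]
        if ".." not in loc:
            raise FormatError(f"{path}:{lineno}: location {loc!r} lacks '..'")
        start_s, end_s = loc.split("..", 1)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric location {loc!r}") from None
        try:
            strand = Strand(strand_s.strip())
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad strand {strand_s!r}") from None
        try:
            records.append(
                GeneRecord(
                    replicon_id=replicon_id,
                    start=start,
                    end=end,
                    strand=strand,
                    locus_tag=synonym if synonym != "-" else "",
                    gene_name=gene if gene != "-" else "",
                    product=product if product != "-" else "",
                    protein_id=pid if pid != "-" else "",
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    records.sort(key=lambda g: (g.start, g.end, g.locus_tag))
    return records


def write_ptt(genes: Sequence[GeneRecord], path: str | Path, title: str = "") -> None:
    """Write genes as a PTT table (three header lines, nine columns)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{title}\n{len(genes)} proteins\n")
        fh.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
        for g in sorted(genes, key=lambda g: (g.start, g.end, g.locus_tag)):
            aa_len = max(1, (g.length_nt - 3) // 3)
            fh.write(
                f"{g.start}..{g.end}\t{g.strand.value}\t{aa_len}\t{g.protein_id or '-'}\t"
                f"{g.gene_name or '-'}\t{g.locus_tag or '-'}\t-\t-\t{g.product or '-'}\n"
            )


# ---------------------------------------------------------------------------
# Metadata / localization tables
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "taxon_id",
    "organism",
    "kingdom",
    "phylum",
    "gram",
    "habitat",
    "oxygen",
    "genome_size_mb",
]


def _norm_token(value: str) -> str:
    return re.sub(r"[^A-Z0-9]+", "_", value.strip().upper()).strip("_")


def _parse_enum(cls, value: str, *, fallback_na: bool, context: str):
    token = _norm_token(value)
    try:
        return cls[token]
    except KeyError:
        if fallback_na and hasattr(cls, "NA"):
            logger.warning("%s: unknown %s value %r mapped to NA", context, cls.__name__, value)
            return cls.NA
        raise FormatError(f"{context}: unknown {cls.__name__} value {value!r}") from None


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read the genome phenotype metadata TSV.

    Enum columns parse case-insensitively; unknown habitat/oxygen/Gram
    strings map to NA with a logged warning (real lproks tables contain
    free-text oddities such as "microaerophilic").
    """
    path = Path(path)
    out: list[GenomeMetadata] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in _META_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        idx = {c: header.index(c) for c in _META_COLUMNS}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            ctx = f"{path}:{lineno}"
            out.append(
                GenomeMetadata(
                    taxon_id=cols[idx["taxon_id"]],
                    organism=cols[idx["organism"]],
                    kingdom=_parse_enum(Kingdom, cols[idx["kingdom"]], fallback_na=False, context=ctx),
                    phylum=cols[idx["phylum"]],
                    gram=_parse_enum(Gram, cols[idx["gram"]], fallback_na=True, context=ctx),
                    habitat=_parse_enum(Habitat, cols[idx["habitat"]], fallback_na=True, context=ctx),
                    oxygen=_parse_enum(Oxygen, cols[idx["oxygen"]], fallback_na=True, context=ctx),
                    genome_size_mb=float(cols[idx["genome_size_mb"]]),
                )
            )
    return out


def write_metadata(records: Sequence[GenomeMetadata], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for m in records:
            fh.write(
                f"{m.taxon_id}\t{m.organism}\t{m.kingdom.value}\t{m.phylum}\t{m.gram.value}\t"
                f"{m.habitat.value}\t{m.oxygen.value}\t{m.genome_size_mb:.6g}\n"
            )


def read_localization(path: str | Path) -> list[LocalizationRecord]:
    """Read a per-protein localization TSV (columns protein_id, category).

    Categories: TM, SP, TMSP, CYT, NaN (no information available).
    """
    path = Path(path)
    out: list[LocalizationRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("protein_id", "category"):
            if col not in header:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        idx = {c: header.index(c) for c in ("protein_id", "category")}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            cat = _parse_enum(Localization, cols[idx["category"]], fallback_na=False,
                              context=f"{path}:{lineno}")
            out.append(LocalizationRecord(protein_id=cols[idx["protein_id"]], category=cat))
    return out


def write_localization(records: Sequence[LocalizationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\tcategory\n")
        for r in records:
            label = "NaN" if r.category is Localization.NAN else r.category.value
            fh.write(f"{r.protein_id}\t{label}\n")


# ---------------------------------------------------------------------------
# FASTA (needed only by motif matching)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by the first word of each header."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in sequences:
            seq = sequences[pid]
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# iTOL multi-value bar annotation
# ---------------------------------------------------------------------------

_ITOL_FIELDS = [Localization.TM, Localization.SP, Localization.TMSP, Localization.CYT]
_ITOL_COLORS = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a"]


def write_itol_bars(profiles: Sequence, path: str | Path) -> None:
    """Write an iTOL multi-value bar dataset: per taxon the counts of PDZ
    proteins in the four known localization categories (TM, SP, TMSP, CYT).

    ``profiles`` are :class:`~domarch.comparative_stats.GenomeProfile`-like
    objects exposing ``metadata.taxon_id`` and ``loc_counts``.
    """
    if not profiles:
        raise ValueError("cannot write iTOL bars for an empty profile list")
    seen: set[str] = set()
    rows: list[str] = []
    for p in profiles:
        taxon = p.metadata.taxon_id
        if taxon in seen:
            raise ValueError(f"duplicate taxon_id {taxon!r}")
        seen.add(taxon)
        counts = [int(p.loc_counts.get(cat, 0)) for cat in _ITOL_FIELDS]
        known_total = sum(
            v for cat, v in p.loc_counts.items() if cat is not Localization.NAN
        )
        if sum(counts) != known_total:
            raise ValueError(
                f"{taxon}: localization counts {counts} do not sum to the known-category total {known_total}"
            )
        rows.append(f"{taxon}," + ",".join(str(c) for c in counts))
    path = Path(path)
    with path.open("w") as fh:
        fh.write("DATASET_MULTIBAR\nSEPARATOR COMMA\nDATASET_LABEL,PDZ protein localization\n")
        fh.write("COLOR,#555555\n")
        fh.write("FIELD_COLORS," + ",".join(_ITOL_COLORS) + "\n")
        fh.write("FIELD_LABELS," + ",".join(c.value for c in _ITOL_FIELDS) + "\n")
        fh.write("DATA\n")
        for row in rows:
            fh.write(row + "\n")
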