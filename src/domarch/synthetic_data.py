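"""Seeded synthetic genome cohorts with planted ground truth.

The generator emulates the statistical structure the survey analysis
assumes: per-genome PDZ gene counts following a negative-binomial rate model
(higher in aerobic, terrestrial and aquatic eubacteria; flat and low in
archaea and fungi), family membership drawn from the 12 signature templates
plus an unclassifiable remainder, tandem PDZ repeats, Phobius-style
localization labels dominated by membrane-targeted categories, codirectional
gene clusters planted next to RseP / Fe-S oxidoreductase / Lon anchors, and
decoy HMM hits above the inclusion thresholds to exercise filtering.

It emits exactly the file formats the readers consume (domtblout dialect,
Superfamily TSV, PTT, metadata/localization TSV, FASTA) plus a ground-truth
manifest, and is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    DomainHit,
    GeneRecord,
    GenomeMetadata,
    Gram,
    Habitat,
    Kingdom,
    Localization,
    LocalizationRecord,
    Oxygen,
    Source,
    Strand,
)
from .comparative_stats import GenomeProfile
from .family_classify import Family, UNCLASSIFIED

__all__ = [
    "CohortConfig",
    "PlantedNeighborhood",
    "TruthManifest",
    "Cohort",
    "simulate",
    "generate_cohort",
    "plant_neighborhood",
    "truth_profiles",
    "DEFAULT_FAMILY_MIX",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Typical Pfam-model lengths (residues) used to lay out planted domains.
DOMAIN_LENGTHS: dict[str, int] = {
    "PDZ": 85,
    "PDZ_2": 90,
    "50156": 95,
    "Trypsin": 220,
    "Peptidase_S41": 200,
    "Peptidase_M50": 210,
    "Peptidase_M61": 250,
    "Lon_C": 200,
    "Peptidase_S55": 230,
    "Asp_protease": 100,
    "Peptidase_M28": 220,
    "Pilus_P": 100,
    "Radical_SAM": 180,
    "ChaN": 130,
    "HisKA_3": 70,
    "HATPase_c": 110,
    "DUF3340": 110,
}

#: Non-PDZ domains planted per family (conjunction; CTP extras are optional).
FAMILY_DOMAINS: dict[Family, list[str]] = {
    Family.HTRA: ["Trypsin"],
    Family.CTP: ["Peptidase_S41"],
    Family.RSEP: ["Peptidase_M50"],
    Family.APN: ["Peptidase_M61"],
    Family.LON: ["Lon_C"],
    Family.SPOIVB: ["Peptidase_S55"],
    Family.AP: ["Asp_protease"],
    Family.ZEP: ["Peptidase_M28"],
    Family.GSPC: ["Pilus_P"],
    Family.FESO: ["Radical_SAM"],
    Family.HAEM: ["ChaN"],
    Family.COMP: ["HisKA_3", "HATPase_c"],
}

#: Families whose planted PDZ hit comes from the Superfamily model only
#: (their Pfam PDZ models miss the highly diverged sequence).
SUPERFAMILY_ONLY_PDZ = frozenset({Family.FESO, Family.GSPC})

#: Vocabulary for planted unclassifiable architectures; never overlaps the
#: signature vocabulary, so these can never complete a family rule.
UNCLASS_VOCAB = ("DUF9101", "DUF9102", "DUF9103", "Big_synth")
#: Decoy domain vocabulary for above-threshold noise hits.
DECOY_VOCAB = ("DecoyA", "DecoyB", "DecoyC", "DecoyD")

#: Family mix derived from the survey's phyletic table, renormalised so
#: protease families make up 88% of classified proteins and 7% of all
#: proteins stay unclassifiable.
_TABLE_WEIGHTS = {
    Family.HTRA: 2902, Family.CTP: 1716, Family.RSEP: 1262, Family.APN: 294,
    Family.LON: 292, Family.GSPC: 182, Family.FESO: 156, Family.SPOIVB: 139,
    Family.AP: 49, Family.COMP: 48, Family.HAEM: 37, Family.ZEP: 29,
}


def _default_family_mix() -> dict:
    protease = {f: w for f, w in _TABLE_WEIGHTS.items()
                if f in (Family.HTRA, Family.CTP, Family.RSEP, Family.APN,
                         Family.LON, Family.SPOIVB, Family.AP, Family.ZEP)}
    nonprot = {f: w for f, w in _TABLE_WEIGHTS.items() if f not in protease}
    p_sum, n_sum = sum(protease.values()), sum(nonprot.values())
    classified = 0.93
    mix = {f: classified * 0.88 * w / p_sum for f, w in protease.items()}
    mix.update({f: classified * 0.12 * w / n_sum for f, w in nonprot.items()})
    mix[UNCLASSIFIED] = 0.07
    return mix


DEFAULT_FAMILY_MIX = _default_family_mix()


@dataclass(frozen=True)
class PlantedNeighborhood:
    """A codirectional gene run planted next to anchors of one family."""

    anchor_family: Family
    neighbor_names: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.neighbor_names):
            raise ValueError("need one gap per neighbor")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be non-negative")


DEFAULT_NEIGHBORHOODS = (
    PlantedNeighborhood(Family.RSEP, ("cdsA", "uppS", "dxr", "frr", "rpsB"), (20, 15, 30, 10, 25)),
    PlantedNeighborhood(Family.FESO, ("engA", "gpsA"), (12, 40)),
    PlantedNeighborhood(Family.LON, ("coaD", "rsmD"), (18, 22)),
)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the surveyed conditions: ~400 PDZ proteins across 60
    genomes dominated by eubacteria; negative-binomial per-genome counts
    with aerobic genomes richer than anaerobic ones and terrestrial/aquatic
    habitats richer than host-associated/specialized ones; 7% of proteins
    unclassifiable and 88% of the classified carrying a protease domain;
    ~27% of PDZ proteins with a second (tandem) PDZ hit so domains outnumber
    proteins as in the survey; ~11% cytoplasmic localization.
    """

    n_genomes: int = 60
    seed: int = 0
    kingdom_mix: dict = field(default_factory=lambda: {
        Kingdom.EUBACTERIA: 0.8, Kingdom.ARCHAEA: 0.12, Kingdom.FUNGI: 0.08})
    genome_size_range: dict = field(default_factory=lambda: {
        Kingdom.EUBACTERIA: (1.5, 10.0), Kingdom.ARCHAEA: (1.5, 5.5),
        Kingdom.FUNGI: (8.0, 40.0)})
    oxygen_means: dict = field(default_factory=lambda: {
        Oxygen.AEROBIC: 8.0, Oxygen.ANAEROBIC: 3.0, Oxygen.FACULTATIVE: 5.0})
    habitat_factors: dict = field(default_factory=lambda: {
        Habitat.TERRESTRIAL: 1.4, Habitat.AQUATIC: 1.3, Habitat.MULTIPLE: 1.0,
        Habitat.HOST_ASSOCIATED: 0.7, Habitat.SPECIALIZED: 0.6})
    other_kingdom_means: dict = field(default_factory=lambda: {
        Kingdom.ARCHAEA: 2.0, Kingdom.FUNGI: 1.5})
    size_scaling: bool = True  # eubacterial mean scales with genome size
    dispersion: float | None = 5.0  # NB size parameter; None = Poisson
    family_mix: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    tandem_rate: float = 0.27  # probability of a second PDZ hit
    localization_mix: dict = field(default_factory=lambda: {
        Localization.TM: 0.33, Localization.SP: 0.46,
        Localization.TMSP: 0.0984, Localization.CYT: 0.1116})
    nan_loc_rate: float = 0.03
    sf_corroboration_rate: float = 0.6
    decoy_rate: float = 0.7  # expected above-threshold decoy hits per protein
    pdz_only_rate: float = 0.5  # fraction of UNCLASSIFIED proteins with PDZ alone
    neighborhood_plants: tuple = DEFAULT_NEIGHBORHOODS
    balanced_phenotypes: bool = False  # cycle phenotypes for exact group sizes

    def validate(self) -> None:
        for name in ("kingdom_mix", "family_mix", "localization_mix"):
            mix = getattr(self, name)
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not (0 <= self.tandem_rate <= 1):
            raise ValueError("tandem_rate must be a probability")


@dataclass
class TruthManifest:
    """Planted ground truth covering every emitted record."""

    proteins: pd.DataFrame  # protein_id, taxon_id, family, tandem_count, localization
    genomes: pd.DataFrame  # metadata columns + planted_count
    clusters: pd.DataFrame  # taxon_id, anchor_protein, anchor_locus, neighbors, gaps
    decoys: pd.DataFrame  # protein_id, domain_id, table, seq_evalue, dom_evalue


@dataclass
class Cohort:
    """In-memory realization of one synthetic cohort."""

    config: CohortConfig
    metadata: list[GenomeMetadata]
    search_hits: dict[str, list[DomainHit]]  # per taxon
    scan_hits: dict[str, list[DomainHit]]
    superfamily_hits: dict[str, list[DomainHit]]
    genes: dict[str, list[GeneRecord]]
    sequences: dict[str, str]  # per protein
    localizations: list[LocalizationRecord]
    protein_to_genome: dict[str, str]
    truth: TruthManifest


def _choice(rng: np.random.Generator, mix: Mapping) -> object:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    k = dispersion
    return int(rng.negative_binomial(k, k / (k + mean)))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=length)]


def _instantiate_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        c if c != "x" else str(_AA[rng.integers(0, len(_AA))]) for c in pattern
    )


def _splice(seq: np.ndarray, pos0: int, motif: str) -> None:
    seq[pos0 : pos0 + len(motif)] = list(motif)


def _log_evalue(rng: np.random.Generator) -> float:
    """Comfortably sub-threshold E-value (<= 1e-3)."""
    return float(10.0 ** rng.uniform(-30, -3))


def _sample_genome_metadata(config: CohortConfig, rng: np.random.Generator) -> list[GenomeMetadata]:
    phyla = {
        Kingdom.EUBACTERIA: ["Proteobacteria", "Firmicutes", "Actinobacteria",
                             "Cyanobacteria", "Planctomycetes", "Bacteroidetes"],
        Kingdom.ARCHAEA: ["Euryarchaeota", "Crenarchaeota"],
        Kingdom.FUNGI: ["Ascomycota", "Basidiomycota"],
    }
    habitats = list(config.habitat_factors.keys())
    oxygens = list(config.oxygen_means.keys())
    out = []
    for i in range(config.n_genomes):
        taxon = f"T{i:04d}"
        if config.balanced_phenotypes:
            kingdom = Kingdom.EUBACTERIA
            habitat = habitats[0] if len(habitats) == 1 else habitats[i % len(habitats)]
            oxygen = oxygens[i % len(oxygens)]
        else:
            kingdom = _choice(rng, config.kingdom_mix)
            habitat = habitats[rng.integers(0, len(habitats))]
            oxygen = oxygens[rng.integers(0, len(oxygens))]
        phylum = phyla[kingdom][int(rng.integers(0, len(phyla[kingdom])))]
        if kingdom is Kingdom.EUBACTERIA:
            gram = Gram.POSITIVE if phylum in ("Firmicutes", "Actinobacteria") else Gram.NEGATIVE
        else:
            gram = Gram.NA
        lo, hi = config.genome_size_range[kingdom]
        size = float(rng.uniform(lo, hi))
        out.append(
            GenomeMetadata(
                taxon_id=taxon,
                organism=f"Synthetica sp. {taxon}",
                kingdom=kingdom,
                phylum=phylum,
                gram=gram,
                habitat=habitat,
                oxygen=oxygen,
                genome_size_mb=round(size, 3),
            )
        )
    return out


def expected_count(config: CohortConfig, meta: GenomeMetadata) -> float:
    """Mean of the planted per-genome PDZ protein count under the rate model."""
    if meta.kingdom is not Kingdom.EUBACTERIA:
        return config.other_kingdom_means[meta.kingdom]
    mean = config.oxygen_means[meta.oxygen] * config.habitat_factors[meta.habitat]
    if config.size_scaling:
        lo, hi = config.genome_size_range[Kingdom.EUBACTERIA]
        mean *= meta.genome_size_mb / ((lo + hi) / 2.0)
    return mean


def sample_counts(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fast counts-only realization: genome metadata plus planted counts.

    Used for statistical calibration at many replicates without laying out
    hits, genes or sequences.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    metas = _sample_genome_metadata(config, rng)
    rows = []
    for m in metas:
        count = _nb_draw(rng, expected_count(config, m), config.dispersion)
        rows.append({
            "taxon_id": m.taxon_id, "kingdom": m.kingdom.value, "phylum": m.phylum,
            "gram": m.gram.value, "habitat": m.habitat.value, "oxygen": m.oxygen.value,
            "genome_size_mb": m.genome_size_mb, "planted_count": count,
        })
    return pd.DataFrame(rows)


def truth_profiles(counts: pd.DataFrame) -> list[GenomeProfile]:
    """Wrap a counts-only realization as genome profiles (localization
    unknown) so the comparison machinery can run on planted counts."""
    profiles = []
    for row in counts.itertuples(index=False):
        meta = GenomeMetadata(
            taxon_id=row.taxon_id, organism=row.taxon_id,
            kingdom=Kingdom(row.kingdom), phylum=row.phylum, gram=Gram(row.gram),
            habitat=Habitat(row.habitat), oxygen=Oxygen(row.oxygen),
            genome_size_mb=row.genome_size_mb,
        )
        n = int(row.planted_count)
        profiles.append(
            GenomeProfile(
                metadata=meta, n_pdz_proteins=n, n_pdz_domains=n,
                n_multidomain=0, loc_counts={Localization.NAN: n},
            )
        )
    return profiles


def plant_neighborhood(
    anchor: GeneRecord,
    neighbor_names: Sequence[str],
    gaps: Sequence[int],
    strand: Strand | None = None,
    locus_prefix: str = "NB",
    gene_length: int = 900,
) -> list[GeneRecord]:
    """Lay out codirectional neighbor genes downstream of ``anchor`` with the
    exact stated intergenic distances.

    A gap above the analysis threshold plants a deliberate chain break.
    Overlapping placement (negative gap) is rejected.
    """
    if len(neighbor_names) != len(gaps):
        raise ValueError("need one gap per neighbor")
    if any(g < 0 for g in gaps):
        raise ValueError("overlapping placement: gaps must be non-negative")
    strand = strand or anchor.strand
    out = []
    pos = anchor.end
    for i, (name, gap) in enumerate(zip(neighbor_names, gaps)):
        start = pos + gap + 1
        end = start + gene_length - 1
        out.append(
            GeneRecord(
                replicon_id=anchor.replicon_id, start=start, end=end, strand=strand,
                locus_tag=f"{locus_prefix}_{i:02d}", gene_name=name,
                product=f"{name} protein",
            )
        )
        pos = end
    return out


def _build_protein(
    rng: np.random.Generator,
    pid: str,
    family: Family | str,
    tandem: int,
    pdz_only: bool,
) -> tuple[list[tuple[str, int, int]], str]:
    """Lay out (domain_id, start, end) segments and the residue sequence."""
    # choose PDZ flavor label: Ctp carries the canonical Pfam family, the
    # Superfamily-only families carry 50156, everything else PDZ_2
    if family == UNCLASSIFIED:
        pdz_id = "PDZ_2"
        others = [] if pdz_only else [str(UNCLASS_VOCAB[rng.integers(0, len(UNCLASS_VOCAB))])]
    else:
        pdz_id = ("PDZ" if family is Family.CTP
                  else "50156" if family in SUPERFAMILY_ONLY_PDZ else "PDZ_2")
        others = list(FAMILY_DOMAINS[family])
        if family is Family.CTP and rng.random() < 0.4:
            others.append("DUF3340")

    if family is Family.RSEP:
        order = others + ["PDZ"] * tandem
    elif family is Family.FESO:
        order = ["PDZ"] * tandem + others  # PDZ N-terminal to the radical SAM domain
    else:
        order = ["PDZ"] * tandem + others

    segments: list[tuple[str, int, int]] = []
    pos = int(rng.integers(5, 25))
    for dom in order:
        did = pdz_id if dom == "PDZ" else dom
        length = DOMAIN_LENGTHS.get(did, 120)
        segments.append((did, pos, pos + length - 1))
        pos += length + int(rng.integers(5, 25))
    total_len = pos + int(rng.integers(10, 30))

    seq = _random_seq(rng, total_len)
    if family is Family.RSEP:
        _splice(seq, 4, _instantiate_motif(rng, "HExGH"))
        _splice(seq, total_len - 15, _instantiate_motif(rng, "NxxPxxxLDG"))
    elif family is Family.FESO:
        sam_start = next(s for d, s, e in segments if d == "Radical_SAM")
        _splice(seq, sam_start + 9, _instantiate_motif(rng, "CxxxCxxC"))
    return segments, "".join(seq)


def simulate(config: CohortConfig) -> Cohort:
    """Realize a full cohort in memory (deterministic for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    metas = _sample_genome_metadata(config, rng)
    plants_by_family = {p.anchor_family: p for p in config.neighborhood_plants}

    search_hits: dict[str, list[DomainHit]] = {}
    scan_hits: dict[str, list[DomainHit]] = {}
    sf_hits: dict[str, list[DomainHit]] = {}
    genes: dict[str, list[GeneRecord]] = {}
    sequences: dict[str, str] = {}
    localizations: list[LocalizationRecord] = []
    protein_to_genome: dict[str, str] = {}
    prot_rows, genome_rows, cluster_rows, decoy_rows = [], [], [], []

    for meta in metas:
        taxon = meta.taxon_id
        rep = f"{taxon}_chr"
        n_pdz = _nb_draw(rng, expected_count(config, meta), config.dispersion)
        search_hits[taxon], scan_hits[taxon], sf_hits[taxon] = [], [], []
        gene_list: list[GeneRecord] = []
        cursor = int(rng.integers(200, 600))
        locus_counter = 0

        def next_locus() -> str:
            nonlocal locus_counter
            locus_counter += 1
            return f"{taxon}_G{locus_counter:05d}"

        def add_filler() -> None:
            nonlocal cursor
            length = int(rng.integers(300, 2400))
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            gene_list.append(
                GeneRecord(replicon_id=rep, start=cursor, end=cursor + length - 1,
                           strand=strand, locus_tag=next_locus(),
                           product="hypothetical protein"))
            cursor += length + int(rng.integers(100, 400))

        for _ in range(int(rng.integers(3, 7))):
            add_filler()

        for j in range(n_pdz):
            pid = f"{taxon}_P{j:03d}"
            protein_to_genome[pid] = taxon
            family = _choice(rng, config.family_mix)
            tandem = 1 + (1 if rng.random() < config.tandem_rate else 0)
            pdz_only = family == UNCLASSIFIED and rng.random() < config.pdz_only_rate
            if pdz_only:
                tandem = max(tandem, 1)
            segments, seq = _build_protein(rng, pid, family, tandem, pdz_only)
            sequences[pid] = seq

            # --- hit tables ---------------------------------------------
            sf_only = family in SUPERFAMILY_ONLY_PDZ
            for did, start, end in segments:
                is_pdz = did in ("PDZ", "PDZ_2", "50156")
                if is_pdz:
                    # search pass (PDZ HMMs only)
                    search_hits[taxon].append(DomainHit(
                        protein_id=pid, domain_id=did, source=Source.PFAM,
                        seq_evalue=_log_evalue(rng), dom_evalue=_log_evalue(rng),
                        start=start, end=end, bit_score=float(rng.uniform(60, 300))))
                    if sf_only:
                        sf_hits[taxon].append(DomainHit(
                            protein_id=pid, domain_id="50156", source=Source.SUPERFAMILY,
                            seq_evalue=_log_evalue(rng), dom_evalue=_log_evalue(rng),
                            start=start, end=end, bit_score=0.0))
                        continue  # no Pfam scan hit for this diverged PDZ
                scan_hits[taxon].append(DomainHit(
                    protein_id=pid, domain_id=did, source=Source.PFAM,
                    seq_evalue=_log_evalue(rng), dom_evalue=_log_evalue(rng),
                    start=start, end=end, bit_score=float(rng.uniform(40, 300))))
                if is_pdz and rng.random() < config.sf_corroboration_rate:
                    jitter = int(rng.integers(0, 6))
                    sf_hits[taxon].append(DomainHit(
                        protein_id=pid, domain_id="50156", source=Source.SUPERFAMILY,
                        seq_evalue=_log_evalue(rng), dom_evalue=_log_evalue(rng),
                        start=start + jitter, end=end - 1, bit_score=0.0))

            # --- decoys --------------------------------------------------
            arch_end = segments[-1][2]
            for d in range(int(rng.poisson(config.decoy_rate))):
                did = str(DECOY_VOCAB[rng.integers(0, len(DECOY_VOCAB))])
                fail_seq = rng.random() < 0.5
                seq_ev = float(rng.uniform(0.011, 0.5)) if fail_seq else _log_evalue(rng)
                dom_ev = _log_evalue(rng) if fail_seq else float(rng.uniform(0.011, 0.5))
                start = arch_end + 10 + 40 * d
                scan_hits[taxon].append(DomainHit(
                    protein_id=pid, domain_id=did, source=Source.PFAM,
                    seq_evalue=seq_ev, dom_evalue=dom_ev,
                    start=start, end=start + 30, bit_score=float(rng.uniform(5, 20))))
                decoy_rows.append({"protein_id": pid, "domain_id": did, "table": "scan",
                                   "seq_evalue": seq_ev, "dom_evalue": dom_ev})
            if rng.random() < 0.3:
                # above-threshold PDZ decoy in the search pass
                dom_ev = float(rng.uniform(0.031, 0.5))
                search_hits[taxon].append(DomainHit(
                    protein_id=pid, domain_id="PDZ_2", source=Source.PFAM,
                    seq_evalue=_log_evalue(rng), dom_evalue=dom_ev,
                    start=arch_end + 200, end=arch_end + 280,
                    bit_score=float(rng.uniform(5, 15))))
                decoy_rows.append({"protein_id": pid, "domain_id": "PDZ_2",
                                   "table": "search", "seq_evalue": 0.0,
                                   "dom_evalue": dom_ev})

            # --- localization -------------------------------------------
            if rng.random() < config.nan_loc_rate:
                loc = Localization.NAN
            else:
                loc = _choice(rng, config.localization_mix)
            localizations.append(LocalizationRecord(protein_id=pid, category=loc))

            # --- gene placement -----------------------------------------
            gene_len = 3 * len(seq) + 3
            fam_label = family.value if isinstance(family, Family) else family
            plant = plants_by_family.get(family) if isinstance(family, Family) else None
            anchor = GeneRecord(
                replicon_id=rep, start=cursor, end=cursor + gene_len - 1,
                strand=Strand.PLUS, locus_tag=next_locus(),
                gene_name=fam_label.lower() if plant else "",
                product=f"planted {fam_label} PDZ protein", protein_id=pid)
            gene_list.append(anchor)
            cursor = anchor.end
            if plant is not None:
                neighbors = plant_neighborhood(
                    anchor, plant.neighbor_names, plant.gaps,
                    locus_prefix=f"{taxon}_N{j:03d}")
                # re-tag loci into the genome's namespace
                neighbors = [dataclasses.replace(g, locus_tag=next_locus(),
                                                 product=f"{g.gene_name} protein")
                             for g in neighbors]
                gene_list.extend(neighbors)
                cursor = neighbors[-1].end
                cluster_rows.append({
                    "taxon_id": taxon, "anchor_protein": pid,
                    "anchor_locus": anchor.locus_tag,
                    "neighbors": ",".join(plant.neighbor_names),
                    "gaps": ",".join(str(g) for g in plant.gaps),
                })
            cursor += int(rng.integers(100, 400))
            add_filler()

            prot_rows.append({
                "protein_id": pid, "taxon_id": taxon, "family": fam_label,
                "tandem_count": tandem, "localization":
                    ("NaN" if loc is Localization.NAN else loc.value),
                "pdz_only": pdz_only,
            })

        genes[taxon] = sorted(gene_list, key=lambda g: (g.start, g.end, g.locus_tag))
        row = {"taxon_id": taxon, "kingdom": meta.kingdom.value, "phylum": meta.phylum,
               "gram": meta.gram.value, "habitat": meta.habitat.value,
               "oxygen": meta.oxygen.value, "genome_size_mb": meta.genome_size_mb,
               "planted_count": n_pdz}
        genome_rows.append(row)

    truth = TruthManifest(
        proteins=pd.DataFrame(prot_rows, columns=[
            "protein_id", "taxon_id", "family", "tandem_count", "localization", "pdz_only"]),
        genomes=pd.DataFrame(genome_rows),
        clusters=pd.DataFrame(cluster_rows, columns=[
            "taxon_id", "anchor_protein", "anchor_locus", "neighbors", "gaps"]),
        decoys=pd.DataFrame(decoy_rows, columns=[
            "protein_id", "domain_id", "table", "seq_evalue", "dom_evalue"]),
    )
    return Cohort(
        config=config, metadata=metas, search_hits=search_hits, scan_hits=scan_hits,
        superfamily_hits=sf_hits, genes=genes, sequences=sequences,
        localizations=localizations, protein_to_genome=protein_to_genome, truth=truth,
    )


def generate_cohort(config: CohortConfig, outdir: str | Path) -> tuple[Cohort, Path]:
    """Realize a cohort and write it as a one-directory-per-genome tree.

    Layout: ``<outdir>/<taxon>/`` holds ``pdz_search.domtbl`` (hmmsearch
    orientation), ``domains_scan.domtbl`` (hmmscan orientation),
    ``superfamily.tsv``, ``<taxon>.ptt`` and ``proteome.faa``; cohort-level
    ``metadata.tsv`` and ``localization.tsv`` plus a ``truth/`` manifest sit
    beside them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate(config)
    for meta in cohort.metadata:
        taxon = meta.taxon_id
        gdir = outdir / taxon
        gdir.mkdir(exist_ok=True)
        iof.write_domtblout(cohort.search_hits[taxon], gdir / "pdz_search.domtbl",
                            orientation="search")
        iof.write_domtblout(cohort.scan_hits[taxon], gdir / "domains_scan.domtbl",
                            orientation="scan")
        iof.write_superfamily_table(cohort.superfamily_hits[taxon], gdir / "superfamily.tsv")
        iof.write_ptt(cohort.genes[taxon], gdir / f"{taxon}.ptt",
                      title=f"{meta.organism} chromosome")
        seqs = {pid: cohort.sequences[pid] for pid in sorted(cohort.sequences)
                if cohort.protein_to_genome[pid] == taxon}
        iof.write_fasta(seqs, gdir / "proteome.faa")
    iof.write_metadata(cohort.metadata, outdir / "metadata.tsv")
    iof.write_localization(cohort.localizations, outdir / "localization.tsv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.truth.proteins.to_csv(truth_dir / "proteins.tsv", sep="\t", index=False)
    cohort.truth.genomes.to_csv(truth_dir / "genomes.tsv", sep="\t", index=False)
    cohort.truth.clusters.to_csv(truth_dir / "clusters.tsv", sep="\t", index=False)
    cohort.truth.decoys.to_csv(truth_dir / "decoys.tsv", sep="\t", index=False)
    return cohort, outdir
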