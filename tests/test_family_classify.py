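"""Signature definitions, motif matching, classification precedence, and
Table-style family summaries."""

import itertools

import pytest

from domarch.architecture import build_architecture
from domarch.family_classify import (
    Family,
    FamilyAssignment,
    MotifPattern,
    PROTEASE_FAMILIES,
    Region,
    UNCLASSIFIED,
    classify_protein,
    default_signatures,
    match_motif,
    protease_fraction,
    signatures_from_yaml,
    signatures_to_yaml,
    summarize_families,
)
from domarch.io_formats import GenomeMetadata, Gram, Habitat, Kingdom, Oxygen

from conftest import make_hit


def arch_of(*domain_specs):
    """Build an architecture from (domain_id, start, end) tuples."""
    hits = [make_hit(domain_id=d, start=s, end=e) for d, s, e in domain_specs]
    return build_architecture("p1", hits)


def seq_with(length=400, motifs=()):
    """An alanine backbone with motif instances spliced at given positions."""
    seq = list("A" * length)
    for pos0, motif in motifs:
        seq[pos0 : pos0 + len(motif)] = list(motif)
    return "".join(seq)


RSEP_SEQ = seq_with(400, [(4, "HELGH"), (385, "NAAPAAALDG")])
FESO_SEQ = seq_with(400, [(150, "CAAACAAC")])
ALL_MOTIF_SEQ = seq_with(400, [(4, "HELGH"), (150, "CAAACAAC"), (385, "NAAPAAALDG")])


class TestDefaultSignatures:
    def test_exactly_twelve_families(self):
        sigs = default_signatures()
        assert len(sigs) == 12
        assert [s.family_id for s in sigs][:3] == [Family.HTRA, Family.CTP, Family.RSEP]

    def test_feso_demands_pdz_before_radical_sam(self):
        (feso,) = [s for s in default_signatures() if s.family_id is Family.FESO]
        assert feso.pdz_n_terminal_of == "Radical_SAM"
        assert feso.motifs_mandatory

    def test_comp_requires_both_kinase_domains(self):
        (comp,) = [s for s in default_signatures() if s.family_id is Family.COMP]
        assert len(comp.required) == 2
        arch = arch_of(("PDZ_2", 10, 90), ("HisKA_3", 120, 185))
        assert classify_protein(arch).family_id == UNCLASSIFIED

    def test_yaml_round_trip(self, tmp_path):
        sigs = default_signatures()
        signatures_to_yaml(sigs, tmp_path / "sigs.yaml")
        assert signatures_from_yaml(tmp_path / "sigs.yaml") == sigs


class TestMatchMotif:
    @pytest.mark.parametrize(
        "sequence,pattern,expected",
        [
            ("AAHELGHAA", "HExGH", [3]),
            ("CAAACAACAA", "CxxxCxxC", [1]),
            ("AAAA", "HExGH", []),
            ("HELGHAHELGH", "HExGH", [1, 7]),  # all (overlapping-capable) matches
        ],
    )
    def test_positions(self, sequence, pattern, expected):
        assert match_motif(sequence, MotifPattern(pattern, pattern)) == expected

    def test_region_constraints(self):
        seq = "HELGH" + "A" * 10 + "HEAGH"  # motifs at 1 and 16, length 20
        n_half = MotifPattern("m", "HExGH", Region.N_TERMINAL_HALF)
        c_half = MotifPattern("m", "HExGH", Region.C_TERMINAL_HALF)
        assert match_motif(seq, n_half) == [1]
        assert match_motif(seq, c_half) == [16]

    def test_invalid_pattern_characters_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", "HE*GH")


class TestClassifyProtein:
    def test_ctp_from_architecture(self):
        arch = arch_of(("PDZ", 10, 90), ("Peptidase_S41", 120, 320), ("DUF3340", 340, 440))
        a = classify_protein(arch)
        assert a.family_id is Family.CTP
        assert "DUF3340" in a.matched_domains

    def test_feso_with_motif(self):
        arch = arch_of(("50156", 10, 100), ("Radical_SAM", 130, 310))
        a = classify_protein(arch, sequence=FESO_SEQ)
        assert a.family_id is Family.FESO
        assert "CxxxCxxC" in a.matched_motifs

    def test_feso_rejected_when_pdz_is_c_terminal(self):
        arch = arch_of(("Radical_SAM", 10, 190), ("50156", 220, 310))
        assert classify_protein(arch, sequence=FESO_SEQ).family_id == UNCLASSIFIED

    def test_novel_architecture_unclassified(self):
        arch = arch_of(("PDZ_2", 10, 90), ("NovelDomainX", 120, 300))
        assert classify_protein(arch).family_id == UNCLASSIFIED

    def test_rsep_motifs_mandatory_with_sequence(self):
        arch = arch_of(("Peptidase_M50", 10, 210), ("PDZ_2", 240, 330))
        assert classify_protein(arch, sequence=RSEP_SEQ).family_id is Family.RSEP
        # motif-free sequence fails the mandatory check
        assert classify_protein(arch, sequence="A" * 400).family_id == UNCLASSIFIED
        # without a sequence, domain evidence suffices with a note
        a = classify_protein(arch, sequence=None)
        assert a.family_id is Family.RSEP
        assert a.confidence_note == "motif unchecked"

    def test_non_pdz_architecture_is_precondition_error(self):
        arch = arch_of(("Trypsin", 10, 200))
        with pytest.raises(ValueError):
            classify_protein(arch)

    def test_order_invariance(self):
        specs = [("PDZ", 10, 90), ("Peptidase_S41", 120, 320)]
        a1 = classify_protein(arch_of(*specs))
        a2 = classify_protein(arch_of(*reversed(specs)))
        assert a1.family_id == a2.family_id == Family.CTP


SIGNATURE_DOMAINS = {
    Family.HTRA: [("Trypsin", 220)],
    Family.CTP: [("Peptidase_S41", 200)],
    Family.RSEP: [("Peptidase_M50", 210)],
    Family.APN: [("Peptidase_M61", 250)],
    Family.LON: [("Lon_C", 200)],
    Family.SPOIVB: [("Peptidase_S55", 230)],
    Family.AP: [("Asp_protease", 100)],
    Family.ZEP: [("Peptidase_M28", 220)],
    Family.GSPC: [("Pilus_P", 100)],
    Family.FESO: [("Radical_SAM", 180)],
    Family.HAEM: [("ChaN", 130)],
    Family.COMP: [("HisKA_3", 70), ("HATPase_c", 110)],
}


class TestPrecedence:
    def test_every_signature_pair_resolves_to_earlier_family(self):
        """A protein satisfying two signatures is always assigned the
        earlier-precedence family, for all 66 signature pairs."""
        order = [s.family_id for s in default_signatures()]
        for fam_a, fam_b in itertools.combinations(order, 2):
            specs = [("PDZ_2", 10, 95)]
            pos = 130
            for fam in (fam_a, fam_b):
                for dom, length in SIGNATURE_DOMAINS[fam]:
                    specs.append((dom, pos, pos + length - 1))
                    pos += length + 20
            seq = seq_with(pos + 50, [(4, "HELGH"), (200, "CAAACAAC"),
                                      (pos + 30, "NAAPAAALDG")])
            got = classify_protein(arch_of(*specs), sequence=seq).family_id
            assert got is fam_a, f"{fam_a}/{fam_b} resolved to {got}"


def meta(taxon, phylum="Firmicutes", kingdom=Kingdom.EUBACTERIA):
    return GenomeMetadata(
        taxon_id=taxon, organism=taxon, kingdom=kingdom, phylum=phylum,
        gram=Gram.NA, habitat=Habitat.NA, oxygen=Oxygen.NA, genome_size_mb=3.0,
    )


class TestSummaries:
    def test_members_over_organisms_cells(self):
        assignments = [
            FamilyAssignment(f"p{i}", Family.CTP) for i in range(3)
        ]
        mapping = {"p0": "T1", "p1": "T1", "p2": "T2"}
        matrix = summarize_families(assignments, [meta("T1"), meta("T2")], mapping)
        table = matrix.to_table1()
        assert table.loc[("EUBACTERIA", "Firmicutes"), "CTP"] == "3/2"
        assert table.loc[("EUBACTERIA", "Firmicutes"), "HTRA"] == ""

    def test_kingdom_row_is_sum_over_phyla(self):
        assignments = [
            FamilyAssignment("p0", Family.HTRA),
            FamilyAssignment("p1", Family.HTRA),
            FamilyAssignment("p2", Family.HTRA),
        ]
        mapping = {"p0": "T1", "p1": "T2", "p2": "T3"}
        metas = [meta("T1", "Firmicutes"), meta("T2", "Proteobacteria"),
                 meta("T3", "Proteobacteria")]
        matrix = summarize_families(assignments, metas, mapping)
        per_phylum = matrix.members.drop(index="ALL", level="phylum")["HTRA"].sum()
        assert matrix.members.loc[("EUBACTERIA", "ALL"), "HTRA"] == per_phylum == 3

    def test_orphan_protein_raises_with_ids(self):
        assignments = [FamilyAssignment("ghost", Family.HTRA)]
        with pytest.raises(ValueError, match="ghost"):
            summarize_families(assignments, [meta("T1")], {})

    def test_phylum_buckets(self):
        assignments = [FamilyAssignment("p0", Family.ZEP)]
        matrix = summarize_families(
            assignments, [meta("T1", phylum="Fusobacteria")], {"p0": "T1"},
            phylum_buckets={"Fusobacteria": "Other bacteria"},
        )
        assert matrix.members.loc[("EUBACTERIA", "Other bacteria"), "ZEP"] == 1


class TestProteaseFraction:
    def test_mixed_cohort(self):
        assignments = [FamilyAssignment(f"p{i}", Family.HTRA) for i in range(8)]
        assignments += [FamilyAssignment("p8", Family.GSPC),
                        FamilyAssignment("p9", Family.FESO)]
        assert protease_fraction(assignments) == pytest.approx(0.8)

    def test_all_protease(self):
        assert protease_fraction([FamilyAssignment("p", Family.HTRA)]) == 1.0

    def test_unclassified_excluded_from_denominator(self):
        assignments = [FamilyAssignment("p0", Family.HTRA),
                       FamilyAssignment("p1", UNCLASSIFIED)]
        assert protease_fraction(assignments) == 1.0

    def test_zero_classified_is_error(self):
        with pytest.raises(ValueError):
            protease_fraction([FamilyAssignment("p", UNCLASSIFIED)])


class TestMotifProperties:
    from hypothesis import given, settings, strategies as st

    residues = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=20, max_size=120)

    @given(residues, st.integers(min_value=0, max_value=10))
    @settings(max_examples=50, derandomize=True)
    def test_spliced_motif_is_always_found(self, backbone, offset):
        """Any sequence with the Fe-S cluster motif spliced in matches it."""
        motif = "CAAACAAC"  # an instantiation of CxxxCxxC
        seq = backbone[:offset] + motif + backbone[offset:]
        pattern = MotifPattern("feso", "CxxxCxxC")
        assert (offset + 1) in match_motif(seq, pattern)
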