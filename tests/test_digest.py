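"""Tryptic digestion against brute-force and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msidissect as md
from msidissect.digest import MASS_H2O_MONO, MASS_PROTON, cleavage_sites

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence: str, max_missed: int):
    """Independent enumerator: every substring bounded by valid cleavage
    sites (or the termini) with <= max_missed internal sites."""
    sites = [i for i in range(len(sequence) - 1)
             if sequence[i] in "KR" and sequence[i + 1] != "P"]
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            sub = sequence[bounds[a]:bounds[b]]
            internal = sum(1 for s in sites if bounds[a] <= s < bounds[b] - 1)
            if internal <= max_missed:
                out.add((sub, bounds[a] + 1, bounds[b], internal))
    return out


def protein(seq, acc="TEST1"):
    return md.ProteinRecord(acc, acc, seq)


class TestDigest:
    def test_cleaves_after_kr_not_before_p(self):
        peps = md.digest(protein("GGGKAAARPPPK"), max_missed=0)
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("GGGK", 1, 4),
            ("AAARPPPK", 5, 12),
        ]

    def test_no_sites_single_peptide(self):
        peps = md.digest(protein("AAAA"), max_missed=3)
        assert len(peps) == 1
        assert peps[0].sequence == "AAAA"
        assert peps[0].missed_cleavages == 0

    def test_one_missed_cleavage_adds_joined_peptide(self):
        peps = md.digest(protein("GGGKAAARPPPK"), max_missed=1)
        assert len(peps) == 3
        assert {(p.sequence, p.missed_cleavages) for p in peps} == {
            ("GGGK", 0),
            ("AAARPPPK", 0),
            ("GGGKAAARPPPK", 1),
        }

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    def test_matches_brute_force_enumerator(self, max_missed):
        rng = np.random.default_rng(17)
        for _ in range(60):
            seq = "".join(rng.choice(list(AMINO), size=rng.integers(1, 51)))
            got = {
                (p.sequence, p.start, p.end, p.missed_cleavages)
                for p in md.digest(protein(seq), max_missed)
            }
            assert got == brute_force_digest(seq, max_missed)

    def test_matches_pyteomics_cleave(self):
        from pyteomics import parser as pparser

        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = "".join(rng.choice(list(AMINO), size=rng.integers(5, 60)))
            ours = {p.sequence for p in md.digest(protein(seq), max_missed=1)}
            theirs = pparser.cleave(seq, pparser.expasy_rules["trypsin"], missed_cleavages=1)
            assert ours == set(theirs)

    def test_zero_missed_peptides_reconstruct_parent(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO), size=rng.integers(10, 120)))
            zero = [p for p in md.digest(protein(seq), 2) if p.missed_cleavages == 0]
            zero.sort(key=lambda p: p.start)
            assert "".join(p.sequence for p in zero) == seq

    def test_raising_max_missed_never_removes(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        small = {(p.sequence, p.start) for p in md.digest(protein(seq), 0)}
        large = {(p.sequence, p.start) for p in md.digest(protein(seq), 2)}
        assert small <= large


class TestPeptideMass:
    def test_glycine_reference_value(self):
        assert md.peptide_mh("G", "mono") == pytest.approx(
            57.02146 + 18.010565 + 1.007276, abs=1e-6
        )

    @settings(deadline=None, max_examples=300)
    @given(
        st.text(alphabet=AMINO, min_size=2, max_size=40),
        st.data(),
    )
    def test_mass_additivity(self, seq, data):
        cut = data.draw(st.integers(min_value=1, max_value=len(seq) - 1))
        whole = md.peptide_mh(seq, "mono")
        parts = md.peptide_mh(seq[:cut], "mono") + md.peptide_mh(seq[cut:], "mono")
        assert whole == pytest.approx(parts - MASS_H2O_MONO - MASS_PROTON, abs=1e-9)

    def test_average_exceeds_monoisotopic(self):
        assert md.peptide_mh("AAAK", "avg") > md.peptide_mh("AAAK", "mono")

    def test_against_pyteomics(self):
        from pyteomics import mass as pmass

        rng = np.random.default_rng(9)
        for _ in range(50):
            seq = "".join(rng.choice(list(AMINO), size=rng.integers(3, 30)))
            theirs = pmass.fast_mass(seq, ion_type="M", charge=1)
            assert md.peptide_mh(seq, "mono") == pytest.approx(theirs, abs=1e-3)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            md.peptide_mh("", "mono")


class TestMassRangeFilter:
    def test_low_mass_removed(self):
        peps = md.digest(protein("GGGKAAARPPPK"), 0)
        gggk = [p for p in peps if p.sequence == "GGGK"][0]
        assert gggk.mh_mono < 600  # ~318.2 Da
        assert gggk not in md.filter_mass_range(peps)

    def test_boundary_inclusive(self):
        pep = md.TrypticPeptide("GGGK", "T", 1, 4, 0, 600.0, 600.4)
        assert md.filter_mass_range([pep], 600.0, 3200.0) == [pep]

    def test_empty_and_bad_bounds(self):
        assert md.filter_mass_range([]) == []
        with pytest.raises(ValueError):
            md.filter_mass_range([], low=3200, high=600)


class TestUniqueness:
    def test_parent_only_is_unique(self):
        prot = protein("GGGKAAAWCESR", "P1")
        proteome = md.Proteome([prot, protein("MMMMKTTTT", "P2")])
        pep = md.digest(prot, 0)[1]
        assert md.check_uniqueness(pep, proteome) is True
        assert pep.unique_in_proteome is True

    def test_shared_peptide_not_unique(self):
        prot = protein("GGGKAAAWCESR", "P1")
        proteome = md.Proteome([prot, protein("MMMKAAAWCESRTTT", "P2")])
        pep = [p for p in md.digest(prot, 0) if p.sequence == "AAAWCESR"][0]
        assert md.check_uniqueness(pep, proteome) is False

    def test_isoleucine_leucine_equivalence(self):
        prot = protein("GGGKALKWWW", "P1")
        pep = [p for p in md.digest(prot, 0) if p.sequence == "ALK"][0]
        proteome = md.Proteome([prot, protein("CCCAIKCCC", "P2")])
        assert md.check_uniqueness(pep, proteome) is False

    def test_peptide_absent_from_parent_is_internal_error(self):
        proteome = md.Proteome([protein("AAAA", "P1")])
        ghost = md.TrypticPeptide("WWW", "P1", 1, 3, 0, 500.0, 500.0)
        with pytest.raises(RuntimeError, match="consistency"):
            md.check_uniqueness(ghost, proteome)

    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            md.Proteome([protein("AAAA", "P1"), protein("CCCC", "P1")])


class TestSelectMarkerPeptides:
    def make_fixture(self):
        # marker with exactly 3 unique in-window zero-missed peptides;
        # one peptide shadowed in a homologous decoy
        marker = protein("WWDDDDDKYYEEEEERFFFFFFKHHHHHHHR", "MARK1")
        decoy = protein("GGGGWWDDDDDKGGGG", "DEC1")  # shares peptide 1
        return marker, md.Proteome([marker, decoy])

    def test_top_ranked_returned(self):
        marker, proteome = self.make_fixture()
        sel = md.select_marker_peptides(marker, proteome, n=2, max_missed=1)
        assert len(sel) == 2
        assert all(p.unique_in_proteome for p in sel)
        assert "WWDDDDDK" not in {p.sequence for p in sel}
        # ranking: fewest missed cleavages first, then descending mass
        assert sel[0].missed_cleavages <= sel[1].missed_cleavages
        if sel[0].missed_cleavages == sel[1].missed_cleavages:
            assert sel[0].mh_mono >= sel[1].mh_mono

    def test_fully_shadowed_marker_returns_empty(self):
        marker = protein("AAAWCESK", "MARK1")
        twin = protein("TTTKAAAWCESKTTT", "TWIN1")
        sel = md.select_marker_peptides(marker, md.Proteome([marker, twin]), n=2)
        assert sel == []

    def test_n_zero(self):
        marker, proteome = self.make_fixture()
        assert md.select_marker_peptides(marker, proteome, n=0) == []
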