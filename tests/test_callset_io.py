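"""Call-set reading, allele reconciliation and genotype-class assignment."""

import pytest
from hypothesis import given, strategies as st

from gtconcord.callset_io import (
    GenotypeCall,
    GenotypeClass,
    Platform,
    Site,
    VarClass,
    assign_genotype_class,
    harmonize_pair,
    indel_symbol_map,
    read_beadchip_report,
    read_wgs_vcf,
    reverse_complement,
)


class TestReadWgsVcf:
    def test_parses_het_missing_indel_and_homref(self, vcf_path):
        calls = read_wgs_vcf(vcf_path, "S1")
        by_id = {c.site.id: (c, a) for c, a in calls}
        # filtered record is dropped
        assert set(by_id) == {"rs1633365", "snp_nocall", "ins_homalt", "homref"}

        het, ann = by_id["rs1633365"]
        assert het.alleles == ("C", "T")
        assert (ann.dp, ann.gq, ann.qual) == (30, 99, 100.0)

        nocall, _ = by_id["snp_nocall"]
        assert nocall.missing and nocall.alleles == ()

        ins, _ = by_id["ins_homalt"]
        assert ins.alleles == ("AG", "AG")
        assert ins.site.var_class is VarClass.INDEL

        homref, ann = by_id["homref"]
        assert homref.alleles == ("A", "A")
        assert ann.rgq == 90 and ann.gq is None

    def test_missing_sample_is_configuration_error(self, vcf_path):
        with pytest.raises(KeyError, match="nosuch"):
            read_wgs_vcf(vcf_path, "nosuch")


class TestReadBeadchipReport:
    def test_parses_rows(self, beadchip_path):
        out = read_beadchip_report(beadchip_path)
        assert len(out) == 3
        by_id = {c.site.id: (c, r) for c, r in out}

        indel, rec = by_id["rs3832043"]
        assert indel.alleles == ("I", "I")
        assert indel.site.var_class is VarClass.INDEL
        assert rec.theta == 0.02 and rec.gc_score == 0.78

        nocall, _ = by_id["rs_nocall"]
        assert nocall.missing

        het, _ = by_id["rs_het"]
        assert het.alleles == ("A", "G")

    def test_missing_column_reported_by_name(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("[Header]\nNum SNPs\t0\n[Data]\nSNP Name\tChr\tPosition\n")
        with pytest.raises(ValueError, match="GC Score"):
            read_beadchip_report(p)


class TestAssignGenotypeClass:
    @pytest.mark.parametrize(
        "ref,alts,alleles,expected",
        [
            ("G", ("A",), ("A", "A"), GenotypeClass.BB),  # hom-alt, e.g. GG->AA call
            ("G", ("A",), ("G", "G"), GenotypeClass.AA),
            ("G", ("A", "T"), ("A", "T"), GenotypeClass.BC),
            ("G", ("A", "T"), ("G", "T"), GenotypeClass.AC),
            ("T", ("C",), ("C", "T"), GenotypeClass.AB),
        ],
    )
    def test_snv_labels(self, ref, alts, alleles, expected):
        site = Site("1", 100, "s", ref, alts)
        call = GenotypeCall(site, alleles, Platform.WGS)
        assert assign_genotype_class(site, call) is expected

    def test_missing_maps_to_missing(self):
        site = Site("1", 100, "s", "T", ("C",))
        call = GenotypeCall(site, (), Platform.WGS, missing=True)
        assert assign_genotype_class(site, call) is GenotypeClass.MISSING

    def test_indel_calls_compared_through_symbols(self):
        site = Site("1", 300, "ins", "A", ("AG",))
        assert indel_symbol_map(site) == {"AG": "I", "A": "D", "I": "I", "D": "D"}
        seq_call = GenotypeCall(site, ("AG", "AG"), Platform.WGS)
        sym_call = GenotypeCall(site, ("I", "I"), Platform.BEADCHIP)
        assert assign_genotype_class(site, seq_call) is GenotypeClass.BB
        assert assign_genotype_class(site, sym_call) is GenotypeClass.BB

    def test_unreconciled_allele_is_an_error(self):
        site = Site("1", 100, "s", "T", ("C",))
        call = GenotypeCall(site, ("A", "A"), Platform.WGS)
        with pytest.raises(ValueError, match="harmonization bug"):
            assign_genotype_class(site, call)


def _bead(site, alleles, missing=False):
    shadow = Site(site.chrom, site.pos, site.id, "N", (),
                  VarClass.INDEL if set(alleles) <= {"I", "D"} and alleles
                  else VarClass.SNV)
    return GenotypeCall(shadow, alleles, Platform.BEADCHIP, missing=missing)


class TestHarmonizePair:
    def _sites(self):
        return {
            "dis": Site("1", 109711919, "rs1633365", "T", ("C",)),
            "con": Site("1", 200, "s2", "C", ("A",)),
            "flip": Site("1", 300, "s3", "T", ("C",)),
            "pal": Site("1", 400, "s4", "A", ("T",)),
            "miss": Site("1", 500, "s5", "G", ("A",)),
        }

    def test_pairing_classes_and_exclusions(self):
        s = self._sites()
        wgs = [
            GenotypeCall(s["dis"], ("T", "T"), Platform.WGS),
            GenotypeCall(s["con"], ("C", "C"), Platform.WGS),
            GenotypeCall(s["flip"], ("C", "T"), Platform.WGS),
            GenotypeCall(s["pal"], ("A", "A"), Platform.WGS),
            GenotypeCall(s["miss"], ("G", "G"), Platform.WGS),
        ]
        bead = [
            _bead(s["dis"], ("C", "T")),     # BeadChip TC vs WGS TT -> AB vs AA
            _bead(s["con"], ("C", "C")),     # identical hom-ref
            _bead(s["flip"], ("A", "G")),    # opposite strand: revcomp -> (C,T)
            _bead(s["pal"], ("C", "C")),     # mismatch at A/T site: ambiguous
            _bead(s["miss"], (), missing=True),
        ]
        pairs, report = harmonize_pair(wgs, bead)
        by_id = {p.site.id: p for p in pairs}
        assert set(by_id) == {"rs1633365", "s2", "s3"}

        dis = by_id["rs1633365"]
        assert (dis.class_truth, dis.class_test) == (GenotypeClass.AA, GenotypeClass.AB)
        assert not dis.concordant

        con = by_id["s2"]
        assert con.concordant and con.class_truth is GenotypeClass.AA

        flip = by_id["s3"]
        assert flip.call_test.alleles == ("C", "T")
        assert flip.concordant

        assert report.n_ambiguous_strand == 1
        assert report.n_missing_either == 1
        assert report.n_paired == 3

    def test_exclude_chroms(self):
        site = Site("X", 100, "sx", "T", ("C",))
        wgs = [GenotypeCall(site, ("T", "T"), Platform.WGS)]
        bead = [_bead(site, ("T", "T"))]
        pairs, report = harmonize_pair(wgs, bead, {"X"})
        assert pairs == [] and report.n_excluded_chrom == 1

    def test_site_membership_symmetric(self):
        s = self._sites()
        wgs = [GenotypeCall(s["dis"], ("T", "T"), Platform.WGS),
               GenotypeCall(s["con"], ("C", "C"), Platform.WGS)]
        bead = [_bead(s["dis"], ("C", "T")), _bead(s["con"], ("C", "C"))]
        fwd, _ = harmonize_pair(wgs, bead)
        rev, _ = harmonize_pair(bead, wgs)
        assert {(p.site.chrom, p.site.pos) for p in fwd} == \
               {(p.site.chrom, p.site.pos) for p in rev}

    def test_no_pair_carries_missing_class(self):
        s = self._sites()
        wgs = [GenotypeCall(st, ("T", "T") if st.ref == "T" else (st.ref, st.ref),
                            Platform.WGS) for st in s.values()]
        bead = [_bead(st, (st.ref, st.ref)) for st in s.values()]
        pairs, _ = harmonize_pair(wgs, bead)
        assert pairs
        for p in pairs:
            assert GenotypeClass.MISSING not in (p.class_truth, p.class_test)

    def test_strand_flip_panel(self):
        """Five-marker panel where the array is typed on the opposite strand."""
        panel = [
            ("T", "C", ("A", "G"), ("C", "T")),
            ("G", "A", ("C", "C"), ("G", "G")),
            ("A", "C", ("T", "T"), ("A", "A")),
            ("C", "T", ("A", "G"), ("C", "T")),
            ("G", "C", ("G", "C"), ("C", "G")),  # palindromic but direct match
        ]
        wgs, bead = [], []
        for i, (ref, alt, bead_alleles, expected) in enumerate(panel):
            site = Site("1", 1000 + i, f"m{i}", ref, (alt,))
            wgs.append(GenotypeCall(site, expected, Platform.WGS))
            bead.append(_bead(site, bead_alleles))
        pairs, report = harmonize_pair(wgs, bead)
        assert report.n_paired == 5
        for p, (_, _, _, expected) in zip(pairs, panel):
            assert p.call_test.alleles == tuple(sorted(expected))
            assert p.concordant


@given(st.text(alphabet="ACGT", min_size=1, max_size=8))
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_site_rejects_nonpositive_positions():
    with pytest.raises(ValueError):
        Site("1", 0, "bad", "A", ("C",))


def test_var_class_inferred_from_allele_lengths():
    assert Site("1", 1, "a", "A", ("C",)).var_class is VarClass.SNV
    assert Site("1", 1, "b", "A", ("AG",)).var_class is VarClass.INDEL
    assert Site("1", 1, "c", "AT", ("A",)).var_class is VarClass.INDEL
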