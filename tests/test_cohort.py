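"""Cohort I/O, allele normalization and the packaged fixtures."""

import hashlib
import io
from importlib import resources

import pytest
from hypothesis import given, strategies as st

from mpsi_predict import (
    Allele,
    CohortError,
    Genotype,
    MalformedAlleleError,
    TriState,
    normalize_allele,
    parse_gestational_age,
    read_cohort,
    read_mutation_list,
    write_cohort,
)

HEADER = (
    "patient_id,phenotype,gestational_age,allele1,allele2,"
    "idua_activity,urt_obstruction,inguinal_hernia"
)


class TestNormalizeAllele:
    @pytest.mark.parametrize(
        "raw, namespace, token",
        [
            (" p.W402X ", "protein", "W402X"),
            ("c.134del12", "coding", "134DEL12"),
            ("P.w402x", "protein", "W402X"),
            ("c.474-2A > G", "coding", "474-2A>G"),
            ("c.474-2A&gt;G", "coding", "474-2A>G"),
        ],
    )
    def test_normalization(self, raw, namespace, token):
        assert normalize_allele(raw) == Allele(namespace, token)

    @pytest.mark.parametrize("raw", ["", "  ", "W402X", "x.W402X", "p."])
    def test_malformed(self, raw):
        with pytest.raises(MalformedAlleleError):
            normalize_allele(raw)

    def test_round_trip_idempotent(self):
        a = normalize_allele("p.w402x")
        assert normalize_allele(a.render()) == a

    @given(st.text(alphabet="pc.XWQL0123456789delins>+- \t", min_size=1))
    def test_normalize_total_or_error(self, raw):
        """Normalization either yields a render-stable allele or raises the
        dedicated error; comparison is whitespace- and case-insensitive."""
        try:
            allele = normalize_allele(raw)
        except MalformedAlleleError:
            return
        assert allele.token == allele.token.upper()
        assert normalize_allele(allele.render()) == allele
        assert normalize_allele(" " + raw.upper() + " ") == allele


class TestGenotype:
    def test_symmetry(self):
        a, b = normalize_allele("p.W402X"), normalize_allele("p.Q70X")
        assert Genotype(a, b) == Genotype(b, a)
        assert hash(Genotype(a, b)) == hash(Genotype(b, a))

    def test_homozygous_not_equal_heterozygous(self):
        a, b = normalize_allele("p.W402X"), normalize_allele("p.Q70X")
        assert Genotype(a, a) != Genotype(a, b)


class TestGestationalAge:
    @pytest.mark.parametrize(
        "raw, days, term",
        [("37 + 0", 259, True), ("33 + 6", 237, False), ("41+2", 289, True)],
    )
    def test_parse(self, raw, days, term):
        ga = parse_gestational_age(raw)
        assert ga.total_days == days
        assert ga.is_term is term

    def test_unknown_marker(self):
        ga = parse_gestational_age("X")
        assert not ga.known
        assert ga.total_days is None
        assert ga.is_term and not ga.is_preterm  # unknown assumed term

    @pytest.mark.parametrize("raw", ["37 + 9", "abc", "37", "+2"])
    def test_parse_errors(self, raw):
        with pytest.raises(CohortError):
            parse_gestational_age(raw)


class TestReadCohort:
    def test_packaged_cohort_shape(self, cohort):
        assert len(cohort) == 30
        assert sum(r.phenotype == "H" for r in cohort) == 17
        assert sum(r.idua_activity is not None for r in cohort) == 18

    def test_packaged_cohort_pinned(self):
        """Checksum pin of the packaged cohort file."""
        raw = (
            resources.files("mpsi_predict.data")
            .joinpath("reference_cohort.csv")
            .read_bytes()
        )
        assert (
            hashlib.sha256(raw).hexdigest()
            == "2fe5a831a9d30893ca7e3bb55f0804c1c61894ce2b2deb6ac965cd651293b0d7"
        )

    def test_spot_cells(self, by_id):
        p5 = by_id["5"]
        assert p5.genotype.allele2 == normalize_allele("c.134del12")
        assert p5.idua_activity == pytest.approx(0.26)
        p22 = by_id["22"]
        assert p22.gestational_age.total_days == 259
        assert p22.phenotype == "HS"
        assert by_id["26"].findings.urt_obstruction is TriState.UNKNOWN
        assert by_id["21"].findings.inguinal_hernia is TriState.ABSENT

    def test_empty_cohort(self):
        assert read_cohort(io.StringIO(HEADER + "\n")) == []

    def test_header_only_required(self):
        with pytest.raises(CohortError, match="required columns"):
            read_cohort(io.StringIO("patient_id,phenotype\n1,H\n"))

    def test_duplicate_id(self):
        body = "\n".join(
            [HEADER, "1,H,40 + 0,p.W402X,p.W402X,X,+,-", "1,S,40 + 0,p.R383H,p.R383H,X,-,-"]
        )
        with pytest.raises(CohortError, match="duplicate"):
            read_cohort(io.StringIO(body))

    def test_bad_activity_and_phenotype(self):
        with pytest.raises(CohortError, match="activity"):
            read_cohort(
                io.StringIO(HEADER + "\n1,H,40 + 0,p.W402X,p.W402X,soup,+,-\n")
            )
        with pytest.raises(CohortError, match="phenotype"):
            read_cohort(
                io.StringIO(HEADER + "\n1,Q,40 + 0,p.W402X,p.W402X,X,+,-\n")
            )

    def test_tab_delimited_and_extra_features(self):
        text = (
            HEADER.replace(",", "\t")
            + "\tfeat_kyphosis\n"
            + "1\tH\t40 + 0\tp.W402X\tp.W402X\t0.31\t+\t-\t+\n"
        )
        [rec] = read_cohort(io.StringIO(text))
        assert rec.findings.get("kyphosis") is TriState.PRESENT

    def test_round_trip(self, cohort):
        buf = io.StringIO()
        write_cohort(cohort, buf)
        again = read_cohort(io.StringIO(buf.getvalue()))
        assert again == cohort


class TestMutationList:
    def test_packaged_list(self, severe):
        assert len(severe) == 25
        assert normalize_allele("p.A327P") in severe
        assert normalize_allele("p.R383H") not in severe

    def test_dedup(self):
        sl = read_mutation_list(io.StringIO("p.W402X\np.W402X\n"))
        assert len(sl) == 1

    def test_comments_and_line_numbers(self):
        sl = read_mutation_list(io.StringIO("# header\np.W402X  # trailing\n\n"))
        assert len(sl) == 1
        with pytest.raises(MalformedAlleleError, match="line 2"):
            read_mutation_list(io.StringIO("p.W402X\nnot-an-allele\n"))
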