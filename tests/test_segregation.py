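"""Affection status, transmission, phasing and co-segregation."""

import pytest

from sliprio.models import Affection, Genotype
from sliprio.segregation import (
    Cosegregation,
    Origin,
    Phase,
    affection_status,
    cosegregation,
    mendelian_audit,
    phase_comphet,
    transmission_check,
)

KEY = ("chr8", 107738486, "G", "A")
KEY2 = ("chr8", 107739000, "C", "T")


class TestAffectionStatus:
    @pytest.mark.parametrize(
        "els, rls, expected",
        [
            (65.9, None, Affection.affected),
            (100, 100, Affection.unaffected),
            (77.5, None, Affection.unaffected),  # strictly below the 1.5 SD cut
            (77.4, 90, Affection.affected),
            (90, 70, Affection.affected),
            (None, None, Affection.unknown),
        ],
    )
    def test_threshold(self, els, rls, expected):
        assert affection_status(els, rls) is expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            affection_status(-5, None)


class TestTransmissionCheck:
    def test_de_novo(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.het,
                ("D", KEY): Genotype.hom_ref,
                ("M", KEY): Genotype.hom_ref,
            }
        )
        assert transmission_check(KEY, fam) is Origin.de_novo

    def test_inferred_paternal_when_father_ungenotyped(self, family_factory):
        fam = family_factory(
            genotypes={("P", KEY): Genotype.het, ("M", KEY): Genotype.hom_ref}
        )
        assert transmission_check(KEY, fam) is Origin.inferred_paternal

    def test_both_parents_het_is_ambiguous(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.het,
                ("D", KEY): Genotype.het,
                ("M", KEY): Genotype.het,
            }
        )
        assert transmission_check(KEY, fam) is Origin.unknown

    def test_single_carrier_parent(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.het,
                ("D", KEY): Genotype.hom_ref,
                ("M", KEY): Genotype.het,
            }
        )
        assert transmission_check(KEY, fam) is Origin.maternal

    def test_missing_proband_genotype_rejected(self, family_factory):
        fam = family_factory()
        with pytest.raises(ValueError):
            transmission_check(KEY, fam)


class TestPhaseComphet:
    def _fam(self, family_factory, father_gts, mother_gts):
        genotypes = {("P", KEY): Genotype.het, ("P", KEY2): Genotype.het}
        genotypes[("D", KEY)], genotypes[("D", KEY2)] = father_gts
        genotypes[("M", KEY)], genotypes[("M", KEY2)] = mother_gts
        return family_factory(genotypes=genotypes)

    def test_opposite_parents_is_trans(self, family_factory):
        fam = self._fam(
            family_factory,
            (Genotype.het, Genotype.hom_ref),
            (Genotype.hom_ref, Genotype.het),
        )
        assert phase_comphet([KEY, KEY2], fam) is Phase.trans

    def test_same_parent_is_cis(self, family_factory):
        fam = self._fam(
            family_factory,
            (Genotype.hom_ref, Genotype.hom_ref),
            (Genotype.het, Genotype.het),
        )
        assert phase_comphet([KEY, KEY2], fam) is Phase.cis

    def test_unresolved_origin_is_unknown(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.het,
                ("P", KEY2): Genotype.het,
                ("D", KEY): Genotype.hom_ref,
                ("M", KEY): Genotype.het,
                ("D", KEY2): Genotype.het,
                ("M", KEY2): Genotype.het,  # both parents carry the second variant
            }
        )
        assert phase_comphet([KEY, KEY2], fam) is Phase.unknown


class TestCosegregation:
    def test_affected_carriers_only(self, family_factory):
        fam = family_factory(
            children_status=("affected", "affected", "affected"),
            genotypes={
                ("P", KEY): Genotype.het,
                ("S1", KEY): Genotype.het,
                ("S2", KEY): Genotype.het,
            },
        )
        assert cosegregation(KEY, fam) is Cosegregation.co_segregates

    def test_unaffected_carrier_is_partial(self, family_factory):
        fam = family_factory(
            children_status=("affected", "unaffected"),
            genotypes={("P", KEY): Genotype.het, ("S1", KEY): Genotype.het},
        )
        assert cosegregation(KEY, fam) is Cosegregation.partial

    def test_inverted_pattern_contradicts(self, family_factory):
        fam = family_factory(
            children_status=("affected", "unaffected"),
            genotypes={("P", KEY): Genotype.hom_ref, ("S1", KEY): Genotype.het},
        )
        assert cosegregation(KEY, fam) is Cosegregation.contradicts

    def test_single_informative_child_uninformative(self, family_factory):
        fam = family_factory(
            children_status=("affected", "unknown"),
            genotypes={("P", KEY): Genotype.het, ("S1", KEY): Genotype.het},
        )
        assert cosegregation(KEY, fam) is Cosegregation.uninformative

    def test_symmetric_under_child_relabeling(self, family_factory):
        a = family_factory(
            children_status=("affected", "unaffected"),
            genotypes={("P", KEY): Genotype.het, ("S1", KEY): Genotype.hom_ref},
        )
        b = family_factory(
            children_status=("unaffected", "affected"),
            genotypes={("P", KEY): Genotype.hom_ref, ("S1", KEY): Genotype.het},
        )
        assert cosegregation(KEY, a) is cosegregation(KEY, b)


class TestMendelianAudit:
    def test_de_novo_signature_not_flagged(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.het,
                ("D", KEY): Genotype.hom_ref,
                ("M", KEY): Genotype.hom_ref,
            }
        )
        assert mendelian_audit(fam) == []

    def test_hom_alt_child_of_hom_ref_parent_flagged(self, family_factory):
        fam = family_factory(
            genotypes={
                ("P", KEY): Genotype.hom_alt,
                ("D", KEY): Genotype.hom_ref,
                ("M", KEY): Genotype.het,
            }
        )
        problems = mendelian_audit(fam)
        assert len(problems) == 1 and problems[0][0] == "F1_P"


class TestSimulatedRecovery:
    def test_trans_phase_recovered_with_both_parents_genotyped(self):
        """On simulated families with known transmitted haplotypes, phasing
        makes zero errors when both parents are genotyped."""
        from sliprio.simulate import SimConfig, simulate_cohort

        cohort = simulate_cohort(SimConfig(n_families=12, plant_comphet=4, seed=99))
        fams = {f.fid: f for f in cohort.pedigrees}
        for item in cohort.truth.comphet:
            phase = phase_comphet([tuple(k) for k in item["keys"]], fams[item["family"]])
            assert phase is Phase.trans
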