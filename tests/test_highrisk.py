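"""Stop-gain screen, compound-het grouping, multiple-hit pooling."""

import numpy as np
import pytest

from sliprio.filters import FilterConfig, qc_filter
from sliprio.candidates import screen_candidates
from sliprio.highrisk import (
    comphet_candidates,
    hom_alt_rare_deleterious,
    multihit_probands,
    stopgain_screen,
)
from sliprio.models import FrequencyTier, FuncClass, Genotype
from tests._oracles import brute_force_comphet, random_cohort
from tests.test_filters import make_variant


class TestStopgainScreen:
    def test_fixture_all_retained(self, stopgain_table, protein_annotations):
        variants, carriers = stopgain_table
        records = stopgain_screen(
            variants, carriers, protein_annotations=protein_annotations
        )
        assert len(records) == 7
        assert all(r.tier is FrequencyTier.rare for r in records)

    def test_truncation_annotation(self, stopgain_table, protein_annotations):
        variants, carriers = stopgain_table
        records = stopgain_screen(
            variants, carriers, protein_annotations=protein_annotations
        )
        by_gene = {r.variant.gene: r.truncation_pct for r in records}
        # near-start stop loses almost the whole protein
        assert by_gene["OXR1"] == 97.7
        assert by_gene["NUDT16L1"] == 3.6

    def test_low_frequency_stopgain_excluded(self):
        v = make_variant(func_class=FuncClass.stopgain, freq_kg=0.02)
        assert stopgain_screen([v], {v.key: ("1",)}) == []

    def test_nonsynonymous_not_in_scope(self):
        v = make_variant(freq_kg=0.001, sift=0.0)
        assert stopgain_screen([v], {v.key: ("1",)}) == []


class TestComphetCandidates:
    def test_fixture_eleven_genes(self, multivariant_table):
        variants, carriers = multivariant_table
        retained, _ = qc_filter(variants)
        candidates = comphet_candidates(retained, carriers)
        assert len({c.gene for c in candidates}) == 11

    def test_proximity_pair_removed(self):
        a = make_variant(pos=1000, freq_kg=0.001, sift=0.0)
        b = make_variant(pos=1005, ref="C", alt="T", freq_kg=0.001, sift=0.0)
        carriers = {a.key: ("1",), b.key: ("1",)}
        assert comphet_candidates([a, b], carriers) == []

    def test_distant_pair_kept(self):
        a = make_variant(pos=1000, freq_kg=0.001, sift=0.0)
        b = make_variant(pos=1011, ref="C", alt="T", freq_kg=0.001, sift=0.0)
        carriers = {a.key: ("1",), b.key: ("1",)}
        (cand,) = comphet_candidates([a, b], carriers)
        assert cand.gene == "GENEA" and len(cand.variants) == 2

    def test_order_invariance(self, multivariant_table):
        variants, carriers = multivariant_table
        retained, _ = qc_filter(variants)
        forward = comphet_candidates(retained, carriers)
        backward = comphet_candidates(retained[::-1], carriers)
        assert forward == backward

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(1234)
        for _ in range(15):
            variants, carriers = random_cohort(
                rng, n_probands=int(rng.integers(3, 12)), n_variants=int(rng.integers(20, 90))
            )
            retained, _ = qc_filter(variants)
            got = {
                (c.proband, c.gene): frozenset(v.key for v in c.variants)
                for c in comphet_candidates(retained, carriers)
            }
            # oracle works from the same QC-passed records, by literal predicates
            expected = brute_force_comphet(retained, carriers)
            assert got == expected

    def test_postconditions_reassert(self, multivariant_table):
        from sliprio.filters import frequency_tier, is_deleterious

        variants, carriers = multivariant_table
        retained, _ = qc_filter(variants)
        for cand in comphet_candidates(retained, carriers):
            for v in cand.variants:
                assert frequency_tier(v) in (FrequencyTier.novel, FrequencyTier.rare)
                assert is_deleterious(v)
                assert not v.segdup


class TestHomAltReport:
    def test_hom_alt_flagged_separately(self):
        v = make_variant(freq_kg=0.001, sift=0.0)
        hits = hom_alt_rare_deleterious([v], {("1", v.key): Genotype.hom_alt})
        assert hits == [("1", v)]
        assert hom_alt_rare_deleterious([v], {("1", v.key): Genotype.het}) == []


class TestMultihit:
    def _candidate_entry(self, gene, proband, pos):
        v = make_variant(gene=gene, pos=pos)
        _, shortlist = screen_candidates([v], {v.key: (proband,)}, genes=(gene,))
        return shortlist[0]

    def test_candidate_plus_stopgain_reported(self):
        cand = self._candidate_entry("SEMA6D", "30", 48063365)
        sg_variant = make_variant(
            gene="SYNPR", pos=63466576, func_class=FuncClass.stopgain, freq_evs=0.0001
        )
        stopgains = stopgain_screen([sg_variant], {sg_variant.key: ("30",)})
        reports = multihit_probands([cand], stopgains, [])
        assert len(reports) == 1
        assert {cat for cat, _, _ in reports[0].hits} == {"candidate_gene", "stopgain"}

    def test_single_hit_not_reported(self):
        cand = self._candidate_entry("ERC1", "23", 1137072)
        assert multihit_probands([cand], [], []) == []

    def test_comphet_pair_alone_reported_once(self):
        a = make_variant(pos=1000, freq_kg=0.001, sift=0.0)
        b = make_variant(pos=2000, ref="C", alt="T", freq_kg=0.001, sift=0.0)
        carriers = {a.key: ("9",), b.key: ("9",)}
        comphets = comphet_candidates([a, b], carriers)
        reports = multihit_probands([], [], comphets)
        assert len(reports) == 1
        assert reports[0].hits == [("comphet_gene", "GENEA", (a.key, b.key))]

    def test_superset_of_multiply_screened_probands(self, multivariant_table):
        variants, carriers = multivariant_table
        retained, _ = qc_filter(variants)
        comphets = comphet_candidates(retained, carriers)
        stopgains = stopgain_screen(retained, carriers)
        reports = multihit_probands([], stopgains, comphets)
        in_two_screens = {c.proband for c in comphets} & {
            p for r in stopgains for p in r.carriers
        }
        assert in_two_screens <= {r.proband for r in reports}
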