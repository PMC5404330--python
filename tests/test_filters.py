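"""Exclusion filters, frequency tiers, deleteriousness, truncation fraction."""

import pytest
from hypothesis import given, settings, strategies as st

from sliprio.filters import (
    FilterConfig,
    frequency_tier,
    is_deleterious,
    qc_filter,
    truncation_fraction,
)
from sliprio.models import AnnotatedVariant, FrequencyTier, FuncClass


def make_variant(**kw):
    base = dict(
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="G",
        gene="GENEA",
        func_class=FuncClass.nonsynonymous_snv,
        min_depth=30,
    )
    base.update(kw)
    return AnnotatedVariant(**base)


class TestQcFilter:
    def test_class_exclusion(self):
        variants = [
            make_variant(func_class=FuncClass.intronic),
            make_variant(pos=2000),
        ]
        retained, counts = qc_filter(variants)
        assert len(retained) == 1
        assert counts.as_dict() == {"class": 1, "segdup": 0, "depth": 0, "retained": 1}

    def test_segdup_exclusion(self):
        retained, counts = qc_filter([make_variant(segdup=True)])
        assert retained == [] and counts.segdup == 1

    def test_counts_match_direct_recount(self):
        """Composition of a 100-variant mix equals a literal re-count."""
        variants = []
        for i in range(25):
            variants.append(make_variant(pos=10_000 + i, func_class=FuncClass.synonymous))
        for i in range(20):
            variants.append(make_variant(pos=20_000 + i, segdup=True))
        for i in range(15):
            variants.append(make_variant(pos=30_000 + i, min_depth=5))
        for i in range(40):
            variants.append(make_variant(pos=40_000 + i))
        _, counts = qc_filter(variants)
        coding = {
            "nonsynonymous_snv", "stopgain", "stoploss", "splice",
            "frameshift_ins", "frameshift_del", "nonframeshift_indel",
        }
        expected_class = sum(1 for v in variants if v.func_class.value not in coding)
        expected_segdup = sum(
            1 for v in variants if v.func_class.value in coding and v.segdup
        )
        expected_depth = sum(
            1
            for v in variants
            if v.func_class.value in coding and not v.segdup and v.min_depth < 10
        )
        assert counts.as_dict() == {
            "class": expected_class,
            "segdup": expected_segdup,
            "depth": expected_depth,
            "retained": 40,
        }

    def test_idempotent(self):
        variants = [make_variant(pos=p) for p in range(100, 160)]
        once, _ = qc_filter(variants)
        twice, counts = qc_filter(once)
        assert twice == once
        assert counts.as_dict()["retained"] == len(once)


class TestFrequencyTier:
    @pytest.mark.parametrize(
        "kg, evs, expected",
        [
            (None, 0.0008, FrequencyTier.rare),
            (None, None, FrequencyTier.novel),
            (0.03, 0.02, FrequencyTier.low_frequency),
            (0.10, None, FrequencyTier.common),
            # boundaries: rare is strictly < 1%, low tier closed at 5%
            (0.01, None, FrequencyTier.low_frequency),
            (0.0099999, None, FrequencyTier.rare),
            (0.05, None, FrequencyTier.low_frequency),
            (0.0500001, None, FrequencyTier.common),
        ],
    )
    def test_tiers(self, kg, evs, expected):
        v = make_variant(freq_kg=kg, freq_evs=evs)
        assert frequency_tier(v) is expected

    def test_rsid_does_not_preclude_novelty(self):
        v = make_variant(rsid="rs368057493")
        assert frequency_tier(v) is FrequencyTier.novel

    def test_max_over_panels(self):
        v = make_variant(freq_kg=0.002, freq_evs=0.03)
        assert frequency_tier(v) is FrequencyTier.low_frequency
        assert frequency_tier(v, FilterConfig(tier_panel="kg")) is FrequencyTier.rare

    @settings(max_examples=200, deadline=None)
    @given(
        kg=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        evs=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    )
    def test_total_function(self, kg, evs):
        tier = frequency_tier(make_variant(freq_kg=kg, freq_evs=evs))
        assert tier in FrequencyTier


class TestIsDeleterious:
    @pytest.mark.parametrize(
        "sift, polyphen, expected",
        [
            (0.00, 0.91, True),
            (0.59, 0.00, False),
            (0.05, 0.10, True),  # boundary of SIFT <= 0.05
            (0.06, 0.84, False),
            (None, None, False),
            (None, 0.85, True),
        ],
    )
    def test_substitutions(self, sift, polyphen, expected):
        v = make_variant(sift=sift, polyphen=polyphen)
        assert is_deleterious(v) is expected

    def test_lof_exemption(self):
        v = make_variant(func_class=FuncClass.stopgain, sift=1.0, polyphen=None)
        assert is_deleterious(v)
        cfg = FilterConfig(stopgain_exempt_from_scores=False)
        assert not is_deleterious(v, cfg)

    @settings(max_examples=150, deadline=None)
    @given(
        sift=st.floats(0, 1, allow_nan=False),
        polyphen=st.floats(0, 1, allow_nan=False),
        d_sift=st.floats(0, 1, allow_nan=False),
        d_pp=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone(self, sift, polyphen, d_sift, d_pp):
        """Lowering SIFT or raising PolyPhen never flips deleterious -> benign."""
        v = make_variant(sift=sift, polyphen=polyphen)
        worse = make_variant(
            sift=max(0.0, sift - d_sift), polyphen=min(1.0, polyphen + d_pp)
        )
        if is_deleterious(v):
            assert is_deleterious(worse)


class TestTruncationFraction:
    @pytest.mark.parametrize(
        "stop, length, expected",
        [
            (1, 100, 100.0),
            (5, 174, 97.7),  # oracle: 100 * (174 - 5 + 1) / 174 = 97.7011...
            (50, 50, 2.0),
        ],
    )
    def test_values(self, stop, length, expected):
        assert truncation_fraction(stop, length) == expected

    def test_stop_beyond_protein_rejected(self):
        with pytest.raises(ValueError):
            truncation_fraction(101, 100)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(rare_threshold=0.05, low_freq_threshold=0.01)
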