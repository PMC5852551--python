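import itertools

import numpy as np
import pandas as pd
import pytest

from empaikit.io_tables import PipelineConfig, ProteinRecord
from empaikit.paralogs import (
    ParalogFamily,
    excess_report,
    family_correlations,
    group_families,
    null_fractions,
    pair_correlation,
    select_variable_proteins,
)

from .conftest import lpai_matrix


def _coarse(profiles: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(profiles, orient="index")


class TestSelectVariable:
    def test_span_rule_with_inclusive_boundary(self):
        lpai = np.array(
            [
                [0.0, 0.0, 0.0],  # constant -> excluded
                [0.0, 0.5, 0.2],  # span exactly tau -> included
                [0.0, 0.49, 0.1],  # just under -> excluded
                [-3.0, 0.0, -3.0],  # pseudo-values count toward the span
            ]
        )
        m = lpai_matrix(lpai, ["a", "b", "c"], ["P0", "P1", "P2", "P3"], "a")
        kept = select_variable_proteins(m, tau=0.5)
        assert list(kept) == ["P1", "P3"]


class TestGroupFamilies:
    def _records(self, assignment):
        return [
            ProteinRecord(t, "c1", i + 1, arcog_id=g)
            for i, (t, g) in enumerate(assignment.items())
        ]

    def test_all_distinct_groups_means_no_families(self):
        records = self._records({"A": "g1", "B": "g2", "C": None})
        fams, singles = group_families(["A", "B", "C"], records)
        assert fams == []
        assert singles == ["A", "B", "C"]

    def test_toy_grouping(self):
        records = self._records({"A": "g1", "B": "g1", "C": "g2"})
        fams, singles = group_families(["A", "B", "C"], records)
        assert [(f.arcog_id, f.member_loci) for f in fams] == [("g1", ("A", "B"))]
        assert singles == ["C"]

    def test_family_membership_restricted_to_subset(self):
        records = self._records({"A": "g1", "B": "g1", "C": "g1"})
        fams, singles = group_families(["A", "C"], records)  # B not in subset
        assert fams[0].member_loci == ("A", "C")
        assert singles == []

    def test_singleton_family_invalid(self):
        with pytest.raises(ValueError):
            ParalogFamily("g1", ("only",))


class TestPairCorrelations:
    def test_identical_and_reversed_profiles(self):
        coarse = _coarse({"A": [0, 1, 2, 3], "B": [0, 1, 2, 3], "C": [3, 2, 1, 0]})
        fam = ParalogFamily("g", ("A", "B", "C"))
        pairs, fr = family_correlations([fam], coarse, cutoff=0.8)
        by = {(p.locus_a, p.locus_b): p.r for p in pairs}
        assert by[("A", "B")] == pytest.approx(1.0)
        assert by[("A", "C")] == pytest.approx(-1.0)
        assert fr.frac_pos == pytest.approx(1 / 3)
        assert fr.frac_neg == pytest.approx(2 / 3)

    def test_constant_profile_invalid_not_zero(self):
        coarse = _coarse({"A": [0, 0, 0], "B": [0, 1, 2]})
        p = pair_correlation("A", "B", coarse)
        assert not p.valid and np.isnan(p.r)
        fam = ParalogFamily("g", ("A", "B"))
        with pytest.raises(ValueError):
            family_correlations([fam], coarse, cutoff=0.8)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(0)
        coarse = _coarse({f"P{i}": rng.integers(0, 4, 6) for i in range(12)})
        fam = ParalogFamily("g", tuple(coarse.index))
        fracs = []
        for cutoff in (0.2, 0.5, 0.8, 0.95):
            _, fr = family_correlations([fam], coarse, cutoff=cutoff)
            fracs.append((fr.frac_pos, fr.frac_neg))
        assert [f[0] for f in fracs] == sorted((f[0] for f in fracs), reverse=True)
        assert [f[1] for f in fracs] == sorted((f[1] for f in fracs), reverse=True)


class TestNullFractions:
    def _singleton_profiles(self, n=20, seed=4):
        rng = np.random.default_rng(seed)
        return _coarse({f"S{i}": rng.integers(0, 4, 6) for i in range(n)})

    def test_matches_exhaustive_enumeration(self):
        # brute-force oracle: all unordered pairs of the 20 singletons
        coarse = self._singleton_profiles()
        cfg = PipelineConfig(null_pairs=40_000, rng_seed=0, correlation_cutoff=0.8)
        null = null_fractions(list(coarse.index), coarse, cfg)
        rs = []
        for a, b in itertools.combinations(coarse.index, 2):
            p = pair_correlation(a, b, coarse)
            if p.valid:
                rs.append(p.r)
        exact_pos = np.mean([r > 0.8 for r in rs])
        exact_neg = np.mean([r < -0.8 for r in rs])
        # 3 standard errors of the sampled fraction
        for sampled, exact in [
            (null.fractions.frac_pos, exact_pos),
            (null.fractions.frac_neg, exact_neg),
        ]:
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / cfg.null_pairs)
            assert abs(sampled - exact) <= 3 * se + 1e-12

    def test_seed_determinism(self):
        coarse = self._singleton_profiles()
        cfg = PipelineConfig(null_pairs=5000, rng_seed=42)
        a = null_fractions(list(coarse.index), coarse, cfg)
        b = null_fractions(list(coarse.index), coarse, cfg)
        assert a == b

    def test_constant_singletons_excluded_and_too_few_rejected(self):
        coarse = _coarse({"A": [1, 1, 1], "B": [0, 1, 2], "C": [2, 2, 2]})
        cfg = PipelineConfig(null_pairs=10)
        with pytest.raises(ValueError):
            null_fractions(["A", "B", "C"], coarse, cfg)


class TestExcessReport:
    def test_observed_equals_null_gives_unit_ratio(self):
        coarse = self._mixed_coarse()
        fam = ParalogFamily("g", ("A", "B"))
        pairs, obs = family_correlations([fam], coarse, cutoff=0.8)
        cfg = PipelineConfig(null_pairs=1000, rng_seed=0)
        null = null_fractions(["A", "B", "C", "D"], coarse, cfg)
        report = excess_report(obs, null)
        assert set(report.index) == {"pos", "neg"}
        assert (report["ratio_lo"] <= report["ratio"]).all()
        assert (report["ratio"] <= report["ratio_hi"]).all()

    def _mixed_coarse(self):
        rng = np.random.default_rng(1)
        return _coarse({t: rng.integers(0, 4, 6) for t in "ABCD"})

    def test_printed_fraction_ratio(self):
        # ratio of the two tail fractions is their plain quotient
        from empaikit.paralogs import TailFractions, CorrelationNull

        obs = TailFractions(0.105, 0.125, 1000, 0, 0.8)
        null = CorrelationNull(10_000, 0, TailFractions(0.032, 0.038, 10_000, 0, 0.8))
        report = excess_report(obs, null)
        assert report.loc["pos", "ratio"] == pytest.approx(3.28, abs=0.01)
        assert report.loc["neg", "ratio"] == pytest.approx(3.29, abs=0.01)

    def test_zero_null_fraction_gives_infinite_ratio(self):
        from empaikit.paralogs import TailFractions, CorrelationNull

        obs = TailFractions(0.2, 0.0, 100, 0, 0.8)
        null = CorrelationNull(100, 0, TailFractions(0.0, 0.0, 100, 0, 0.8))
        report = excess_report(obs, null)
        assert np.isinf(report.loc["pos", "ratio"])

    def test_mismatched_cutoffs_rejected(self):
        from empaikit.paralogs import TailFractions, CorrelationNull

        obs = TailFractions(0.1, 0.1, 100, 0, 0.8)
        null = CorrelationNull(100, 0, TailFractions(0.1, 0.1, 100, 0, 0.9))
        with pytest.raises(ValueError):
            excess_report(obs, null)
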