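"""Fine-structure patterns, centroiding and channel grouping."""

import math

import numpy as np
import pytest

from cidval.chem import parse_formula
from cidval.pattern import (
    InstrumentModel,
    centroid_pattern,
    fine_pattern,
    group_by_tracer_channel,
)

from conftest import enumerate_fine_pattern

INF = InstrumentModel(resolving_power=math.inf)


def match_oracle(formula_str, table, tol=1e-12):
    f = parse_formula(formula_str)
    fp = fine_pattern(f, prune_threshold=0.0)
    om, oa = enumerate_fine_pattern(f, table)
    assert len(fp) == len(om)
    order = np.argsort(fp.masses)
    assert np.allclose(fp.masses[order], om, atol=1e-8)
    assert np.allclose(fp.abundances[order], oa, atol=tol)


class TestFinePattern:
    def test_single_isotope_elements_give_one_species(self):
        fp = fine_pattern(parse_formula("P4"))
        assert len(fp) == 1
        assert fp.abundances[0] == pytest.approx(1.0, abs=1e-12)

    def test_c2_binomial_expansion(self, table):
        a12, a13 = table["C"].abundances
        fp = fine_pattern(parse_formula("C2"), prune_threshold=0.0)
        assert np.allclose(
            np.sort(fp.abundances)[::-1], sorted([a12**2, 2 * a12 * a13, a13**2], reverse=True),
            atol=1e-15,
        )

    @pytest.mark.parametrize("formula", ["CHNOS", "C2H2O2", "SeH2", "C3H4O", "C2H3NS"])
    def test_small_formulas_match_enumeration_oracle(self, formula, table):
        """Convolution agrees with exhaustive isotope-assignment enumeration."""
        match_oracle(formula, table)

    def test_semet_against_enumeration(self, semet, table):
        # 20 atoms is past the oracle's comfort zone for full product
        # enumeration, so check the Se-Met backbone without hydrogens
        # (H contributes a near-trivial binomial layer checked separately).
        match_oracle("C5NO2Se", table)

    def test_retained_probability_bound(self, semet):
        thr = 1e-8
        fp = fine_pattern(semet, prune_threshold=thr)
        assert fp.total_abundance >= 1.0 - thr

    def test_deterministic(self, semet):
        a = fine_pattern(semet)
        b = fine_pattern(semet)
        assert np.array_equal(a.masses, b.masses)
        assert np.array_equal(a.abundances, b.abundances)


class TestCentroiding:
    def test_infinite_resolution_is_identity(self, semet):
        fp = fine_pattern(semet)
        cp = centroid_pattern(fp, INF)
        assert len(cp) == len(fp)
        assert np.allclose(np.sort(fp.masses), cp.masses)

    def test_fwhm_above_span_collapses_to_one_centroid(self, semet):
        fp = fine_pattern(semet)
        cp = centroid_pattern(fp, InstrumentModel(resolving_power=1.0, scaling="flat"))
        assert len(cp) == 1
        assert cp.abundances[0] == pytest.approx(fp.total_abundance, abs=1e-12)

    def test_total_abundance_conserved(self, semet, inst120, inst30):
        fp = fine_pattern(semet)
        for inst in (inst120, inst30):
            cp = centroid_pattern(fp, inst)
            assert cp.total_abundance == pytest.approx(fp.total_abundance, abs=1e-12)

    def test_centroid_count_monotone_in_resolving_power(self, semet):
        fp = fine_pattern(semet)
        counts = [
            len(centroid_pattern(fp, InstrumentModel(r)))
            for r in (1e3, 1e4, 3e4, 1.2e5, 1e6, 1e8)
        ]
        assert counts == sorted(counts)

    def test_masses_strictly_increasing_after_centroiding(self, semet, inst30):
        cp = centroid_pattern(fine_pattern(semet), inst30)
        assert np.all(np.diff(cp.masses) > 0)

    def test_se76_c13_merges_with_se77_at_30k_not_120k(self, semet, table, inst120, inst30):
        """The near-isobar pair ~2.7 mDa apart at m/z ~197 straddles the
        two FWHM settings: resolved at 120 K, one centroid at 30 K."""
        light = sum(n * table[s].lightest_mass for s, n in semet.counts.items())
        m_76_c13 = light + (table.mass("Se", 76) - table.mass("Se", 74)) + (
            table.mass("C", 13) - table.mass("C", 12)
        )
        m_77 = light + (table.mass("Se", 77) - table.mass("Se", 74))
        gap = abs(m_77 - m_76_c13)
        assert inst120.fwhm(m_77) < gap < inst30.fwhm(m_77)
        fp = fine_pattern(semet)
        n120 = len(centroid_pattern(fp, inst120))
        n30 = len(centroid_pattern(fp, inst30))
        assert n30 < n120


class TestGrouping:
    def test_pure_se_reproduces_abundance_table(self, table):
        se = parse_formula("Se")
        g = group_by_tracer_channel(centroid_pattern(fine_pattern(se), INF), se, "Se")
        assert np.allclose(g.fractions_percent, np.array(table["Se"].abundances) * 100, atol=1e-9)

    def test_fractions_sum_to_100(self, semet, inst120, inst30):
        fp = fine_pattern(semet)
        for inst in (inst120, inst30):
            g = group_by_tracer_channel(centroid_pattern(fp, inst), semet, "Se")
            assert g.fractions_percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_semet_120k_matches_hand_built_assignment(self, semet, table, inst120):
        """Oracle: enumerate the backbone fine species, keep those within
        one FWHM of a selenium-channel anchor, renormalize."""
        om, oa = enumerate_fine_pattern(parse_formula("C5NO2Se"), table)
        light = om[0]
        anchors = light + np.array(table["Se"].masses) - table.mass("Se", 74)
        groups = np.zeros(len(anchors))
        for m, a in zip(om, oa):
            j = np.abs(anchors - m).argmin()
            if abs(m - anchors[j]) <= inst120.fwhm(m):
                groups[j] += a
        expect = groups / groups.sum() * 100
        f = parse_formula("C5NO2Se")
        g = group_by_tracer_channel(centroid_pattern(fine_pattern(f), inst120), f, "Se")
        assert np.allclose(g.fractions_percent, expect, atol=0.05)

    def test_single_polyisotopic_element_grouping_resolution_independent(self, table):
        """With only one polyisotopic element there is nothing to merge:
        any resolution reproduces that element's abundance vector."""
        f = parse_formula("SeP2")
        fp = fine_pattern(f)
        for r in (5e3, 3e4, 1.2e5):
            g = group_by_tracer_channel(centroid_pattern(fp, InstrumentModel(r)), f, "Se")
            assert np.allclose(
                g.fractions_percent, np.array(table["Se"].abundances) * 100, atol=1e-9
            )
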