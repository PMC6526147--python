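"""Resolution-aware natural-abundance correction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidval.chem import default_table, parse_formula
from cidval.correction import build_correction_matrix, correct_areas
from cidval.pattern import InstrumentModel
from cidval.tracer import CIDVector, predict_cid

INST120 = InstrumentModel(resolving_power=120000.0)
INST_LOW = InstrumentModel(resolving_power=10000.0)


class TestBuildMatrix:
    def test_ch_formula_carbon_off_is_identity(self):
        """2H is resolved from 13C at 120 K, so with carbon treated as pure
        12C nothing contaminates any channel."""
        cm = build_correction_matrix(parse_formula("C3H8"), INST120, carbon_correction=False)
        assert np.allclose(cm.matrix, np.eye(4), atol=1e-12)

    def test_column_sums_bounded_by_one(self, methionine):
        for inst, cc in itertools.product((INST120, INST_LOW), (True, False)):
            cm = build_correction_matrix(methionine, inst, carbon_correction=cc)
            assert np.all(cm.matrix.sum(axis=0) <= 1.0 + 1e-9)

    def test_column0_reproduces_natural_envelope(self):
        """With carbon correction on, column 0 is the unlabeled molecule's
        channel-binned natural pattern — oracle: single-atom enumeration."""
        f = parse_formula("C2H6")  # small enough for an exact hand model
        cm = build_correction_matrix(f, INST120, carbon_correction=True)
        t = default_table()
        a12, a13 = t["C"].abundances
        # at 120 K every 2H species is resolved away -> pure carbon binomial
        expect = np.array([a12**2, 2 * a12 * a13, a13**2])
        assert np.allclose(cm.matrix[:, 0], expect, atol=1e-9)

    def test_unresolved_34s_contributes_two_channels_up(self, methionine):
        """At low resolving power 34S merges with the +2 carbon channel.

        Oracle: per fixed label count k, convolve the fine species of the
        rest of the molecule and bin at the FWHM criterion by hand."""
        cm = build_correction_matrix(methionine, INST_LOW, carbon_correction=False)
        t = default_table()
        s = t["S"]
        a34 = s.abundances[list(map(round, s.masses)).index(34)]
        for k in range(0, 4):
            assert cm.matrix[k + 2, k] >= a34 * 0.9
        # and at 120 K the 34S offset is resolved from 2x13C
        cm_hi = build_correction_matrix(methionine, INST120, carbon_correction=False)
        assert cm_hi.matrix[2, 0] < 1e-6

    def test_low_res_matrix_matches_enumeration_oracle(self):
        """Full matrix for a tiny S-containing formula against brute force."""
        f = parse_formula("C2H2S")
        inst = INST_LOW
        t = default_table()
        step = t.mass("C", 13) - t.mass("C", 12)
        light = sum(n * t[el].lightest_mass for el, n in f.counts.items())
        anchors = light + step * np.arange(3)

        # independent oracle: enumerate H2 x S isotope combos, drop species
        # resolved from every carbon offset, renormalize per element, then
        # bin each (k-labeled) species to its unresolved nearest anchor
        def element_dist(sym, count):
            iso = t[sym]
            keep = []
            for m, a in zip(iso.masses, iso.abundances):
                d = m - iso.masses[0]
                j = round(d / step)
                if d == 0 or abs(d - j * step) < inst.fwhm(light + j * step):
                    keep.append((m - iso.masses[0], a))
            tot = sum(a for _, a in keep)
            keep = [(d, a / tot) for d, a in keep]
            dist = {0.0: 1.0}
            for _ in range(count):
                nxt = {}
                for off, p in dist.items():
                    for d, a in keep:
                        key = off + d
                        nxt[key] = nxt.get(key, 0.0) + p * a
                dist = nxt
            return dist

        expect = np.zeros((3, 3))
        for k in range(3):
            rest = {0.0: 1.0}
            for sym, cnt in (("H", 2), ("S", 1)):
                d = element_dist(sym, cnt)
                nxt = {}
                for o1, p1 in rest.items():
                    for o2, p2 in d.items():
                        nxt[o1 + o2] = nxt.get(o1 + o2, 0.0) + p1 * p2
                rest = nxt
            for off, p in rest.items():
                m = light + k * step + off
                j = int(np.abs(anchors - m).argmin())
                if abs(m - anchors[j]) < inst.fwhm((m + anchors[j]) / 2):
                    expect[j, k] += p
        cm = build_correction_matrix(f, inst, carbon_correction=False)
        assert np.allclose(cm.matrix, expect, atol=1e-9)


class TestCorrectAreas:
    def test_identity_matrix_normalizes_input(self):
        cm = build_correction_matrix(parse_formula("C3H8"), INST120)
        cid, res = correct_areas(np.array([1.0, 2.0, 3.0, 4.0]), cm)
        assert np.allclose(cid.fractions, [10, 20, 30, 40], atol=1e-9)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_forward_simulation_round_trip(self, methionine):
        cm = build_correction_matrix(methionine, INST_LOW, carbon_correction=True)
        true = predict_cid(5, 0.49755)
        areas = cm.matrix @ (true.fractions / 100.0)
        rec, _ = correct_areas(areas, cm)
        assert np.allclose(rec.fractions, true.fractions, atol=1e-8)

    def test_unlabeled_molecule_corrects_to_pure_m0(self):
        f = parse_formula("C6H12O6")
        cm = build_correction_matrix(f, INST120, carbon_correction=True)
        rec, _ = correct_areas(cm.matrix[:, 0].copy(), cm)
        assert rec.fractions[0] == pytest.approx(100.0, abs=1e-8)

    def test_all_zero_rejected(self):
        cm = build_correction_matrix(parse_formula("C3H8"), INST120)
        with pytest.raises(ValueError):
            correct_areas(np.zeros(4), cm)

    @given(
        raw=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=6, max_size=6).filter(
            lambda v: sum(v) > 0.05
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_round_trip_random_cids(self, raw, methionine):
        """build x cid then NNLS recovers any non-negative CID."""
        cid = np.array(raw) / sum(raw) * 100.0
        cm = build_correction_matrix(methionine, INST_LOW, carbon_correction=True)
        areas = cm.matrix @ (cid / 100.0)
        rec, _ = correct_areas(areas, cm)
        assert np.allclose(rec.fractions, cid, atol=1e-6)

    def test_carbon_off_changes_nothing_for_pure_ch_pattern(self):
        """Correcting reference-material data for a formula with no other
        polyisotopic contribution must be a no-op (the reference pattern is
        already the quantity of interest)."""
        f = parse_formula("C4H10")
        cm = build_correction_matrix(f, INST120, carbon_correction=False)
        cid = predict_cid(4, 0.49755)
        rec, _ = correct_areas(cid.fractions.copy(), cm)
        assert np.allclose(rec.fractions, cid.fractions, atol=1e-9)
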