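"""Duplex construction protocol: build, flip, isoG, modified pair, ions."""

import numpy as np
import pytest

from dyndist import geometry as geo
from dyndist.cv import dynamic_distance, pair_distances
from dyndist.geometry import (
    DEFAULT_SEQ1,
    build_antiparallel_duplex,
    build_default_duplex,
    guanine_to_isoguanine,
    hydrogen_bonds,
    insert_modified_pair,
    neutralize,
    parallelize,
    remove_hg,
    select_constraint_pairs,
)


def _strand_seq(duplex, strand):
    units = sorted(
        (u for u in duplex.units if u.strand_index == strand),
        key=lambda u: u.position,
    )
    return [u.base_code for u in units]


def _axis_extent(duplex, strand):
    units = sorted(
        (u for u in duplex.units if u.strand_index == strand),
        key=lambda u: u.position,
    )
    return units[-1].site("C1'")[2] - units[0].site("C1'")[2]


class TestBuild:
    def test_default_sequence_gives_13_pairs_26_units(self):
        d = build_antiparallel_duplex(DEFAULT_SEQ1, rise=3.38, twist=36.0)
        assert d.n_pairs == 13
        assert len(d.units) == 26

    def test_single_base_pairs_with_complement(self):
        d = build_antiparallel_duplex("A")
        assert d.n_pairs == 1
        assert _strand_seq(d, 2) == ["T"]

    def test_consecutive_c1_axial_separation_equals_rise(self):
        rise = 3.38
        d = build_antiparallel_duplex("GC", rise=rise, twist=36.0)
        z1 = d.unit_at(1, 1).site("C1'")[2]
        z2 = d.unit_at(1, 2).site("C1'")[2]
        assert abs((z2 - z1) - rise) < 1e-9

    def test_unknown_base_rejected_naming_character(self):
        with pytest.raises(ValueError, match="'X'"):
            build_antiparallel_duplex("GAXG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_antiparallel_duplex("")

    def test_all_watson_crick_bonds_at_template_length(self):
        d = build_antiparallel_duplex(DEFAULT_SEQ1)
        pos, _, _, smap = d.to_arrays()
        for _, h, a in hydrogen_bonds(d):
            assert np.linalg.norm(pos[smap[h]] - pos[smap[a]]) == pytest.approx(
                1.88, abs=1e-9
            )

    def test_deterministic_rebuild(self):
        a = build_default_duplex(seed=3)
        b = build_default_duplex(seed=3)
        pa, _, la, _ = a.to_arrays()
        pb, _, lb, _ = b.to_arrays()
        assert la == lb
        np.testing.assert_array_equal(pa, pb)


class TestParallelize:
    def test_t7_pairs_ea20_after_modification(self):
        d = build_default_duplex(seed=0, neutralized=False)
        assert d.modified_pairs == [(7, 7, "modified")]
        assert d.unit_at(1, 7).label == "T7"
        assert d.unit_at(2, 7).label == "eA20"

    def test_both_strands_run_5prime_to_3prime_in_plus_z(self):
        anti = build_antiparallel_duplex(DEFAULT_SEQ1)
        assert _axis_extent(anti, 1) > 0 > _axis_extent(anti, 2)
        par = parallelize(anti)
        assert _axis_extent(par, 1) > 0 and _axis_extent(par, 2) > 0

    def test_parallel_complementarity(self):
        par = parallelize(build_antiparallel_duplex(DEFAULT_SEQ1))
        assert "".join(_strand_seq(par, 2)) == "CTCCCTATCTTTC"
        for i, j, _ in par.pairing:
            assert i == j

    def test_single_pair_duplex(self):
        par = parallelize(build_antiparallel_duplex("A"))
        assert par.pairing == [(1, 1, "AT")]

    def test_double_parallelize_rejected(self):
        par = parallelize(build_antiparallel_duplex("AT"))
        with pytest.raises(ValueError, match="already parallel"):
            parallelize(par)


class TestIsoguanine:
    def test_default_duplex_has_six_isoguanines(self):
        d = guanine_to_isoguanine(parallelize(build_antiparallel_duplex(DEFAULT_SEQ1)))
        assert sum(1 for u in d.units if u.base_code == "iG") == 6

    def test_no_guanine_is_identity(self):
        d = build_antiparallel_duplex("ATA")
        d2 = guanine_to_isoguanine(d)
        p1, _, _, _ = d.to_arrays()
        p2, _, _, _ = d2.to_arrays()
        np.testing.assert_array_equal(p1, p2)

    def test_involution_restores_exocyclic_positions(self):
        d = parallelize(build_antiparallel_duplex(DEFAULT_SEQ1))
        back = guanine_to_isoguanine(guanine_to_isoguanine(d))
        for u, v in zip(d.units, back.units):
            assert u.base_code == v.base_code
            np.testing.assert_allclose(u.coords, v.coords, atol=1e-12)

    def test_isog_restores_parallel_gc_hydrogen_bonds(self):
        par = parallelize(build_antiparallel_duplex(DEFAULT_SEQ1))
        gc_bonds_before = [b for b in hydrogen_bonds(par) if b[0] == "iGC"]
        iso = guanine_to_isoguanine(par)
        gc_bonds_after = [b for b in hydrogen_bonds(iso) if b[0] == "iGC"]
        # flipped C cannot donate/accept properly against G, but does vs iG
        assert len(gc_bonds_before) < len(gc_bonds_after) == 18


class TestModifiedPair:
    def test_insertion_places_two_hg_in_no_pattern(self, default_duplex):
        d = default_duplex
        assert len(d.hg_ions) == 2
        pos, _, _, smap = d.to_arrays()
        for hg, (n_site, o_site) in (
            ("Hg1", ("eA20:N7", "T7:O4")),
            ("Hg2", ("eA20:N6", "T7:O2")),
        ):
            for partner in (n_site, o_site):
                r = np.linalg.norm(pos[smap[hg]] - pos[smap[partner]])
                assert r == pytest.approx(2.15, abs=1e-9)

    def test_each_hg_sees_exactly_two_acceptors_within_2p5(self, default_duplex):
        pos, _, labels, smap = default_duplex.to_arrays()
        acceptors = [
            i for l, i in smap.items()
            if ":" in l and l.split(":")[1][0] in ("N", "O")
        ]
        for hg in ("Hg1", "Hg2"):
            x = pos[smap[hg]]
            n_close = sum(
                1 for i in acceptors if np.linalg.norm(pos[i] - x) < 2.5
            )
            assert n_close == 2

    def test_thymine_deprotonated_and_charge_plus_three(self, default_duplex):
        t7 = default_duplex.unit_at(1, 7)
        assert not t7.has_site("H3")
        assert t7.base_charge == -1
        # base-pair charge: deprotonated T (-1) + eA (0) + 2 Hg(2+)
        ea = default_duplex.unit_at(2, 7)
        assert t7.base_charge + ea.base_charge + 2 * len(default_duplex.hg_ions) == 3

    def test_hg_free_protonated_analogue(self):
        d = build_default_duplex(seed=0, hg=False, neutralized=False)
        assert d.hg_ions == []
        t7 = d.unit_at(1, 7)
        assert t7.has_site("H3") and t7.base_charge == 0

    def test_non_at_position_rejected(self):
        d = guanine_to_isoguanine(parallelize(build_antiparallel_duplex(DEFAULT_SEQ1)))
        with pytest.raises(ValueError, match="not A:T"):
            insert_modified_pair(d, 1)


class TestNeutralize:
    def test_default_duplex_needs_23_cations(self):
        d = build_default_duplex(seed=0, neutralized=False)
        assert d.total_charge == -23
        n = neutralize(d, seed=0)
        assert len(n.counter_ions) == 23
        assert all(e == "NA" for e, _, _ in n.counter_ions)
        assert n.total_charge == 0

    def test_structure3_from_structure1_adds_three_ions(self, default_duplex):
        d3 = remove_hg(default_duplex)
        assert d3.total_charge == -3
        d3n = neutralize(d3, seed=5)
        assert len(d3n.counter_ions) - len(d3.counter_ions) == 3
        assert d3n.total_charge == 0

    def test_zero_charge_input_adds_no_ions(self, default_duplex):
        again = neutralize(default_duplex, seed=9)
        assert len(again.counter_ions) == len(default_duplex.counter_ions)

    def test_ion_exclusion_radius(self, default_duplex):
        pos, _, labels, _ = default_duplex.to_arrays()
        ion_idx = [i for i, l in enumerate(labels) if ":" not in l and not l.startswith("Hg")]
        other = [i for i in range(len(labels)) if i not in ion_idx]
        for i in ion_idx:
            d = np.linalg.norm(pos[other] - pos[i], axis=1).min()
            assert d >= 3.0


class TestConstraintSelection:
    def test_dna_variant_has_12_nh_plus_2_no_pairs(self, default_duplex, dna_spec):
        assert dna_spec.n_pairs == 14
        no_pairs = [l for l in dna_spec.labels if "N7" in l or "N6" in l]
        assert len(no_pairs) == 2

    def test_equi_variant_counts_all_regular_hbonds(self, equi_spec):
        # 6 iG:C pairs x 3 bonds + 6 A:T pairs x 2 bonds
        assert equi_spec.n_pairs == 30

    def test_iso_variant_two_pairs(self, default_duplex):
        spec = select_constraint_pairs(default_duplex, "ISO")
        assert spec.n_pairs == 2
        assert sorted(spec.labels) == [
            "eA20:N6--T7:O2",
            "eA20:N7--T7:O4",
        ]

    def test_initial_cv_values(self, default_duplex, equi_spec, dna_spec):
        pos, _, _, _ = default_duplex.to_arrays()
        assert dynamic_distance(equi_spec, pos) == pytest.approx(1.88, abs=1e-9)
        assert dynamic_distance(dna_spec, pos) == pytest.approx(2.984, abs=2e-3)

    def test_no_atom_in_two_pairs(self, default_duplex):
        for variant in ("EQUI", "DNA", "ISO"):
            spec = select_constraint_pairs(default_duplex, variant)
            flat = spec.pairs.ravel()
            assert len(np.unique(flat)) == len(flat)

    def test_hg_free_fallback_uses_donor_acceptor_pairs(self):
        d3 = build_default_duplex(seed=0, hg=False, neutralized=False)
        spec = select_constraint_pairs(d3, "ISO")
        assert sorted(spec.labels) == [
            "T7:H3--eA20:N7",
            "T7:O2--eA20:N6",
        ]

    def test_unknown_variant_rejected(self, default_duplex):
        with pytest.raises(ValueError, match="variant"):
            select_constraint_pairs(default_duplex, "BOGUS")
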