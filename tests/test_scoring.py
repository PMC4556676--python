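"""Depth-dependent score terms: atom transfer, solvation, hydrogen bonding,
packing, residue tables, penalties, and the weighted total."""

import numpy as np
import pytest

from mpslab import FixtureSpec, MembraneGeometry, build_helix, detect_spans
from mpslab.core import Atom, Residue, Structure, apply_transform, hydration_fraction
from mpslab.scoring import (
    cbeta_score,
    env_atom_score,
    env_residue_score,
    hbond_depth_weight,
    hbond_score,
    packing_score,
    pair_score,
    penalty_scores,
    solvation_score,
    total_score,
)
from mpslab.tables import (
    AtomTransferTable,
    CbetaTable,
    PairDepthTable,
    ResidueDepthTable,
    ScoreWeights,
    SolvationParams,
    VdwParams,
    default_tables,
)

from conftest import random_rigid_transform


def atom_structure(*positions, category="aliphatic_C", aa="ALA"):
    """Structure of bare pseudo-atoms at given positions (one per residue)."""
    residues = [
        Residue(i + 1, "A", aa, [Atom("CB", "C", np.array(p, float), category)])
        for i, p in enumerate(positions)
    ]
    return Structure([("A", residues)])


class TestEnvAtom:
    def test_far_outside_contributes_nothing(self, geom):
        s = atom_structure((0, 0, 10 * geom.thickness))
        table = AtomTransferTable.default()
        assert abs(env_atom_score(s, geom, table)) < 1e-6 * abs(table.dg("aliphatic_C"))

    def test_center_contributes_full_transfer(self, geom):
        s = atom_structure((0, 0, 0))
        table = AtomTransferTable.default()
        assert env_atom_score(s, geom, table) == pytest.approx(table.dg("aliphatic_C"))

    def test_boundary_contributes_half(self, geom):
        s = atom_structure((0, 0, 15.0))
        table = AtomTransferTable.default()
        assert env_atom_score(s, geom, table) == pytest.approx(0.5 * table.dg("aliphatic_C"))

    def test_unknown_category_names_atom(self, geom):
        s = atom_structure((0, 0, 0))
        table = AtomTransferTable({"backbone": 0.0})
        with pytest.raises(KeyError, match="aliphatic_C"):
            env_atom_score(s, geom, table)

    def test_whole_structure_limits(self, helix21, geom):
        far = helix21.copy()
        far.set_coords(far.coords() + np.array([0, 0, 500.0]))
        assert abs(env_atom_score(far, geom)) < 1e-6


class TestSolvation:
    def test_isolated_atom_zero(self, geom):
        assert solvation_score(atom_structure((0, 0, 0)), geom) == 0.0

    def test_two_atom_closed_form(self, geom):
        """Deep-membrane vs bulk-water pair differ by the reference scaling."""
        params = SolvationParams.default()
        r = 4.0
        deep = atom_structure((0, 0, 0), (r, 0, 0))
        water = atom_structure((0, 0, 400.0), (r, 0, 400.0))
        lam = params.lam["aliphatic_C"]
        rad = params.radius["aliphatic_C"]
        vol = params.volume["aliphatic_C"]
        occl = np.exp(-(((r - rad) / lam) ** 2)) / (2 * np.pi**1.5 * lam * r**2) * vol

        def expected(dgref):
            return 2 * (-dgref * occl)

        assert solvation_score(deep, geom, params) == pytest.approx(
            expected(params.dgfree_memb["aliphatic_C"]), rel=1e-9
        )
        assert solvation_score(water, geom, params) == pytest.approx(
            expected(params.dgfree_water["aliphatic_C"]), rel=1e-6
        )

    def test_continuous_in_depth(self, geom):
        """No jumps along a dense z-scan of a two-atom probe."""
        vals = []
        for z in np.arange(-40, 40.01, 0.25):
            s = atom_structure((0, 0, z), (4.0, 0, z))
            vals.append(solvation_score(s, geom))
        steps = np.abs(np.diff(vals))
        assert np.max(steps) < 0.05


class TestHbond:
    def test_weight_outside_is_one(self, geom):
        assert hbond_depth_weight(geom, 200.0, 201.0) == pytest.approx(1.0, abs=1e-9)

    def test_weight_at_center_is_w_memb(self, geom):
        assert hbond_depth_weight(geom, 0.0, 0.0, w_memb=2.0) == pytest.approx(2.0)

    def test_weight_at_boundary(self, geom):
        # z_mid = T/2: f = 1/2, weight = (1 + w_memb) / 2
        assert hbond_depth_weight(geom, 15.0, 15.0, 2.0) == pytest.approx(1.5)

    def test_invalid_w_memb(self, geom):
        with pytest.raises(ValueError):
            hbond_depth_weight(geom, 0, 0, 0.5)

    def test_helix_backbone_ladder(self, helix21, geom):
        """An ideal helix forms roughly one i,i+4 bond per non-terminal residue."""
        e = hbond_score(helix21, geom)
        n_bonds = -e / 2.0  # every bond near z=0..15 carries weight <= 2
        assert 10 <= n_bonds <= 21

    def test_membrane_strengthens_helix_ladder(self, helix21, geom):
        inside = hbond_score(helix21, geom)
        far = helix21.copy()
        far.set_coords(far.coords() + np.array([0, 0, 500.0]))
        outside = hbond_score(far, geom)
        assert inside < outside < 0


class TestPacking:
    def test_beyond_contact_negligible(self):
        vdw = VdwParams.default()
        sigma = 2 * vdw.radius["aliphatic_C"]
        att, rep = packing_score(atom_structure((0, 0, 0), (3 * sigma, 0, 0)),
                                 pair_cutoff=12.0)
        assert rep == 0.0
        assert abs(att) < 0.01

    def test_zero_repulsion_at_contact(self):
        vdw = VdwParams.default()
        sigma = 2 * vdw.radius["aliphatic_C"]
        eps = vdw.epsilon["aliphatic_C"]
        att, rep = packing_score(atom_structure((0, 0, 0), (sigma, 0, 0)))
        assert rep == 0.0
        assert att == pytest.approx(-eps, rel=1e-9)

    def test_overlap_matches_closed_form(self):
        vdw = VdwParams.default()
        sigma = 2 * vdw.radius["aliphatic_C"]
        eps = vdw.epsilon["aliphatic_C"]
        r = 0.7 * sigma
        att, rep = packing_score(atom_structure((0, 0, 0), (r, 0, 0)))
        s6 = (sigma / r) ** 6
        assert rep == pytest.approx(eps * (s6**2 - 2 * s6 + 1), rel=1e-9)
        assert att == pytest.approx(-eps, rel=1e-9)

    def test_capped_below_point_six_sigma(self):
        vdw = VdwParams.default()
        sigma = 2 * vdw.radius["aliphatic_C"]
        _, rep_035 = packing_score(atom_structure((0, 0, 0), (0.35 * sigma, 0, 0)))
        _, rep_030 = packing_score(atom_structure((0, 0, 0), (0.30 * sigma, 0, 0)))
        # linear growth below the cap, not the 1/r^12 explosion
        assert rep_030 > rep_035
        assert (rep_030 - rep_035) < 10 * rep_035


class TestResidueTables:
    def test_zero_table_scores_zero(self, helix21, geom):
        assert env_residue_score(helix21, geom, ResidueDepthTable.zero()) == 0.0

    def test_delta_table_counts_single_cell(self, geom):
        h = build_helix(FixtureSpec(n_res=21, sequence="A" * 10 + "L" + "A" * 10))
        table = ResidueDepthTable.zero()
        leu = h.residue("A", 11)
        row = table.aas.index("LEU")
        col = table.bin_of(leu.ca[2])
        vals = table.values.copy()
        vals[row, col] = -1.0
        table = ResidueDepthTable(table.aas, table.z_min, table.bin_width, vals)
        assert env_residue_score(h, geom, table) == pytest.approx(-1.0)

    def test_random_table_matches_brute_force(self, helix21, geom):
        rng = np.random.default_rng(12)
        table = ResidueDepthTable(
            ResidueDepthTable.zero().aas, -36.0, 2.0, rng.normal(size=(20, 36))
        )
        expected = sum(
            table.lookup(r.aa, float(np.dot(r.ca - geom.center, geom.normal)))
            for r in helix21.residues()
        )
        assert env_residue_score(helix21, geom, table) == pytest.approx(expected, rel=1e-12)

    def test_pair_zero_default(self, helix21, geom):
        assert pair_score(helix21, geom, PairDepthTable()) == 0.0

    def test_pair_single_cell(self, geom):
        s = atom_structure((0, 0, 0), (5.0, 0, 0), aa="ALA")
        table = PairDepthTable(values={("ALA", "ALA", 2, 6): -2.5})
        assert pair_score(s, geom, table) == pytest.approx(-2.5)

    def test_pair_random_matches_double_loop(self, helix21, geom):
        rng = np.random.default_rng(13)
        values = {
            ("ALA", "ALA", db, zb): float(rng.normal())
            for db in range(8) for zb in range(12)
        }
        table = PairDepthTable(values=values)
        residues = list(helix21.residues())
        expected = 0.0
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                cb_i = residues[i].atom("CB").pos
                cb_j = residues[j].atom("CB").pos
                z = 0.5 * (cb_i[2] + cb_j[2])
                expected += table.lookup("ALA", "ALA",
                                         float(np.linalg.norm(cb_i - cb_j)), z)
        assert pair_score(helix21, geom, table) == pytest.approx(expected, rel=1e-12)

    def test_cbeta_zero_default(self, helix21):
        assert cbeta_score(helix21, CbetaTable()) == 0.0

    def test_cbeta_counts_neighbors(self, helix21):
        table = CbetaTable(values=tuple(float(i) for i in range(30)))
        cbs = np.array([r.atom("CB").pos for r in helix21.residues()])
        d = np.linalg.norm(cbs[:, None] - cbs[None, :], axis=-1)
        counts = ((d < 10.0) & (d > 0)).sum(axis=1)
        expected = float(sum(min(c, 29) for c in counts))
        assert cbeta_score(helix21, table) == pytest.approx(expected)


class TestPenalties:
    def test_ideal_helix_clean(self, helix21, geom, helix_topology):
        nonhelix, termini, tmproj = penalty_scores(helix21, geom, helix_topology)
        assert (nonhelix, termini, tmproj) == (0.0, 0.0, 0.0)

    def test_forced_loop_labels_counted(self, helix21, geom, helix_topology):
        ss = ["H"] * helix21.n_residues
        span = helix_topology.spans[0]
        core = [r.seq_id for r in helix21.chain("A")
                if span.start <= r.seq_id <= span.end and abs(r.ca[2]) <= 15.0][:5]
        for seq_id in core:
            ss[seq_id - 1] = "L"
        nonhelix, _, _ = penalty_scores(helix21, geom, helix_topology, ss)
        assert nonhelix == 5.0

    def test_projection_penalty_from_long_helix(self, geom):
        h = build_helix(FixtureSpec(n_res=27))
        topo = detect_spans(h, geom)
        span = topo.spans[0]
        z0 = abs(h.residue("A", span.start).ca[2])
        z1 = abs(h.residue("A", span.end).ca[2])
        expected = max(0.0, z0 - 15.0) + max(0.0, z1 - 15.0)
        _, _, tmproj = penalty_scores(h, geom, topo)
        assert tmproj == pytest.approx(expected, abs=1e-9)

    def test_termini_inside_layer(self, geom):
        h = build_helix(FixtureSpec(n_res=8))  # short helix entirely inside
        _, termini, _ = penalty_scores(h, geom, None)
        assert termini == 2.0

    def test_termini_literal_reading_switch(self, helix21, geom):
        _, termini_out, _ = penalty_scores(helix21, geom, None, termini_outside=True)
        assert termini_out == 2.0  # both ends project past the slab boundary

    def test_ss_length_mismatch(self, helix21, geom, helix_topology):
        with pytest.raises(ValueError):
            penalty_scores(helix21, geom, helix_topology, ss=["H"] * 3)


class TestTotalScore:
    def test_all_zero_weights(self, helix21, geom, helix_topology):
        bd = total_score(helix21, geom, helix_topology, ScoreWeights.only())
        assert bd.total == 0.0

    def test_weight_linearity(self, helix21, geom, helix_topology):
        w1 = ScoreWeights.only(env_atom=1.0, packing=1.0)
        w2 = ScoreWeights.only(env_atom=2.0, packing=1.0)
        b1 = total_score(helix21, geom, helix_topology, w1)
        b2 = total_score(helix21, geom, helix_topology, w2)
        assert b2.total - b1.total == pytest.approx(b1.values["env_atom"], rel=1e-9)
        assert b1.values["packing"] == b2.values["packing"]

    def test_total_is_weighted_sum(self, helix21, geom, helix_topology):
        bd = total_score(helix21, geom, helix_topology)
        recomputed = sum(bd.weights.get(t) * v for t, v in bd.values.items())
        assert bd.total == pytest.approx(recomputed, abs=1e-9)

    def test_reproducible_bitwise(self, helix21, geom, helix_topology):
        b1 = total_score(helix21, geom, helix_topology)
        b2 = total_score(helix21, geom, helix_topology)
        assert b1.values == b2.values and b1.total == b2.total

    def test_lowres_term_set(self, helix21, geom, helix_topology):
        bd = total_score(helix21, geom, helix_topology, mode="lowres")
        assert set(bd.values) == {"env_res", "pair", "cbeta", "nonhelix", "termini", "tmproj"}

    def test_unknown_mode_rejected(self, helix21, geom):
        with pytest.raises(ValueError):
            total_score(helix21, geom, None, mode="midres")

    @pytest.mark.parametrize("mode", ["highres", "lowres"])
    def test_rigid_invariance_all_terms(self, helix21, geom, helix_topology, mode):
        ref = total_score(helix21, geom, helix_topology, mode=mode)
        rng = np.random.default_rng(31)
        for _ in range(50):
            t = random_rigid_transform(rng)
            moved = total_score(
                apply_transform(helix21, t), apply_transform(geom, t),
                helix_topology, mode=mode,
            )
            for term, value in ref.values.items():
                assert moved.values[term] == pytest.approx(value, abs=1e-6), term

    def test_infinite_separation_additivity(self, helix21, geom):
        a = helix21.copy()
        b = helix21.copy()
        b.chains = [("B", b.chains[0][1])]
        for r in b.chains[0][1]:
            r.chain = "B"
        b.set_coords(b.coords() + np.array([500.0, 0.0, 0.0]))
        combined = Structure(a.copy().chains + b.copy().chains)
        e_ab = total_score(combined, geom).total
        e_a = total_score(a, geom).total
        e_b = total_score(b, geom).total
        assert e_ab == pytest.approx(e_a + e_b, abs=1e-6)


def test_unknown_weight_term_rejected():
    with pytest.raises(ValueError):
        ScoreWeights({"bogus_term": 1.0})


def test_table_text_round_trips():
    table = AtomTransferTable.default()
    again = AtomTransferTable.from_text(table.to_text())
    assert again.values == table.values
    env = ResidueDepthTable.hydrophobicity_default()
    env2 = ResidueDepthTable.from_text(env.to_text())
    assert env2.aas == env.aas
    assert np.allclose(env2.values, env.values, atol=1e-6)
    pair = PairDepthTable(values={("ALA", "LEU", 1, 2): -0.5})
    assert PairDepthTable.from_text(pair.to_text()).values == pair.values
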