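"""Protocol contracts: rotamer trials, ddG, relax, docking, symmetric assembly."""

import numpy as np
import pytest

from mpslab import (
    FixtureSpec,
    MembraneGeometry,
    ProtocolConfig,
    Structure,
    best_model,
    build_helix,
    compute_ddg,
    detect_spans,
    dock,
    docking_partners,
    relax_lite,
    repack_sidechains,
    symdock,
)
from mpslab.core import Atom, Residue, hydration_fraction, signed_depth, rotation_about_axis
from mpslab.embedding import EmbeddingSearchConfig, set_membrane_position
from mpslab.protocols import replicate_cn
from mpslab.scoring import total_score
from mpslab.sidechains import chi_angles, rotamer_chi_sets
from mpslab.tables import AtomTransferTable, ScoreWeights

ENV_ONLY = ScoreWeights.only(env_atom=1.0)
ENV_CFG = ProtocolConfig(weights=ENV_ONLY)
ZERO_MOVE = ProtocolConfig(mc_cycles=0, quench_cycles=0, init_scale=0.0)


def env_sidechain_sum(structure, geom, position):
    """Independent transfer-energy arithmetic over one side chain's atoms."""
    table = AtomTransferTable.default()
    res = structure.residue(*position)
    total = 0.0
    for a in res.atoms:
        if a.name in ("N", "CA", "C", "O"):
            continue
        z = signed_depth(geom, a.pos)
        total += (1.0 - hydration_fraction(geom, z)) * table.dg(a.category)
    return total


class TestRepack:
    def test_empty_movable_set_is_identity(self, helix21, geom):
        score = lambda s: total_score(s, geom).total
        out = repack_sidechains(helix21, set(), score, seed=1)
        assert np.array_equal(out.coords(), helix21.coords())

    def test_matches_exhaustive_enumeration(self, geom):
        """Single leucine near a clashing probe: trials find the same rotamer
        as brute-force enumeration of the whole candidate set."""
        h = build_helix(FixtureSpec(n_res=15, sequence="A" * 7 + "L" + "A" * 7))
        leu = h.residue("A", 8)
        probe_pos = leu.atom("CD1").pos + np.array([0.4, 0.0, 0.0])
        probe = Residue(1, "X", "ALA", [Atom("CB", "C", probe_pos, "aliphatic_C")])
        clashed = Structure(h.copy().chains + [("X", [probe])])
        score = lambda s: total_score(s, geom).total
        out = repack_sidechains(clashed, {("A", 8)}, score, seed=0)
        best_chis, best_score = None, np.inf
        for cand in rotamer_chi_sets("LEU") + [chi_angles(clashed.residue("A", 8))]:
            trial = clashed.copy()
            from mpslab.sidechains import place_side_chain
            place_side_chain(trial.residue("A", 8), "LEU", tuple(cand))
            s = score(trial)
            if s < best_score:
                best_chis, best_score = tuple(cand), s
        got = np.asarray(chi_angles(out.residue("A", 8)))
        diff = (got - np.asarray(best_chis) + 180.0) % 360.0 - 180.0
        assert np.allclose(diff, 0.0, atol=1e-6)
        assert score(out) <= score(clashed) + 1e-12

    def test_deterministic(self, geom):
        h = build_helix(FixtureSpec(n_res=15, sequence="A" * 7 + "R" + "A" * 7))
        score = lambda s: total_score(s, geom).total
        out1 = repack_sidechains(h, {("A", 8)}, score, seed=5)
        out2 = repack_sidechains(h, {("A", 8)}, score, seed=5)
        assert np.array_equal(out1.coords(), out2.coords())


@pytest.fixture(scope="module")
def leu_helix():
    return build_helix(FixtureSpec(n_res=21, sequence="A" * 10 + "L" + "A" * 10))


class TestDdg:
    def test_identity_mutation_exactly_zero(self, leu_helix, geom):
        topo = detect_spans(leu_helix, geom)
        r = compute_ddg(leu_helix, geom, topo, ("A", 11), "LEU", ENV_CFG, seed=2)
        assert r.ddg == 0.0

    def test_env_only_matches_transfer_arithmetic(self, leu_helix, geom):
        topo = detect_spans(leu_helix, geom)
        r = compute_ddg(leu_helix, geom, topo, ("A", 11), "ARG", ENV_CFG, seed=2)
        oracle = env_sidechain_sum(r.structure_mutant, geom, ("A", 11)) - \
            env_sidechain_sum(r.structure_native, geom, ("A", 11))
        assert r.ddg == pytest.approx(oracle, abs=1e-6)
        # near the slab center the hydration factor is ~0, so the plain
        # table-sum difference is a close approximation
        table = AtomTransferTable.default()
        plain = (4 * table.dg("aliphatic_C") + 3 * table.dg("guanidinium_N")) - (
            4 * table.dg("aliphatic_C")
        )
        assert r.ddg == pytest.approx(plain, abs=0.05)

    def test_far_outside_membrane_is_neutral(self, leu_helix, geom):
        far = leu_helix.copy()
        far.set_coords(far.coords() + np.array([0.0, 0.0, 300.0]))
        r = compute_ddg(far, geom, None, ("A", 11), "ARG", ENV_CFG, seed=2)
        assert abs(r.ddg) < 1e-3

    def test_antisymmetry(self, leu_helix, geom):
        topo = detect_spans(leu_helix, geom)
        fwd = compute_ddg(leu_helix, geom, topo, ("A", 11), "ARG", ENV_CFG, seed=2)
        arg_helix = build_helix(FixtureSpec(n_res=21, sequence="A" * 10 + "R" + "A" * 10))
        rev = compute_ddg(arg_helix, geom, detect_spans(arg_helix, geom),
                          ("A", 11), "LEU", ENV_CFG, seed=2)
        assert fwd.ddg == pytest.approx(-rev.ddg, abs=1e-6)

    def test_breakdown_difference_invariant(self, leu_helix, geom):
        topo = detect_spans(leu_helix, geom)
        r = compute_ddg(leu_helix, geom, topo, ("A", 11), "TRP", seed=0)
        assert r.ddg == pytest.approx(
            r.breakdown_mutant.total - r.breakdown_native.total, abs=1e-9
        )


class TestRelax:
    def test_monotone_and_recovers_shift(self, helix_polyL, geom):
        shifted = helix_polyL.copy()
        shifted.set_coords(shifted.coords() + np.array([0.0, 0.0, 5.0]))
        topo = detect_spans(shifted, geom, require_crossing=False)
        search = EmbeddingSearchConfig(tilt_range_deg=0.0)
        res = relax_lite(shifted, geom, topo, n_cycles=3, cfg=ENV_CFG,
                         search_cfg=search)
        assert all(b - a >= -1e-9 for a, b in zip(res.cycle_totals, res.cycle_totals[1:])) \
            or np.all(np.diff(res.cycle_totals) <= 1e-9)
        # 1-D scan oracle for the optimal membrane offset, evaluated on the
        # final (repacked) structure the relax produced
        zs = np.arange(-10.0, 10.001, 0.1)
        scores = [
            total_score(res.structure,
                        set_membrane_position(geom, np.array([0, 0, z]), geom.normal),
                        topo, ENV_ONLY).total
            for z in zs
        ]
        z_oracle = zs[int(np.argmin(scores))]
        assert abs(res.geometry.center[2] - z_oracle) < 0.5

    def test_fixed_point_of_optimized_input(self, helix_polyL, geom):
        topo = detect_spans(helix_polyL, geom)
        search = EmbeddingSearchConfig(tilt_range_deg=0.0)
        first = relax_lite(helix_polyL, geom, topo, n_cycles=1, cfg=ENV_CFG,
                           search_cfg=search)
        second = relax_lite(first.structure, first.geometry, topo, n_cycles=1,
                            cfg=ENV_CFG, search_cfg=search)
        assert abs(second.breakdown.total - first.breakdown.total) < 1e-6
        assert np.linalg.norm(second.geometry.center - first.geometry.center) < 0.1


class TestDock:
    def test_native_scores_negative_and_repeats(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        m1 = dock(fixed, moving, geom, n_models=1, seed=0, cfg=ZERO_MOVE)[0]
        m2 = dock(fixed, moving, geom, n_models=1, seed=0, cfg=ZERO_MOVE)[0]
        assert m1.interface_score < 0
        assert m1.interface_score == m2.interface_score
        assert np.array_equal(m1.structure.coords(), m2.structure.coords())
        assert m1.ligand_rmsd < 1e-9

    def test_separated_partners_score_zero(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        apart = moving.copy()
        apart.set_coords(apart.coords() + np.array([0.0, 500.0, 0.0]))
        m = dock(fixed, apart, geom, n_models=1, seed=0, cfg=ZERO_MOVE, prepack=False)[0]
        assert abs(m.interface_score) < 1e-6

    def test_interface_score_equals_recomputation(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        m = dock(fixed, moving, geom, n_models=1, seed=4,
                 cfg=ProtocolConfig(mc_cycles=5, quench_cycles=2))[0]
        complex_e = total_score(m.structure, geom).total
        apart = m.structure.copy()
        for r in apart.residues():
            if r.chain == "B":
                for a in r.atoms:
                    a.pos = a.pos + 500.0 * np.array([0.0, 1.0, 0.0])
        sep_e = total_score(apart, geom).total
        assert m.interface_score == pytest.approx(complex_e - sep_e, abs=1e-9)

    def test_models_reproducible_for_fixed_seed(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        a = dock(fixed, moving, geom, n_models=2, seed=9)
        b = dock(fixed, moving, geom, n_models=2, seed=9)
        for ma, mb in zip(a, b):
            assert ma.interface_score == mb.interface_score
            assert np.array_equal(ma.structure.coords(), mb.structure.coords())

    def test_zero_temperature_accepts_only_improvements(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        cfg = ProtocolConfig(kT=0.0, mc_cycles=40, quench_cycles=0)
        m = dock(fixed, moving, geom, n_models=1, seed=3, cfg=cfg)[0]
        for delta, accepted in m.trace:
            if accepted:
                assert delta <= 0

    def test_infinite_temperature_accepts_everything(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        cfg = ProtocolConfig(kT=1e9, mc_cycles=1000, quench_cycles=0)
        m = dock(fixed, moving, geom, n_models=1, seed=3, cfg=cfg)[0]
        mc_trace = m.trace[:1000]
        rate = sum(1 for _, ok in mc_trace if ok) / len(mc_trace)
        assert rate > 0.95

    def test_invalid_model_count(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        with pytest.raises(ValueError):
            dock(fixed, moving, geom, n_models=0)

    def test_best_model_tie_breaking(self, dimer_native, geom):
        fixed, moving = docking_partners(dimer_native)
        models = dock(fixed, moving, geom, n_models=3, seed=1,
                      cfg=ProtocolConfig(mc_cycles=3, quench_cycles=0))
        bm = best_model(models)
        assert bm.interface_score == min(m.interface_score for m in models)


class TestSymdock:
    def test_order_one_interface_is_zero(self, geom):
        helix = build_helix(FixtureSpec(n_res=15))
        m = symdock(helix, 1, geom, seed=0, n_models=1, cfg=ZERO_MOVE)[0]
        assert abs(m.interface_score) < 1e-6

    def test_symmetry_maintained_after_moves(self, bundle_c4_native, geom):
        asym = Structure([bundle_c4_native.copy().chains[0]])
        m = symdock(asym, 4, geom, seed=5, n_models=1,
                    cfg=ProtocolConfig(mc_cycles=20, quench_cycles=5))[0]
        coords = m.structure.coords().reshape(4, -1, 3)
        R = rotation_about_axis(geom.normal, 2 * np.pi / 4)
        for k in range(1, 4):
            expected = coords[k - 1] @ R.T
            assert np.max(np.abs(coords[k] - expected)) < 1e-8

    def test_replicate_cn_exact(self, geom):
        helix = build_helix(FixtureSpec(n_res=10))
        helix.set_coords(helix.coords() + np.array([6.0, 0.0, 0.0]))
        complex_structure = replicate_cn(helix, 3, geom)
        coords = complex_structure.coords().reshape(3, -1, 3)
        R = rotation_about_axis(geom.normal, 2 * np.pi / 3)
        assert np.max(np.abs(coords[1] - coords[0] @ R.T)) < 1e-9

    def test_interface_equals_cumulative_recomputation(self, bundle_c4_native, geom):
        asym = Structure([bundle_c4_native.copy().chains[0]])
        m = symdock(asym, 4, geom, seed=1, n_models=1,
                    cfg=ProtocolConfig(mc_cycles=5, quench_cycles=0))[0]
        sub = Structure([m.structure.copy().chains[0]])
        e_complex = total_score(m.structure, geom).total
        e_sub = total_score(sub, geom).total
        assert m.interface_score == pytest.approx(e_complex - 4 * e_sub, abs=1e-9)

    def test_deterministic(self, bundle_c4_native, geom):
        asym = Structure([bundle_c4_native.copy().chains[0]])
        cfg = ProtocolConfig(mc_cycles=10, quench_cycles=3)
        a = symdock(asym, 4, geom, seed=7, n_models=1, cfg=cfg)[0]
        b = symdock(asym, 4, geom, seed=7, n_models=1, cfg=cfg)[0]
        assert a.interface_score == b.interface_score
        assert np.array_equal(a.structure.coords(), b.structure.coords())
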