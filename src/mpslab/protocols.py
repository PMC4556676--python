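"""The four membrane protocols: ddG of mutation, embedding-optimizing
refinement, membrane-constrained protein-protein docking, and C_n symmetric
assembly.

All protocols are deterministic given (inputs, seed, config).  Docking keeps
the membrane fixed and moves one partner with membrane-constrained rigid
moves (in-plane translation, spin about the membrane normal, small tilt,
depth shift) under Metropolis Monte Carlo; symmetric assembly moves the
asymmetric unit and propagates every move exactly to all C_n copies.
Interface scores are energy differences against the partners separated far
in the membrane plane at fixed internal conformation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MembraneGeometry,
    Structure,
    rotation_about_axis,
    superpose,
)
from .embedding import EmbeddingSearchConfig, optimize_embedding
from .sidechains import chi_angles, place_side_chain, mutate_residue, rotamer_chi_sets
from .scoring import AtomFrame, ScoreBreakdown, total_from_frame, total_score
from .tables import ScoreTables, ScoreWeights, default_tables
from .topology import SpanningTopology

__all__ = [
    "ProtocolConfig",
    "DdgResult",
    "DockModel",
    "RelaxResult",
    "repack_sidechains",
    "compute_ddg",
    "relax_lite",
    "dock",
    "symdock",
    "best_model",
    "interface_residues",
    "combine_structures",
    "replicate_cn",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Shared knobs for all protocols (documented defaults)."""

    weights: ScoreWeights = field(default_factory=ScoreWeights)
    tables: ScoreTables = field(default_factory=default_tables)
    mode: str = "highres"
    kT: float = 1.0                # Metropolis temperature (energy units)
    mc_cycles: int = 50            # low-amplitude MC proposals per model
    quench_cycles: int = 25        # greedy quench proposals per model
    trans_sigma: float = 0.7       # in-plane translation step (Å)
    spin_sigma: float = 3.0        # spin about membrane normal (deg)
    tilt_sigma: float = 2.0        # tilt about in-plane axis (deg)
    zshift_sigma: float = 0.25     # depth shift (Å)
    init_scale: float = 3.0        # initial perturbation, in units of sigma
    separation: float = 500.0      # partner separation for interface scoring (Å)
    shell_radius: float = 8.0      # repack shell / interface radius (Å)
    relax_cycles: int = 8          # repack+embedding cycles in relax_lite
    max_repack_passes: int = 5
    slide_step: float = 0.25       # radial slide-into-contact step (Å)
    slide_max: float = 12.0        # maximum slide distance (Å)

    def total(self, structure, geom, topology=None):
        return total_score(structure, geom, topology, self.weights, self.tables, self.mode)


@dataclass(frozen=True)
class DdgResult:
    """Fixed-backbone ddG of one point mutation.

    Carries the repacked native and mutant structures so callers can inspect
    side-chain placements (e.g. snorkeling of long charged side chains).
    """

    position: tuple[str, int]
    native_aa: str
    target_aa: str
    ddg: float
    breakdown_native: ScoreBreakdown
    breakdown_mutant: ScoreBreakdown
    structure_native: Structure | None = None
    structure_mutant: Structure | None = None


@dataclass
class DockModel:
    """One docked/assembled pose with score, RMSD and provenance."""

    structure: Structure
    interface_score: float
    total: float
    ligand_rmsd: float
    seed: int
    model_id: int
    accepted_moves: int
    trace: list[tuple[float, bool]] = field(default_factory=list, repr=False)


@dataclass
class RelaxResult:
    structure: Structure
    geometry: MembraneGeometry
    breakdown: ScoreBreakdown
    cycle_totals: list[float]


# ---------------------------------------------------------------------------
# side-chain repacking


def repack_sidechains(
    structure: Structure,
    movable: set[tuple[str, int]],
    score_fn,
    rotamers=None,
    seed: int = 0,
    max_passes: int = 5,
) -> Structure:
    """Iterative single-residue rotamer trials over a discrete conformer set.

    Visits movable residues in a seed-shuffled order; a substitution is
    accepted only if it strictly improves ``score_fn``.  Stops when a full
    pass changes nothing.  The input conformation of every residue is always
    among the candidates, so the final score never exceeds the initial one.
    """
    out = structure.copy()
    keys = sorted(movable)
    rng = np.random.default_rng(seed)
    current = score_fn(out)
    for _ in range(max_passes):
        changed = False
        order = list(rng.permutation(len(keys)))
        for idx in order:
            chain, seq_id = keys[idx]
            res = out.residue(chain, seq_id)
            chi_sets = rotamers(res.aa) if rotamers is not None else rotamer_chi_sets(res.aa)
            if not chi_sets:
                continue
            saved = [a.pos.copy() for a in res.atoms]
            best_chis, best_score = None, current
            for cand in chi_sets:
                place_side_chain(res, res.aa, cand)
                s = score_fn(out)
                if s < best_score - 1e-12:
                    best_chis, best_score = cand, s
            if best_chis is None:  # keep the exact input conformation
                for a, p in zip(res.atoms, saved):
                    a.pos = p
            else:
                place_side_chain(res, res.aa, best_chis)
                current = best_score
                changed = True
        if not changed:
            break
    return out


def _repack_frame(
    structure: Structure,
    movable: set[tuple[str, int]],
    geom: MembraneGeometry,
    topology: SpanningTopology | None,
    cfg: ProtocolConfig,
    seed: int = 0,
) -> Structure:
    """Rotamer trials evaluated through a single reusable AtomFrame.

    Chi rotations never change atom identity or connectivity, so the frame's
    exclusion and donor/acceptor data stay valid and only coordinates are
    synced per candidate.  Semantics match :func:`repack_sidechains`.
    """
    out = structure.copy()
    frame = AtomFrame(out)
    rows: dict[tuple[str, int], tuple] = {}
    i = 0
    for r in out.residues():
        rows[(r.chain, r.seq_id)] = (r, list(range(i, i + len(r.atoms))))
        i += len(r.atoms)

    def sync(res, idxs):
        for row, a in zip(idxs, res.atoms):
            frame.coords[row] = a.pos

    keys = sorted(movable)
    rng = np.random.default_rng(seed)
    current = _frame_total(frame, geom, topology, cfg)
    for _ in range(cfg.max_repack_passes):
        changed = False
        for idx in rng.permutation(len(keys)):
            res, idxs = rows[keys[idx]]
            chi_sets = rotamer_chi_sets(res.aa)
            if not chi_sets:
                continue
            saved = [a.pos.copy() for a in res.atoms]
            best_chis, best_score = None, current
            for cand in chi_sets:
                place_side_chain(res, res.aa, cand)
                sync(res, idxs)
                s = _frame_total(frame, geom, topology, cfg)
                if s < best_score - 1e-12:
                    best_chis, best_score = cand, s
            if best_chis is None:
                for a, p in zip(res.atoms, saved):
                    a.pos = p
            else:
                place_side_chain(res, res.aa, best_chis)
                current = best_score
                changed = True
            sync(res, idxs)
        if not changed:
            break
    return out


# ---------------------------------------------------------------------------
# ddG of mutation


def _shell_around(structure: Structure, chain: str, seq_id: int, radius: float):
    target = structure.residue(chain, seq_id)
    tpos = np.array([a.pos for a in target.atoms])
    shell = set()
    for r in structure.residues():
        pos = np.array([a.pos for a in r.atoms])
        d = np.linalg.norm(pos[:, None, :] - tpos[None, :, :], axis=-1)
        if np.min(d) <= radius:
            shell.add((r.chain, r.seq_id))
    return shell


def compute_ddg(
    structure: Structure,
    geom: MembraneGeometry,
    topology: SpanningTopology | None,
    position: tuple[str, int],
    target_aa: str,
    cfg: ProtocolConfig | None = None,
    seed: int = 0,
) -> DdgResult:
    """Fixed-backbone ddG = E(mutant) - E(native) after identical repacking.

    The mutated position is rebuilt with idealized side-chain geometry in
    both branches (so an identity mutation gives exactly zero), then all
    residues with any heavy atom within ``shell_radius`` of the mutated
    residue are repacked with the same seed and protocol in both branches.
    """
    cfg = cfg if cfg is not None else ProtocolConfig()
    chain, seq_id = position
    native_aa = structure.residue(chain, seq_id).aa
    native = mutate_residue(structure, chain, seq_id, native_aa)
    mutant = mutate_residue(structure, chain, seq_id, target_aa)
    shell = _shell_around(native, chain, seq_id, cfg.shell_radius) | _shell_around(
        mutant, chain, seq_id, cfg.shell_radius
    )
    native_rp = _repack_frame(native, shell, geom, topology, cfg, seed)
    mutant_rp = _repack_frame(mutant, shell, geom, topology, cfg, seed)
    b_nat = cfg.total(native_rp, geom, topology)
    b_mut = cfg.total(mutant_rp, geom, topology)
    return DdgResult(position, native_aa, target_aa, b_mut.total - b_nat.total,
                     b_nat, b_mut, native_rp, mutant_rp)


# ---------------------------------------------------------------------------
# relax


def relax_lite(
    structure: Structure,
    geom: MembraneGeometry,
    topology: SpanningTopology,
    n_cycles: int | None = None,
    cfg: ProtocolConfig | None = None,
    seed: int = 0,
    search_cfg: EmbeddingSearchConfig | None = None,
) -> RelaxResult:
    """Alternating full side-chain repack and membrane embedding optimization.

    Each cycle repacks every residue at the current membrane placement, then
    re-optimizes the membrane against the new side chains; the total score is
    monotone non-increasing across cycles.
    """
    cfg = cfg if cfg is not None else ProtocolConfig()
    n_cycles = n_cycles if n_cycles is not None else cfg.relax_cycles
    work = structure.copy()
    current_geom = geom
    movable = {(r.chain, r.seq_id) for r in work.residues()}
    totals: list[float] = []
    emb_score = lambda s, g, t: cfg.total(s, g, t)
    for cycle in range(n_cycles):
        work = _repack_frame(work, movable, current_geom, topology, cfg, seed + cycle)
        current_geom, breakdown = optimize_embedding(
            work, current_geom, topology, emb_score, search_cfg
        )
        totals.append(breakdown.total)
    return RelaxResult(work, current_geom, cfg.total(work, current_geom, topology), totals)


# ---------------------------------------------------------------------------
# docking helpers


def combine_structures(fixed: Structure, moving: Structure) -> Structure:
    ids = [cid for cid, _ in fixed.chains] + [cid for cid, _ in moving.chains]
    if len(ids) != len(set(ids)):
        raise ValueError("docking partners must use disjoint chain ids")
    merged = fixed.copy().chains + moving.copy().chains
    return Structure(merged)


def interface_residues(structure: Structure, group_a: set[str], group_b: set[str],
                       radius: float = 8.0) -> set[tuple[str, int]]:
    """Residues with any heavy-atom pair closer than ``radius`` across groups."""
    res_a = [r for r in structure.residues() if r.chain in group_a]
    res_b = [r for r in structure.residues() if r.chain in group_b]
    out: set[tuple[str, int]] = set()
    for ra in res_a:
        pa = np.array([a.pos for a in ra.atoms])
        for rb in res_b:
            pb = np.array([a.pos for a in rb.atoms])
            if np.min(np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)) <= radius:
                out.add((ra.chain, ra.seq_id))
                out.add((rb.chain, rb.seq_id))
    return out


def _in_plane_axes(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def _metropolis(delta: float, kT: float, rng: np.random.Generator) -> bool:
    if delta <= 0:
        return True
    if kT <= 0:
        return False
    return bool(rng.random() < np.exp(-min(delta / kT, 700.0)))


def _frame_total(frame: AtomFrame, geom, topology, cfg) -> float:
    return total_from_frame(frame, geom, topology, cfg.weights, cfg.tables, cfg.mode).total


class _RigidMover:
    """Membrane-constrained rigid moves of one atom block of a frame."""

    def __init__(self, frame: AtomFrame, mask: np.ndarray, geom: MembraneGeometry):
        self.frame = frame
        self.mask = mask
        self.geom = geom
        self.u, self.v = _in_plane_axes(geom.normal)

    def centroid(self, coords: np.ndarray) -> np.ndarray:
        return coords[self.mask].mean(axis=0)

    def translate(self, coords: np.ndarray, vec: np.ndarray) -> np.ndarray:
        out = coords.copy()
        out[self.mask] += vec
        return out

    def rotate(self, coords: np.ndarray, axis: np.ndarray, angle_deg: float,
               pivot: np.ndarray) -> np.ndarray:
        R = rotation_about_axis(axis, np.radians(angle_deg))
        out = coords.copy()
        out[self.mask] = pivot + (coords[self.mask] - pivot) @ R.T
        return out

    def propose(self, coords: np.ndarray, rng: np.random.Generator,
                scale: float, cfg: ProtocolConfig) -> np.ndarray:
        kind = int(rng.integers(4))
        pivot = self.centroid(coords)
        if kind == 0:  # in-plane translation
            dx, dy = rng.normal(0.0, scale * cfg.trans_sigma, size=2)
            return self.translate(coords, dx * self.u + dy * self.v)
        if kind == 1:  # spin about the membrane normal through the centroid
            ang = rng.normal(0.0, scale * cfg.spin_sigma)
            return self.rotate(coords, self.geom.normal, ang, pivot)
        if kind == 2:  # tilt about a random in-plane axis
            theta = rng.uniform(0.0, 2.0 * np.pi)
            axis = np.cos(theta) * self.u + np.sin(theta) * self.v
            ang = rng.normal(0.0, scale * cfg.tilt_sigma)
            return self.rotate(coords, axis, ang, pivot)
        dz = rng.normal(0.0, scale * cfg.zshift_sigma)
        return self.translate(coords, dz * self.geom.normal)


def _structure_from_frame(template: Structure, coords: np.ndarray) -> Structure:
    out = template.copy()
    out.set_coords(coords)
    return out


def _ligand_rmsd(model: Structure, reference: Structure, fixed_chains: set[str],
                 moving_chains: set[str]) -> float:
    """CA RMSD over the moving partner after superposing the fixed partner."""
    fixed_model = np.array([r.ca for r in model.residues() if r.chain in fixed_chains])
    fixed_ref = np.array([r.ca for r in reference.residues() if r.chain in fixed_chains])
    t, _ = superpose(fixed_model, fixed_ref)
    mov_model = np.array([r.ca for r in model.residues() if r.chain in moving_chains])
    mov_ref = np.array([r.ca for r in reference.residues() if r.chain in moving_chains])
    return float(np.sqrt(np.mean(np.sum((t.apply(mov_model) - mov_ref) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# protein-protein docking


def dock(
    fixed: Structure,
    moving: Structure,
    geom: MembraneGeometry,
    topologies: SpanningTopology | None = None,
    n_models: int = 1,
    seed: int = 0,
    cfg: ProtocolConfig | None = None,
    reference: Structure | None = None,
    prepack: bool = True,
) -> list[DockModel]:
    """Membrane-constrained local docking of ``moving`` onto ``fixed``.

    Prepack separates the partners 100 Å in the membrane plane, repacks
    their interface side chains, and restores the pose.  Each model then
    applies a seeded initial perturbation followed by Metropolis Monte Carlo
    over in-plane translations, spins about the membrane normal, small tilts
    and depth shifts of the moving partner only, a greedy quench, and a
    final interface repack.  The membrane stays fixed throughout.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    cfg = cfg if cfg is not None else ProtocolConfig()
    fixed_chains = {cid for cid, _ in fixed.chains}
    moving_chains = {cid for cid, _ in moving.chains}
    complex_structure = combine_structures(fixed, moving)
    reference = reference if reference is not None else complex_structure.copy()
    u, _ = _in_plane_axes(geom.normal)

    iface = interface_residues(complex_structure, fixed_chains, moving_chains,
                               cfg.shell_radius)
    if prepack and iface:
        apart = complex_structure.copy()
        for r in apart.residues():
            if r.chain in moving_chains:
                for a in r.atoms:
                    a.pos = a.pos + 100.0 * u
        apart = _repack_frame(apart, iface, geom, topologies, cfg, seed)
        for r in apart.residues():
            if r.chain in moving_chains:
                for a in r.atoms:
                    a.pos = a.pos - 100.0 * u
        complex_structure = apart

    frame = AtomFrame(complex_structure)
    mask = np.array(
        [frame.res_chain[ri] in moving_chains for ri in frame.res_index], dtype=bool
    )
    mover = _RigidMover(frame, mask, geom)
    C0 = frame.coords.copy()

    models: list[DockModel] = []
    for m in range(n_models):
        rng = np.random.default_rng([seed, m])
        coords = C0.copy()
        for _ in range(4):  # seeded initial perturbation (one larger move of each kind)
            coords = mover.propose(coords, rng, cfg.init_scale, cfg)
        frame.coords = coords
        current = _frame_total(frame, geom, topologies, cfg)
        trace: list[tuple[float, bool]] = []
        for _ in range(cfg.mc_cycles):
            cand = mover.propose(coords, rng, 1.0, cfg)
            frame.coords = cand
            s = _frame_total(frame, geom, topologies, cfg)
            ok = _metropolis(s - current, cfg.kT, rng)
            trace.append((s - current, ok))
            if ok:
                coords, current = cand, s
        for _ in range(cfg.quench_cycles):
            cand = mover.propose(coords, rng, 0.5, cfg)
            frame.coords = cand
            s = _frame_total(frame, geom, topologies, cfg)
            ok = s < current - 1e-12
            trace.append((s - current, ok))
            if ok:
                coords, current = cand, s
        model_structure = _structure_from_frame(complex_structure, coords)
        iface_final = interface_residues(model_structure, fixed_chains, moving_chains,
                                         cfg.shell_radius)
        if iface_final and any(
            rotamer_chi_sets(model_structure.residue(c, s_).aa) for c, s_ in iface_final
        ):
            model_structure = _repack_frame(model_structure, iface_final, geom,
                                            topologies, cfg, seed)
        mframe = AtomFrame(model_structure)
        total = _frame_total(mframe, geom, topologies, cfg)
        sep = mframe.coords.copy()
        sep[mask] += cfg.separation * u
        mframe.coords = sep
        total_sep = _frame_total(mframe, geom, topologies, cfg)
        interface = total - total_sep
        rmsd = _ligand_rmsd(model_structure, reference, fixed_chains, moving_chains)
        models.append(DockModel(model_structure, interface, total, rmsd, seed, m,
                                sum(1 for _, ok in trace if ok), trace))
    return models


def best_model(models: list[DockModel]) -> DockModel:
    """Lowest interface score; ties broken by total, then by model index."""
    return min(models, key=lambda m: (m.interface_score, m.total, m.model_id))


# ---------------------------------------------------------------------------
# symmetric assembly


def replicate_cn(asym_unit: Structure, n: int, geom: MembraneGeometry) -> Structure:
    """Build a C_n complex by rotating the asymmetric unit about the normal axis."""
    if n < 1:
        raise ValueError("symmetry order must be >= 1")
    if len(asym_unit.chains) != 1:
        raise ValueError("symmetric assembly expects a single-chain asymmetric unit")
    letters = string.ascii_uppercase
    chains = []
    base = asym_unit.copy()
    base_coords = base.coords()
    for k in range(n):
        R = rotation_about_axis(geom.normal, 2.0 * np.pi * k / n)
        sub = asym_unit.copy()
        cid = letters[k]
        sub.chains = [(cid, sub.chains[0][1])]
        for r in sub.chains[0][1]:
            r.chain = cid
        sub.set_coords(geom.center + (base_coords - geom.center) @ R.T)
        chains.append(sub.chains[0])
    return Structure(chains)


def symdock(
    asym_unit: Structure,
    n: int,
    geom: MembraneGeometry,
    seed: int = 0,
    n_models: int = 1,
    cfg: ProtocolConfig | None = None,
    reference: Structure | None = None,
) -> list[DockModel]:
    """C_n symmetric assembly around the membrane normal axis.

    The complex is generated by rotations of the asymmetric unit about the
    normal through the membrane center.  Monte-Carlo moves (radial
    translation, spin about the subunit's own axis, depth shift, tilt) are
    applied to subunit 0 and propagated exactly to all copies after every
    move, so symmetry is maintained to machine precision.  The interface
    score is E(complex) - n * E(isolated subunit), i.e. the cumulative score
    of all symmetric interfaces.
    """
    cfg = cfg if cfg is not None else ProtocolConfig()
    complex_structure = replicate_cn(asym_unit, n, geom)
    reference = reference if reference is not None else complex_structure.copy()
    frame = AtomFrame(complex_structure)
    n_sub_atoms = frame.n_atoms // n
    sub_frame = AtomFrame(asym_unit)
    rotations = [rotation_about_axis(geom.normal, 2.0 * np.pi * k / n) for k in range(n)]

    def propagate(sub_coords: np.ndarray) -> np.ndarray:
        rel = sub_coords - geom.center
        return np.concatenate([geom.center + rel @ R.T for R in rotations])

    def complex_total(sub_coords: np.ndarray) -> float:
        frame.coords = propagate(sub_coords)
        return _frame_total(frame, geom, None, cfg)

    def interface(sub_coords: np.ndarray) -> tuple[float, float]:
        total = complex_total(sub_coords)
        sub_frame.coords = sub_coords
        return total - n * _frame_total(sub_frame, geom, None, cfg), total

    mover = _RigidMover(sub_frame, np.ones(n_sub_atoms, dtype=bool), geom)
    S0 = asym_unit.coords()

    def radial_axis(coords: np.ndarray) -> np.ndarray:
        c = coords.mean(axis=0) - geom.center
        c -= np.dot(c, geom.normal) * geom.normal
        nc = np.linalg.norm(c)
        return c / nc if nc > 1e-9 else mover.u

    models: list[DockModel] = []
    for m in range(n_models):
        rng = np.random.default_rng([seed, m])
        coords = S0.copy()
        for _ in range(4):
            coords = mover.propose(coords, rng, cfg.init_scale, cfg)
        # slide into contact: greedy radial walk toward the symmetry axis
        current = complex_total(coords)
        if n > 1:
            inward = -radial_axis(coords)
            slid = 0.0
            while slid < cfg.slide_max:
                cand = coords + cfg.slide_step * inward
                s = complex_total(cand)
                if s >= current - 1e-12:
                    break
                coords, current, slid = cand, s, slid + cfg.slide_step
        def propose_sym(coords: np.ndarray, scale: float) -> np.ndarray:
            kind = int(rng.integers(4))
            pivot = coords.mean(axis=0)
            if kind == 0:  # radial translation
                dr = rng.normal(0.0, scale * cfg.trans_sigma)
                return coords + dr * radial_axis(coords)
            if kind == 1:  # spin about the subunit's own axis
                ang = rng.normal(0.0, scale * cfg.spin_sigma)
                R = rotation_about_axis(geom.normal, np.radians(ang))
                return pivot + (coords - pivot) @ R.T
            if kind == 2:  # tilt
                theta = rng.uniform(0.0, 2.0 * np.pi)
                axis = np.cos(theta) * mover.u + np.sin(theta) * mover.v
                ang = rng.normal(0.0, scale * cfg.tilt_sigma)
                R = rotation_about_axis(axis, np.radians(ang))
                return pivot + (coords - pivot) @ R.T
            return coords + rng.normal(0.0, scale * cfg.zshift_sigma) * geom.normal

        trace: list[tuple[float, bool]] = []
        for _ in range(cfg.mc_cycles):
            cand = propose_sym(coords, 1.0)
            s = complex_total(cand)
            ok = _metropolis(s - current, cfg.kT, rng)
            trace.append((s - current, ok))
            if ok:
                coords, current = cand, s
        for _ in range(cfg.quench_cycles):
            cand = propose_sym(coords, 0.5)
            s = complex_total(cand)
            ok = s < current - 1e-12
            trace.append((s - current, ok))
            if ok:
                coords, current = cand, s
        iface_score, total = interface(coords)
        model_structure = _structure_from_frame(complex_structure, propagate(coords))
        ca_model = model_structure.ca_coords()
        ca_ref = reference.ca_coords()
        t, rmsd = superpose(ca_model, ca_ref)
        models.append(DockModel(model_structure, iface_score, total, rmsd, seed, m,
                                sum(1 for _, ok in trace if ok), trace))
    return models
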