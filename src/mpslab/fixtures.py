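"""Synthetic structure generators: ideal helices, hairpins, C_n bundles and
docking dimers.

Every generator is deterministic — the same :class:`FixtureSpec` always
yields bit-identical coordinates — so the whole test suite runs without any
external structure files.  Backbones are grown atom by atom from ideal bond
geometry and the requested dihedrals (natural-extension reference frame);
side chains come from idealized templates at their default conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .core import Atom, MembraneGeometry, Residue, Structure, rotation_about_axis
from .scoring import AtomFrame
from .sidechains import AA_1TO3, atom_category, place_side_chain
from .protocols import ProtocolConfig, _frame_total, replicate_cn

__all__ = [
    "FixtureSpec",
    "build_helix",
    "build_hairpin",
    "build_bundle",
    "build_dimer",
    "docking_partners",
    "ClashingFixtureError",
]

# Ideal backbone geometry (Å, degrees), Engh-Huber-flavored.
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


class ClashingFixtureError(ValueError):
    """Generated fixture has inter-chain contacts below the clash threshold."""


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture.

    ``sequence`` is one-letter code for a single helix (default poly-A of
    length ``n_res``); bundles and dimers use ``n_res`` per helix.
    """

    kind: str = "helix"
    n_res: int = 21
    sequence: str | None = None
    n_helices: int = 4
    radius: float = 8.0
    tilt_deg: float = 0.0
    antiparallel: bool = False
    cn_exact: bool = True
    separation: float = 7.2
    groove_spacing: float = 8.2
    polish: bool = True
    seed: int = 0

    def resolved_sequence(self) -> str:
        return self.sequence if self.sequence is not None else "A" * self.n_res


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension frame placement of atom d bonded to c."""
    angle = np.radians(angle_deg)
    tors = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(tors),
        bond * np.sin(angle) * np.sin(tors),
    ])
    return c + m @ d2


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = residues[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for r in residues:  # carbonyl O in the peptide plane: N-CA-C-O = psi + 180
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], B_C_O, A_CA_C_O, psi + 180.0)
    return residues


def build_helix(spec: FixtureSpec, chain: str = "A", start_seq: int = 1) -> Structure:
    """Ideal alpha-helix (phi=-57, psi=-47), axis along +z, CA centroid at origin."""
    seq = spec.resolved_sequence()
    if len(seq) < 4:
        raise ValueError("helix needs at least 4 residues")
    bad = [c for c in seq if c not in AA_1TO3]
    if bad:
        raise ValueError(f"unsupported residue letters: {bad}")
    backbone = _build_backbone(len(seq), PHI_HELIX, PSI_HELIX)
    residues = []
    for i, (letter, bb) in enumerate(zip(seq, backbone)):
        aa = AA_1TO3[letter]
        atoms = [
            Atom("N", "N", bb["N"], atom_category(aa, "N", "N")),
            Atom("CA", "C", bb["CA"], atom_category(aa, "CA", "C")),
            Atom("C", "C", bb["C"], atom_category(aa, "C", "C")),
            Atom("O", "O", bb["O"], atom_category(aa, "O", "O")),
        ]
        res = Residue(start_seq + i, chain, aa, atoms, PHI_HELIX, PSI_HELIX)
        if aa != "GLY":
            place_side_chain(res, aa)
        residues.append(res)
    structure = Structure([(chain, residues)])
    # Align the helix axis with +z using the mean CA->CA direction, then
    # center the CA centroid at the origin.
    ca = structure.ca_coords()
    axis = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    target = np.array([0.0, 0.0, 1.0])
    cross = np.cross(axis, target)
    if np.linalg.norm(cross) > 1e-12:
        R = rotation_about_axis(cross, float(np.arctan2(np.linalg.norm(cross),
                                                        np.dot(axis, target))))
    elif np.dot(axis, target) > 0:
        R = np.eye(3)
    else:
        R = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi)
    coords = structure.coords()
    coords = (coords - ca.mean(axis=0)) @ R.T
    structure.set_coords(coords)
    ca = structure.ca_coords()
    structure.set_coords(structure.coords() - ca.mean(axis=0))
    return structure


def _transform_chain(structure: Structure, R: np.ndarray, t: np.ndarray) -> None:
    structure.set_coords(structure.coords() @ R.T + t)


def _rename_chain(structure: Structure, new_id: str) -> None:
    cid, residues = structure.chains[0]
    structure.chains = [(new_id, residues)]
    for r in residues:
        r.chain = new_id


def _min_interchain_distance(structure: Structure) -> float:
    frames = []
    for cid, _ in structure.chains:
        frames.append(np.array([a.pos for r in structure.chain(cid) for a in r.atoms]))
    best = np.inf
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            d = np.linalg.norm(frames[i][:, None] - frames[j][None, :], axis=-1)
            best = min(best, float(d.min()))
    return best


def build_hairpin(spec: FixtureSpec) -> Structure:
    """Antiparallel two-helix hairpin in one chain, arms crossing the slab.

    Both arms are ideal helices (up at x=0, down at x=10) joined by a short
    synthetic loop placed above the hydrophobic layer; the loop carries real
    backbone atoms but is rigid-piecewise rather than dihedral-continuous,
    which is sufficient for CA-level span and embedding work.
    """
    n = spec.n_res
    arm_spec = replace(spec, kind="helix", sequence=spec.resolved_sequence())
    up = build_helix(arm_spec)
    down = build_helix(arm_spec)
    _transform_chain(down, rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi),
                     np.array([10.0, 0.0, 0.0]))
    top = max(r.ca[2] for r in up.residues()) + 3.0
    loop_x = np.linspace(2.5, 7.5, 3)
    residues: list[Residue] = []
    seq_id = 1
    for r in up.chain("A"):
        residues.append(Residue(seq_id, "A", r.aa,
                                [Atom(a.name, a.element, a.pos.copy(), a.category)
                                 for a in r.atoms], r.phi, r.psi))
        seq_id += 1
    proto = up.chain("A")[len(up.chain("A")) // 2]
    for x in loop_x:
        shift = np.array([x, 0.0, top]) - proto.ca
        atoms = [Atom(a.name, a.element, a.pos + shift, a.category)
                 for a in proto.atoms if a.name in ("N", "CA", "C", "O")]
        residues.append(Residue(seq_id, "A", "GLY", atoms, None, None))
        seq_id += 1
    for r in down.chain("A"):
        residues.append(Residue(seq_id, "A", r.aa,
                                [Atom(a.name, a.element, a.pos.copy(), a.category)
                                 for a in r.atoms], r.phi, r.psi))
        seq_id += 1
    return Structure([("A", residues)])


def build_bundle(spec: FixtureSpec) -> Structure:
    """Helical bundle: ``n_helices`` placed on a circle of ``radius`` about +z.

    With ``cn_exact`` the bundle is generated by exact C_n replication of
    helix 0 (the symmetric-assembly native); otherwise each helix gets its
    own seeded tilt jitter (up to ``tilt_deg``) and, if ``antiparallel``,
    alternating orientation.  One chain per helix (A, B, C, ...).
    """
    if spec.n_helices < 2:
        raise ValueError("a bundle needs at least 2 helices")
    helix = build_helix(replace(spec, kind="helix"))
    if spec.cn_exact:
        sub = helix.copy()
        _transform_chain(sub, np.eye(3), np.array([spec.radius, 0.0, 0.0]))
        geom = MembraneGeometry()
        if spec.polish:
            sub = _polish_cn_subunit(sub, spec.n_helices, geom)
        out = replicate_cn(sub, spec.n_helices, geom)
    else:
        rng = np.random.default_rng(spec.seed)
        chains = []
        import string
        for k in range(spec.n_helices):
            h = helix.copy()
            cid = string.ascii_uppercase[k]
            if spec.antiparallel and k % 2 == 1:
                _transform_chain(h, rotation_about_axis(np.array([1.0, 0, 0]), np.pi),
                                 np.zeros(3))
            if spec.tilt_deg > 0:
                theta = rng.uniform(0, 2 * np.pi)
                ang = rng.uniform(-spec.tilt_deg, spec.tilt_deg)
                axis = np.array([np.cos(theta), np.sin(theta), 0.0])
                _transform_chain(h, rotation_about_axis(axis, np.radians(ang)), np.zeros(3))
            phi = 2 * np.pi * k / spec.n_helices
            _transform_chain(h, np.eye(3),
                             spec.radius * np.array([np.cos(phi), np.sin(phi), 0.0]))
            h.chains = [(cid, h.chains[0][1])]
            for r in h.chains[0][1]:
                r.chain = cid
            chains.append(h.chains[0])
        out = Structure(chains)
    if _min_interchain_distance(out) < 2.0:
        raise ClashingFixtureError(
            f"bundle spec produces inter-chain contacts below 2 Å (radius {spec.radius})"
        )
    return out


def _polish_cn_subunit(sub: Structure, n: int, geom: MembraneGeometry,
                       cfg: ProtocolConfig | None = None) -> Structure:
    """Refine the subunit pose so the C_n complex sits at its interface optimum.

    Coarse multi-start over the subunit tilts (helix bundles pack with a
    supercoil-like tilt, so the untilted pose is a saddle, not the minimum)
    followed by Nelder-Mead over radial offset, spin, depth shift and two
    tilts; the polished pose is the recorded assembly native.
    """
    cfg = cfg if cfg is not None else ProtocolConfig()
    if n < 2:
        return sub
    S0 = sub.coords()
    sub_frame = AtomFrame(sub)
    complex_frame = AtomFrame(replicate_cn(sub, n, geom))
    rotations = [rotation_about_axis(geom.normal, 2.0 * np.pi * k / n) for k in range(n)]
    centroid = S0.mean(axis=0)
    radial = centroid - geom.center
    radial -= np.dot(radial, geom.normal) * geom.normal
    radial /= np.linalg.norm(radial)
    tangent = np.cross(geom.normal, radial)

    def posed(params: np.ndarray) -> np.ndarray:
        dr, spin, dz, tilt_r, tilt_t = params
        R = (
            rotation_about_axis(radial, np.radians(tilt_r))
            @ rotation_about_axis(tangent, np.radians(tilt_t))
            @ rotation_about_axis(geom.normal, np.radians(spin))
        )
        out = centroid + (S0 - centroid) @ R.T
        return out + dr * radial + dz * geom.normal

    def interface(params: np.ndarray) -> float:
        coords = posed(params)
        rel = coords - geom.center
        complex_frame.coords = np.concatenate([geom.center + rel @ R.T for R in rotations])
        sub_frame.coords = coords
        return (_frame_total(complex_frame, geom, None, cfg)
                - n * _frame_total(sub_frame, geom, None, cfg))

    starts = []
    for tilt_r in (-15.0, -7.5, 0.0, 7.5, 15.0):
        for tilt_t in (-15.0, -7.5, 0.0, 7.5, 15.0):
            for dr in (-0.5, 0.0, 0.5):
                p = np.array([dr, 0.0, 0.0, tilt_r, tilt_t])
                starts.append((interface(p), p))
    starts.sort(key=lambda s: s[0])
    results = []
    for _, p0 in starts[:2]:
        r = minimize(interface, p0, method="Nelder-Mead",
                     options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 800})
        results.append((r.fun, r.x))
    best = min(results, key=lambda r: r[0])
    out = sub.copy()
    out.set_coords(posed(best[1]))
    return out


def build_dimer(spec: FixtureSpec, cfg: ProtocolConfig | None = None) -> Structure:
    """Docking fixture: a moving helix packed into a two-helix groove.

    The fixed partner is a pair of parallel helices (chains A and C) sitting
    side by side ``groove_spacing`` Å apart; the moving partner (chain B)
    packs into the groove between them at ``separation`` Å along +x.  The
    double contact makes the recorded pose the unique deep minimum of the
    interface score in its neighbourhood — single-helix faces elsewhere bury
    half the surface.  With ``polish`` the pose of B is refined to the local
    interface-score optimum (coarse crossing-angle grid, then Nelder-Mead
    over all six rigid degrees of freedom), so the constructed native is the
    funnel minimum by construction.
    """
    cfg = cfg if cfg is not None else ProtocolConfig()
    helix_spec = replace(spec, kind="helix")
    h = build_helix(helix_spec, chain="A")
    a1 = h.copy()
    a2 = h.copy()
    _rename_chain(a2, "C")
    _transform_chain(a1, np.eye(3), np.array([0.0, -0.5 * spec.groove_spacing, 0.0]))
    _transform_chain(a2, np.eye(3), np.array([0.0, 0.5 * spec.groove_spacing, 0.0]))
    b = h.copy()
    _rename_chain(b, "B")
    _transform_chain(b, np.eye(3), np.array([spec.separation, 0.0, 0.0]))
    combined = Structure(a1.chains + a2.chains + b.chains)
    if _min_interchain_distance(combined) < 2.0:
        raise ClashingFixtureError("dimer spec produces clashes below 2 Å")
    if not spec.polish:
        return combined

    geom = MembraneGeometry()
    frame = AtomFrame(combined)
    mask = np.array([frame.res_chain[ri] == "B" for ri in frame.res_index])
    C0 = frame.coords.copy()
    pivot = C0[mask].mean(axis=0)
    sep_axis = np.array([1.0, 0.0, 0.0])

    def posed(params: np.ndarray) -> np.ndarray:
        dx, dy, dz, spin, tilt_x, tilt_y = params
        R = (
            rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.radians(tilt_x))
            @ rotation_about_axis(np.array([0.0, 1.0, 0.0]), np.radians(tilt_y))
            @ rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.radians(spin))
        )
        out = C0.copy()
        out[mask] = pivot + (C0[mask] - pivot) @ R.T + np.array([dx, dy, dz])
        return out

    def interface(params: np.ndarray) -> float:
        coords = posed(params)
        frame.coords = coords
        total = _frame_total(frame, geom, None, cfg)
        sep = coords.copy()
        sep[mask] += cfg.separation * sep_axis
        frame.coords = sep
        return total - _frame_total(frame, geom, None, cfg)

    # Multi-start: coarse grid over approach distance and crossing angles,
    # then local refinement from the best starts; helix pairs pack at nonzero
    # crossing angles, so a single descent can miss the packing basin.
    starts = []
    for dx in (-1.0, 0.0, 1.0):
        for tx in (-10.0, 0.0, 10.0):
            for ty in (-10.0, 0.0, 10.0):
                p = np.array([dx, 0.0, 0.0, 0.0, tx, ty])
                starts.append((interface(p), p))
    starts.sort(key=lambda s: s[0])
    results = []
    for _, p0 in starts[:2]:
        r = minimize(interface, p0, method="Nelder-Mead",
                     options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 800})
        results.append((r.fun, r.x))
    best = min(results, key=lambda r: r[0])
    combined.set_coords(posed(best[1]))
    if _min_interchain_distance(combined) < 2.0:
        raise ClashingFixtureError("polished dimer collapsed into a clash")
    return combined



def docking_partners(dimer: Structure) -> tuple[Structure, Structure]:
    """Split a docking fixture into (fixed, moving) partners; chain B moves."""
    d = dimer.copy()
    fixed = [c for c in d.chains if c[0] != "B"]
    moving = [c for c in d.chains if c[0] == "B"]
    if not moving:
        raise ValueError("fixture has no moving chain 'B'")
    return Structure(fixed), Structure(moving)
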