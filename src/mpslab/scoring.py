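"""Depth-dependent membrane score function.

High-resolution terms work at atom level: transfer-energy environment
(``env_atom``), Gaussian-exclusion solvation interpolated between water and
membrane phases (``solv``), depth-strengthened geometric hydrogen bonds
(``hbond``) and a Lennard-Jones packing proxy with capped repulsion
(``packing``).  Low-resolution terms work at residue level: depth propensity
(``env_res``), pair and neighbor-count potentials (``pair``, ``cbeta``) and
whole-structure penalties (``nonhelix``, ``termini``, ``tmproj``).

Internally structures are flattened to numpy arrays (:class:`AtomFrame`) so
Monte-Carlo protocols can rescore thousands of rigid-body poses cheaply; the
public per-term functions accept ordinary :class:`~mpslab.core.Structure`
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import MembraneGeometry, Structure, dihedral, hydration_fraction
from .sidechains import _template
from .tables import (
    HIGHRES_TERMS,
    LOWRES_TERMS,
    TERM_NAMES,
    AtomTransferTable,
    ResidueDepthTable,
    PairDepthTable,
    CbetaTable,
    ScoreTables,
    ScoreWeights,
    SolvationParams,
    VdwParams,
    default_tables,
)
from .topology import SpanningTopology

__all__ = [
    "AtomFrame",
    "ScoreBreakdown",
    "env_atom_score",
    "solvation_score",
    "hbond_depth_weight",
    "packing_score",
    "env_residue_score",
    "pair_score",
    "cbeta_score",
    "penalty_scores",
    "total_score",
    "total_from_frame",
    "assign_secondary_structure",
]

# Helix dihedral window used when no secondary structure is supplied.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)

_SC_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "ND2"), ("GLN", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"),
}
_SC_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}


class AtomFrame:
    """Flattened, numpy-backed view of a structure for fast rescoring.

    Atom order follows structure iteration order.  Connectivity-derived data
    (bond-separation exclusions, donors/acceptors, CB indices) is computed
    once; only ``coords`` is expected to change between evaluations.
    """

    def __init__(self, structure: Structure):
        coords, cats, res_index, names = [], [], [], []
        res_aa, res_chain, res_seq = [], [], []
        ca_idx, cb_idx, n_idx, c_idx = [], [], [], []
        chain_of_res, term_flags = [], []
        atom_i = 0
        res_i = 0
        for chain_id, residues in structure.chains:
            for k, r in enumerate(residues):
                local = {}
                for a in r.atoms:
                    coords.append(a.pos)
                    cats.append(a.category)
                    res_index.append(res_i)
                    names.append(a.name)
                    local[a.name] = atom_i
                    atom_i += 1
                res_aa.append(r.aa)
                res_chain.append(chain_id)
                res_seq.append(r.seq_id)
                ca_idx.append(local.get("CA", -1))
                cb_idx.append(local.get("CB", local.get("CA", -1)))
                n_idx.append(local.get("N", -1))
                c_idx.append(local.get("C", -1))
                chain_of_res.append(chain_id)
                term_flags.append((k == 0, k == len(residues) - 1))
                res_i += 1
        self.coords = np.array(coords, dtype=float)
        self.categories: list[str] = cats
        self.res_index = np.array(res_index, dtype=int)
        self.atom_names: list[str] = names
        self.res_aa: list[str] = res_aa
        self.res_chain: list[str] = res_chain
        self.res_seq: list[int] = res_seq
        self.ca_idx = np.array(ca_idx, dtype=int)
        self.cb_idx = np.array(cb_idx, dtype=int)
        self.n_idx = np.array(n_idx, dtype=int)
        self.c_idx = np.array(c_idx, dtype=int)
        self.term_flags = term_flags
        self.res_key = {(c, s): i for i, (c, s) in enumerate(zip(res_chain, res_seq))}
        self.n_atoms = len(self.coords)
        self.n_res = len(res_aa)
        self._build_connectivity(structure)

    def _build_connectivity(self, structure: Structure) -> None:
        adjacency: list[set[int]] = [set() for _ in range(self.n_atoms)]
        offset = 0
        prev_c: int | None = None
        prev_res = -1
        for r_i in range(self.n_res):
            atoms = [i for i in range(offset, self.n_atoms) if self.res_index[i] == r_i]
            offset = atoms[-1] + 1 if atoms else offset
            local = {self.atom_names[i]: i for i in atoms}
            aa = self.res_aa[r_i]
            try:
                _, _, _, tmpl_adj = _template(aa)
            except Exception:
                tmpl_adj = {}
            for i in atoms:
                for nb in tmpl_adj.get(self.atom_names[i], ()):
                    if nb in local:
                        adjacency[i].add(local[nb])
                        adjacency[local[nb]].add(i)
            # Peptide bond to the previous residue in the same chain.
            if (
                prev_c is not None
                and prev_res == r_i - 1
                and self.res_chain[r_i] == self.res_chain[prev_res]
                and "N" in local
            ):
                adjacency[prev_c].add(local["N"])
                adjacency[local["N"]].add(prev_c)
            prev_c = local.get("C")
            prev_res = r_i
        # Pairs within 3 bonds are excluded from nonbonded terms.
        excl = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        np.fill_diagonal(excl, True)
        for i in range(self.n_atoms):
            frontier = {i}
            seen = {i}
            for _ in range(3):
                frontier = {nb for a in frontier for nb in adjacency[a]} - seen
                seen |= frontier
            for j in seen:
                excl[i, j] = excl[j, i] = True
        self.excl = excl
        self._find_hbond_partners(adjacency)

    def _find_hbond_partners(self, adjacency: list[set[int]]) -> None:
        donors, acceptors, bases = [], [], []
        for i in range(self.n_atoms):
            aa = self.res_aa[self.res_index[i]]
            name = self.atom_names[i]
            if name == "N" and aa != "PRO":
                donors.append(i)
            elif (aa, name) in _SC_DONORS:
                donors.append(i)
            if name == "O" or (aa, name) in _SC_ACCEPTORS:
                acceptors.append(i)
                nbs = sorted(adjacency[i])
                bases.append(nbs[0] if nbs else i)
        self.donors = np.array(donors, dtype=int)
        self.acceptors = np.array(acceptors, dtype=int)
        self.acceptor_base = np.array(bases, dtype=int)

    def depths(self, geom: MembraneGeometry, coords: np.ndarray | None = None):
        c = self.coords if coords is None else coords
        return (c - geom.center) @ geom.normal


@dataclass
class ScoreBreakdown:
    """Per-term unweighted values plus the weighted total."""

    values: dict[str, float]
    weights: ScoreWeights
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.weights.get(t) * v for t, v in self.values.items()))

    def to_dict(self) -> dict:
        return {
            "terms": dict(self.values),
            "weights": {t: self.weights.get(t) for t in self.values},
            "extras": dict(self.extras),
            "total": self.total,
        }

    def to_tsv(self) -> str:
        lines = ["term\tvalue\tweight\tweighted"]
        for t, v in self.values.items():
            w = self.weights.get(t)
            lines.append(f"{t}\t{v:.6f}\t{w}\t{w * v:.6f}")
        lines.append(f"total\t\t\t{self.total:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# atom-level terms (frame core + Structure wrappers)


def _category_array(frame: AtomFrame, mapping: dict[str, float]) -> np.ndarray:
    try:
        return np.array([mapping[c] for c in frame.categories], dtype=float)
    except KeyError as exc:
        missing = exc.args[0]
        i = frame.categories.index(missing)
        raise KeyError(
            f"atom category {missing!r} (atom {frame.atom_names[i]} of residue "
            f"{frame.res_chain[frame.res_index[i]]}{frame.res_seq[frame.res_index[i]]}) "
            "is not covered by the active table"
        ) from None


def _env_atom(frame: AtomFrame, geom: MembraneGeometry, table: AtomTransferTable) -> float:
    z = frame.depths(geom)
    f = hydration_fraction(geom, z)
    dg = _category_array(frame, table.values)
    return float(np.sum((1.0 - f) * dg))


def _solvation(
    frame: AtomFrame, geom: MembraneGeometry, params: SolvationParams,
    cutoff: float, D: np.ndarray,
) -> float:
    z = frame.depths(geom)
    f = hydration_fraction(geom, z)
    dgw = _category_array(frame, params.dgfree_water)
    dgm = _category_array(frame, params.dgfree_memb)
    lam = _category_array(frame, params.lam)
    rad = _category_array(frame, params.radius)
    vol = _category_array(frame, params.volume)
    dgref = f * dgw + (1.0 - f) * dgm
    mask = (D < cutoff) & ~frame.excl
    ii, jj = np.nonzero(np.triu(mask, k=1))
    if len(ii) == 0:
        return 0.0
    r = D[ii, jj]
    pref = 2.0 * np.pi**1.5

    def occlusion(a, b):  # desolvation of atom a by occluding atom b
        g = np.exp(-(((r - rad[a]) / lam[a]) ** 2))
        return -dgref[a] / (pref * lam[a] * r**2) * g * vol[b]

    return float(np.sum(occlusion(ii, jj) + occlusion(jj, ii)))


def hbond_depth_weight(
    geom: MembraneGeometry, z_donor: float, z_acceptor: float, w_memb: float = 2.0
) -> float:
    """Multiplicative hydrogen-bond strengthening at the pair's midpoint depth.

    1 far outside the membrane, ``w_memb`` at the slab center.
    """
    if w_memb < 1.0:
        raise ValueError("w_memb must be >= 1")
    z_mid = 0.5 * (z_donor + z_acceptor)
    return 1.0 + (w_memb - 1.0) * (1.0 - hydration_fraction(geom, z_mid))


def _hbond(frame: AtomFrame, geom: MembraneGeometry, tables: ScoreTables,
           D: np.ndarray) -> float:
    if len(frame.donors) == 0 or len(frame.acceptors) == 0:
        return 0.0
    sub = D[np.ix_(frame.donors, frame.acceptors)]
    ok = sub <= tables.hbond_dist_max
    ok &= ~frame.excl[np.ix_(frame.donors, frame.acceptors)]
    # No self hydrogen bonds within a residue (e.g. hydroxyl donor=acceptor).
    same_res = (
        frame.res_index[frame.donors][:, None]
        == frame.res_index[frame.acceptors][None, :]
    )
    ok &= ~same_res
    di, ai = np.nonzero(ok)
    if len(di) == 0:
        return 0.0
    d_idx = frame.donors[di]
    a_idx = frame.acceptors[ai]
    b_idx = frame.acceptor_base[ai]
    v1 = frame.coords[d_idx] - frame.coords[a_idx]
    v2 = frame.coords[b_idx] - frame.coords[a_idx]
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    keep = angles >= tables.hbond_angle_min
    if not np.any(keep):
        return 0.0
    d_idx, a_idx = d_idx[keep], a_idx[keep]
    r = np.linalg.norm(frame.coords[d_idx] - frame.coords[a_idx], axis=1)
    # A donor carries one hydrogen: it donates a single bond, to its nearest
    # gated acceptor; an unordered atom pair (e.g. hydroxyl-hydroxyl, both
    # donor and acceptor) counts once.  Ties break on atom index.
    best: dict[int, tuple[float, int, int]] = {}
    for dist, d, a in sorted(zip(r, d_idx, a_idx), key=lambda t: (t[1], t[0], t[2])):
        if d not in best:
            best[d] = (dist, d, a)
    pairs = {}
    for dist, d, a in best.values():
        key = (min(d, a), max(d, a))
        if key not in pairs:
            pairs[key] = (d, a)
    z = frame.depths(geom)
    total = 0.0
    for d, a in pairs.values():
        w = 1.0 + (tables.hbond_w_memb - 1.0) * (
            1.0 - hydration_fraction(geom, 0.5 * (z[d] + z[a]))
        )
        total += tables.hbond_energy * w
    return float(total)


def _packing(frame: AtomFrame, tables: ScoreTables, D: np.ndarray) -> tuple[float, float]:
    rad = _category_array(frame, tables.vdw.radius)
    eps = _category_array(frame, tables.vdw.epsilon)
    mask = (D < tables.pack_cutoff) & ~frame.excl
    ii, jj = np.nonzero(np.triu(mask, k=1))
    if len(ii) == 0:
        return 0.0, 0.0
    r = D[ii, jj]
    sigma = rad[ii] + rad[jj]
    e = np.sqrt(eps[ii] * eps[jj])
    s6 = (sigma / r) ** 6
    lj = e * (s6**2 - 2.0 * s6)
    att = np.where(r >= sigma, lj, -e)
    rep = np.where(r < sigma, lj + e, 0.0)
    # Linear cap below 0.6 sigma avoids the steep gradients that blow up
    # rigid-body searches started from clashed poses.
    r0 = 0.6 * sigma
    s6c = (1.0 / 0.6) ** 6
    rep_r0 = e * (s6c**2 - 2.0 * s6c + 1.0)
    slope = e * 12.0 * (-(sigma**12) / r0**13 + sigma**6 / r0**7)
    capped = rep_r0 + slope * (r - r0)
    rep = np.where(r < r0, capped, rep)
    return float(np.sum(att)), float(np.sum(rep))


# ---------------------------------------------------------------------------
# residue-level terms


def _env_res(frame: AtomFrame, geom: MembraneGeometry, table: ResidueDepthTable) -> float:
    z = frame.depths(geom)[frame.ca_idx]
    rows = np.array([table.aas.index(aa) for aa in frame.res_aa])
    return float(np.sum(table.values[rows, table.bin_of(z)]))


def _pair(frame: AtomFrame, geom: MembraneGeometry, table: PairDepthTable) -> float:
    if not table.values:
        return 0.0
    cb = frame.coords[frame.cb_idx]
    z = frame.depths(geom)[frame.cb_idx]
    total = 0.0
    for i in range(frame.n_res):
        for j in range(i + 1, frame.n_res):
            d = float(np.linalg.norm(cb[i] - cb[j]))
            total += table.lookup(frame.res_aa[i], frame.res_aa[j], d, 0.5 * (z[i] + z[j]))
    return total


def _cbeta(frame: AtomFrame, table: CbetaTable) -> float:
    if all(v == 0.0 for v in table.values):
        return 0.0
    cb = frame.coords[frame.cb_idx]
    D = cdist(cb, cb)
    counts = np.sum((D < table.radius) & (D > 0), axis=1)
    return float(sum(table.lookup(int(c)) for c in counts))


def assign_secondary_structure(frame: AtomFrame) -> list[str]:
    """Dihedral-window secondary structure: 'H' for helical phi/psi, else 'L'."""
    ss = ["L"] * frame.n_res
    for i in range(frame.n_res):
        prev_ok = (
            i > 0
            and frame.res_chain[i - 1] == frame.res_chain[i]
            and frame.c_idx[i - 1] >= 0
        )
        next_ok = (
            i + 1 < frame.n_res
            and frame.res_chain[i + 1] == frame.res_chain[i]
            and frame.n_idx[i + 1] >= 0
        )
        if not (prev_ok and next_ok):
            continue
        n, ca, c = frame.n_idx[i], frame.ca_idx[i], frame.c_idx[i]
        phi = dihedral(frame.coords[frame.c_idx[i - 1]], frame.coords[n],
                       frame.coords[ca], frame.coords[c])
        psi = dihedral(frame.coords[n], frame.coords[ca], frame.coords[c],
                       frame.coords[frame.n_idx[i + 1]])
        if HELIX_PHI[0] < phi < HELIX_PHI[1] and HELIX_PSI[0] < psi < HELIX_PSI[1]:
            ss[i] = "H"
    return ss


def _penalties(
    frame: AtomFrame,
    geom: MembraneGeometry,
    topology: SpanningTopology | None,
    ss: Sequence[str] | None,
    termini_outside: bool = False,
) -> tuple[float, float, float]:
    half = geom.half_thickness
    z_ca = frame.depths(geom)[frame.ca_idx]
    if ss is None:
        ss = assign_secondary_structure(frame)
    elif len(ss) != frame.n_res:
        raise ValueError(
            f"secondary structure has {len(ss)} labels for {frame.n_res} residues"
        )
    nonhelix = 0.0
    tmproj = 0.0
    if topology is not None:
        for span in topology.spans:
            i0 = frame.res_key[(span.chain, span.start)]
            i1 = frame.res_key[(span.chain, span.end)]
            for i in range(i0, i1 + 1):
                if abs(z_ca[i]) <= half and ss[i] != "H":
                    nonhelix += 1.0
            tmproj += max(0.0, abs(z_ca[i0]) - half) + max(0.0, abs(z_ca[i1]) - half)
    termini = 0.0
    for i, (is_first, is_last) in enumerate(frame.term_flags):
        for flag in (is_first, is_last):
            if not flag:
                continue
            inside = abs(z_ca[i]) < half
            if inside != termini_outside:
                termini += 1.0
    return nonhelix, termini, tmproj


# ---------------------------------------------------------------------------
# totals


def total_from_frame(
    frame: AtomFrame,
    geom: MembraneGeometry,
    topology: SpanningTopology | None = None,
    weights: ScoreWeights | None = None,
    tables: ScoreTables | None = None,
    mode: str = "highres",
    ss: Sequence[str] | None = None,
) -> ScoreBreakdown:
    if mode not in ("lowres", "highres"):
        raise ValueError(f"mode must be 'lowres' or 'highres', got {mode!r}")
    weights = weights if weights is not None else ScoreWeights()
    tables = tables if tables is not None else default_tables()
    terms = HIGHRES_TERMS if mode == "highres" else LOWRES_TERMS
    values: dict[str, float] = {}
    extras: dict[str, float] = {}
    if mode == "highres":
        need_pairs = any(weights.get(t) != 0.0 for t in ("solv", "packing", "hbond"))
        D = cdist(frame.coords, frame.coords) if need_pairs else None
        values["env_atom"] = (
            _env_atom(frame, geom, tables.transfer) if weights.get("env_atom") != 0 else 0.0
        )
        values["solv"] = (
            _solvation(frame, geom, tables.solvation, tables.solv_cutoff, D)
            if weights.get("solv") != 0 else 0.0
        )
        values["hbond"] = _hbond(frame, geom, tables, D) if weights.get("hbond") != 0 else 0.0
        if weights.get("packing") != 0:
            att, rep = _packing(frame, tables, D)
            values["packing"] = att + rep
            extras["packing_attractive"] = att
            extras["packing_repulsive"] = rep
        else:
            values["packing"] = 0.0
    else:
        values["env_res"] = (
            _env_res(frame, geom, tables.env_res) if weights.get("env_res") != 0 else 0.0
        )
        values["pair"] = _pair(frame, geom, tables.pair) if weights.get("pair") != 0 else 0.0
        values["cbeta"] = _cbeta(frame, tables.cbeta) if weights.get("cbeta") != 0 else 0.0
        nh, tm, tp = _penalties(frame, geom, topology, ss, tables.termini_outside)
        values["nonhelix"], values["termini"], values["tmproj"] = nh, tm, tp
    assert set(values) == set(terms)
    return ScoreBreakdown(values, weights, extras)


def total_score(
    structure: Structure,
    geom: MembraneGeometry,
    topology: SpanningTopology | None = None,
    weights: ScoreWeights | None = None,
    tables: ScoreTables | None = None,
    mode: str = "highres",
    ss: Sequence[str] | None = None,
) -> ScoreBreakdown:
    """Evaluate the mode's term set for a (structure, membrane, topology) triple."""
    return total_from_frame(AtomFrame(structure), geom, topology, weights, tables, mode, ss)


# ---------------------------------------------------------------------------
# public single-term wrappers


def env_atom_score(structure: Structure, geom: MembraneGeometry,
                   table: AtomTransferTable | None = None) -> float:
    """Depth-weighted atomic transfer energy: sum (1 - f(z)) dG_transfer."""
    table = table if table is not None else AtomTransferTable.default()
    return _env_atom(AtomFrame(structure), geom, table)


def solvation_score(structure: Structure, geom: MembraneGeometry,
                    solv_params: SolvationParams | None = None,
                    cutoff: float = 9.0) -> float:
    """Gaussian-exclusion desolvation with depth-interpolated reference energies."""
    params = solv_params if solv_params is not None else SolvationParams.default()
    frame = AtomFrame(structure)
    D = cdist(frame.coords, frame.coords)
    return _solvation(frame, geom, params, cutoff, D)


def packing_score(structure: Structure, pair_cutoff: float = 6.0,
                  radii: VdwParams | None = None) -> tuple[float, float]:
    """(attractive, repulsive) Lennard-Jones packing with capped repulsion."""
    vdw = radii if radii is not None else VdwParams.default()
    tables = ScoreTables(
        transfer=AtomTransferTable.default(), solvation=SolvationParams.default(),
        vdw=vdw, env_res=ResidueDepthTable.zero(), pair=PairDepthTable(),
        cbeta=CbetaTable(), pack_cutoff=pair_cutoff,
    )
    frame = AtomFrame(structure)
    D = cdist(frame.coords, frame.coords)
    return _packing(frame, tables, D)


def hbond_score(structure: Structure, geom: MembraneGeometry,
                tables: ScoreTables | None = None) -> float:
    """Total depth-strengthened hydrogen-bond energy."""
    tables = tables if tables is not None else default_tables()
    frame = AtomFrame(structure)
    D = cdist(frame.coords, frame.coords)
    return _hbond(frame, geom, tables, D)


def env_residue_score(structure: Structure, geom: MembraneGeometry,
                      table: ResidueDepthTable) -> float:
    """Residue depth propensity summed over CA depths."""
    return _env_res(AtomFrame(structure), geom, table)


def pair_score(structure: Structure, geom: MembraneGeometry,
               table: PairDepthTable) -> float:
    """Pairwise residue potential over CB distance and midpoint depth bins."""
    return _pair(AtomFrame(structure), geom, table)


def cbeta_score(structure: Structure, table: CbetaTable) -> float:
    """Neighbor-count density potential over CB neighbors."""
    return _cbeta(AtomFrame(structure), table)


def penalty_scores(structure: Structure, geom: MembraneGeometry,
                   topology: SpanningTopology | None,
                   ss: Sequence[str] | None = None,
                   termini_outside: bool = False) -> tuple[float, float, float]:
    """(nonhelix, termini, tmproj) whole-structure penalties.

    nonhelix counts in-span residues inside the slab without helical
    dihedrals; termini counts chain ends inside the hydrophobic layer (or
    outside it with ``termini_outside=True``, the literal alternative
    reading); tmproj sums the distances by which span end CA atoms project
    beyond the slab boundary (Å).
    """
    return _penalties(AtomFrame(structure), geom, topology, ss, termini_outside)
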