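"""Side-chain construction: idealized templates, chi angles, rotamers, mutation.

Heavy-atom side chains are built from idealized residue templates
(biotite's bundled Chemical Component Dictionary), superimposed onto the
existing backbone via the N/CA/C frame.  Chi angles are standard side-chain
dihedrals; rotating chi_k moves every atom on the distal side of the bond,
found by traversal of the template bond graph.  Each atom carries a
transfer-energy category label used by the membrane environment score.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import Atom, Residue, Structure, dihedral, rotation_about_axis, superpose

__all__ = [
    "AA_3TO1",
    "AA_1TO3",
    "STANDARD_AA",
    "CHI_ATOMS",
    "CATEGORIES",
    "atom_category",
    "place_side_chain",
    "mutate_residue",
    "chi_angles",
    "set_chi_angles",
    "rotamer_chi_sets",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
STANDARD_AA = tuple(AA_3TO1)

BACKBONE = ("N", "CA", "C", "O", "OXT")

# Standard chi dihedral definitions (heavy atoms only).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [], "GLY": [], "PRO": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

CATEGORIES = (
    "backbone", "aliphatic_C", "aromatic_C",
    "polar_N", "charged_N", "guanidinium_N", "polar_O", "charged_O", "sulfur",
)

_AROMATIC_C = {
    ("PHE", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TYR", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TRP", n) for n in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
} | {("HIS", n) for n in ("CG", "CD2", "CE1")}

_CHARGED_N = {("LYS", "NZ")}
# Guanidinium nitrogens share one delocalized charge; they carry a smaller
# per-atom transfer penalty than the localized lysine ammonium.
_GUANIDINIUM_N = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def atom_category(aa: str, name: str, element: str) -> str:
    """Transfer-energy class of a heavy atom, from residue and atom name."""
    if name in BACKBONE:
        return "backbone"
    element = element.upper()
    if element == "C":
        return "aromatic_C" if (aa, name) in _AROMATIC_C else "aliphatic_C"
    if element == "N":
        if (aa, name) in _CHARGED_N:
            return "charged_N"
        if (aa, name) in _GUANIDINIUM_N:
            return "guanidinium_N"
        return "polar_N"
    if element == "O":
        return "charged_O" if (aa, name) in _CHARGED_O else "polar_O"
    if element == "S":
        return "sulfur"
    raise ValueError(f"cannot categorize atom {name} ({element}) in {aa}")


@lru_cache(maxsize=None)
def _template(aa: str):
    """Heavy-atom idealized template: names, elements, coords, bond adjacency."""
    import biotite.structure.info as struc_info

    arr = struc_info.residue(aa)
    heavy = (arr.element != "H") & (arr.atom_name != "OXT")
    names = list(arr.atom_name[heavy])
    elements = list(arr.element[heavy])
    coords = np.asarray(arr.coord[heavy], dtype=float)
    index_of = {n: i for i, n in enumerate(np.where(heavy)[0])}
    adjacency: dict[str, set[str]] = {n: set() for n in names}
    bonds = arr.bonds.as_array() if arr.bonds is not None else np.empty((0, 3), int)
    for i, j, _ in bonds:
        if i in index_of and j in index_of:
            a, b = names[index_of[i]], names[index_of[j]]
            adjacency[a].add(b)
            adjacency[b].add(a)
    return names, elements, coords, adjacency


def _distal_atoms(aa: str, pivot: str, blocked: str) -> set[str]:
    """Atoms reachable from ``pivot`` without crossing ``blocked`` (template graph)."""
    _, _, _, adjacency = _template(aa)
    seen = {blocked, pivot}
    stack = [pivot]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen - {blocked, pivot}


def place_side_chain(
    residue: Residue, aa: str, chis: tuple[float, ...] | None = None
) -> None:
    """Rebuild the residue's side chain (in place) with idealized geometry.

    The template is superimposed on the residue's N/CA/C backbone frame;
    the backbone atoms themselves are untouched.  ``chis`` sets the side-chain
    dihedrals; ``None`` keeps the template's own conformation.
    """
    if aa not in STANDARD_AA:
        raise ValueError(f"unsupported residue type {aa!r}")
    names, elements, coords, _ = _template(aa)
    frame_names = ("N", "CA", "C")
    tmpl_frame = np.array([coords[names.index(n)] for n in frame_names])
    res_frame = np.array([residue.atom(n).pos for n in frame_names])
    transform, _ = superpose(tmpl_frame, res_frame)
    placed = {n: transform.apply(coords[i]) for i, n in enumerate(names)}

    backbone_atoms = [a for a in residue.atoms if a.name in BACKBONE]
    side_names = [n for n in names if n not in BACKBONE]
    side_elements = {n: elements[names.index(n)] for n in side_names}
    residue.aa = aa
    residue.atoms = backbone_atoms + [
        Atom(n, side_elements[n], placed[n], atom_category(aa, n, side_elements[n]))
        for n in side_names
    ]
    for a in residue.atoms:
        a.category = atom_category(aa, a.name, a.element)
    if chis is not None:
        set_chi_angles(residue, chis)


def set_chi_angles(residue: Residue, chis: tuple[float, ...]) -> None:
    """Set the residue's side-chain dihedrals to ``chis`` (degrees), in place."""
    defs = CHI_ATOMS[residue.aa]
    if len(chis) != len(defs):
        raise ValueError(
            f"{residue.aa} has {len(defs)} chi angles, got {len(chis)} values"
        )
    for k, (a1, a2, a3, a4) in enumerate(defs):
        current = dihedral(*(residue.atom(n).pos for n in (a1, a2, a3, a4)))
        delta = np.radians(chis[k] - current)
        p2, p3 = residue.atom(a2).pos, residue.atom(a3).pos
        R = rotation_about_axis(p3 - p2, delta)
        moving = _distal_atoms(residue.aa, a3, a2)
        for atom in residue.atoms:
            if atom.name in moving:
                atom.pos = p3 + R @ (atom.pos - p3)


def chi_angles(residue: Residue) -> tuple[float, ...]:
    """Current side-chain dihedrals of the residue (degrees)."""
    return tuple(
        dihedral(*(residue.atom(n).pos for n in atoms))
        for atoms in CHI_ATOMS[residue.aa]
    )


def rotamer_chi_sets(aa: str, staggered=(-60.0, 60.0, 180.0)) -> list[tuple[float, ...]]:
    """Discrete rotamer library: staggered values enumerated per chi angle."""
    defs = CHI_ATOMS[aa]
    sets: list[tuple[float, ...]] = [()]
    for _ in defs:
        sets = [s + (v,) for s in sets for v in staggered]
    return sets if defs else []


def mutate_residue(
    structure: Structure, chain: str, seq_id: int, target_aa: str
) -> Structure:
    """Return a copy of the structure with one residue's side chain swapped.

    Backbone atoms are kept; the new side chain is placed with idealized
    geometry at the template conformation.
    """
    out = structure.copy()
    res = out.residue(chain, seq_id)
    for name in ("N", "CA", "C"):
        if not res.has_atom(name):
            raise ValueError(f"residue {chain}{seq_id} lacks backbone atom {name}")
    place_side_chain(res, target_aa)
    return out
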