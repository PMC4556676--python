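"""Pluggable score tables and their plain-text format.

All knowledge-based inputs of the score function — atom transfer energies,
solvation parameters, packing radii, residue-depth propensities, pair and
neighbor-count potentials — are plain whitespace-delimited text with
``# key: value`` header lines carrying provenance.  Shipped defaults live in
``mpslab/data``; pair and neighbor-count tables default to zero so nothing
invented masquerades as a fitted statistical potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sidechains import AA_3TO1, CATEGORIES, STANDARD_AA

__all__ = [
    "AtomTransferTable",
    "SolvationParams",
    "VdwParams",
    "ResidueDepthTable",
    "PairDepthTable",
    "CbetaTable",
    "ScoreWeights",
    "ScoreTables",
    "default_tables",
]

# Fauchere-Pliska side-chain octanol partition scale (kcal/mol, positive =
# hydrophobic); sign-flipped it approximates water -> membrane transfer.
SIDECHAIN_HYDROPHOBICITY = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}


def _parse_table_text(text: str) -> tuple[dict[str, str], list[list[str]]]:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                key = k.strip()
                meta[key] = (meta.get(key, "") + " " + v.strip()).strip()
            continue
        rows.append(line.split())
    return meta, rows


def _data_text(name: str) -> str:
    return resources.files("mpslab.data").joinpath(name).read_text()


@dataclass(frozen=True)
class AtomTransferTable:
    """Per-category atomic transfer free energies (water -> membrane core)."""

    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown atom categories: {sorted(unknown)}")

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self.values)

    def dg(self, category: str) -> float:
        try:
            return self.values[category]
        except KeyError:
            raise KeyError(f"atom category {category!r} not in transfer table") from None

    def to_text(self) -> str:
        lines = [f"# provenance: {self.provenance}"] if self.provenance else []
        lines += [f"{c}\t{v:.6f}" for c, v in self.values.items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AtomTransferTable":
        meta, rows = _parse_table_text(text)
        return cls({r[0]: float(r[1]) for r in rows}, meta.get("provenance", ""))

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomTransferTable":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def default(cls) -> "AtomTransferTable":
        return cls.from_text(_data_text("atom_transfer.tsv"))


@dataclass(frozen=True)
class SolvationParams:
    """Gaussian-exclusion solvation parameters per category.

    Each row: reference free energy in water and in the membrane core
    (kcal/mol), correlation length lambda (Å), atomic radius (Å) and group
    volume (Å^3).  The depth-dependent reference is the hydration-weighted
    mix of the two phase values.
    """

    dgfree_water: dict[str, float]
    dgfree_memb: dict[str, float]
    lam: dict[str, float]
    radius: dict[str, float]
    volume: dict[str, float]

    @classmethod
    def from_text(cls, text: str) -> "SolvationParams":
        _, rows = _parse_table_text(text)
        cols = [{r[0]: float(r[i]) for r in rows} for i in range(1, 6)]
        return cls(*cols)

    @classmethod
    def default(cls) -> "SolvationParams":
        return cls.from_text(_data_text("solvation.tsv"))


@dataclass(frozen=True)
class VdwParams:
    """Packing radii (Å) and well depths (kcal/mol) per category."""

    radius: dict[str, float]
    epsilon: dict[str, float]

    @classmethod
    def from_text(cls, text: str) -> "VdwParams":
        _, rows = _parse_table_text(text)
        return cls({r[0]: float(r[1]) for r in rows}, {r[0]: float(r[2]) for r in rows})

    @classmethod
    def default(cls) -> "VdwParams":
        return cls.from_text(_data_text("vdw.tsv"))


@dataclass(frozen=True)
class ResidueDepthTable:
    """Depth-binned per-residue propensities: score = table[aa, bin(z_CA)].

    Bins are contiguous with floor lookup; depths beyond the declared range
    use the flanking bin.
    """

    aas: tuple[str, ...]
    z_min: float
    bin_width: float
    values: np.ndarray  # (n_aa, n_bins)
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.aas):
            raise ValueError("row count does not match residue list")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_of(self, z) -> np.ndarray:
        idx = np.floor((np.asarray(z, dtype=float) - self.z_min) / self.bin_width)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)

    def lookup(self, aa: str, z: float) -> float:
        try:
            row = self.aas.index(aa)
        except ValueError:
            raise KeyError(f"residue type {aa!r} not in depth table") from None
        return float(self.values[row, self.bin_of(z)])

    def to_text(self) -> str:
        lines = [
            f"# provenance: {self.provenance}",
            f"# z_min: {self.z_min}",
            f"# bin_width: {self.bin_width}",
        ]
        for aa, row in zip(self.aas, self.values):
            lines.append(aa + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ResidueDepthTable":
        meta, rows = _parse_table_text(text)
        return cls(
            tuple(r[0] for r in rows),
            float(meta["z_min"]),
            float(meta["bin_width"]),
            np.array([[float(v) for v in r[1:]] for r in rows]),
            meta.get("provenance", ""),
        )

    @classmethod
    def zero(cls, z_min: float = -36.0, bin_width: float = 2.0, n_bins: int = 36):
        return cls(STANDARD_AA, z_min, bin_width, np.zeros((len(STANDARD_AA), n_bins)),
                   "all-zero placeholder")

    @classmethod
    def hydrophobicity_default(
        cls, thickness: float = 30.0, steepness: float = 10.0,
        z_min: float = -36.0, bin_width: float = 2.0, n_bins: int = 36,
    ) -> "ResidueDepthTable":
        """Depth propensity from the side-chain hydrophobicity scale.

        score(aa, z) = -hydrophobicity(aa) * (1 - f(z_bin_center)): hydrophobic
        residues are rewarded inside the slab, polar ones outside.
        """
        centers = z_min + bin_width * (np.arange(n_bins) + 0.5)
        u = np.abs(2.0 * centers / thickness)
        f = u**steepness / (1.0 + u**steepness)
        vals = np.array(
            [-SIDECHAIN_HYDROPHOBICITY[aa] * (1.0 - f) for aa in STANDARD_AA]
        )
        return cls(STANDARD_AA, z_min, bin_width, vals,
                   "side-chain octanol scale modulated by hydration fraction")


@dataclass(frozen=True)
class PairDepthTable:
    """Residue-pair potential binned by CB distance and midpoint depth.

    ``values`` maps (aa_i, aa_j, dist_bin, depth_bin) with the pair stored
    unordered (sorted).  Missing cells score zero, so the default empty table
    is the all-zero potential.
    """

    dist_bin_width: float = 2.0
    depth_z_min: float = -36.0
    depth_bin_width: float = 6.0
    n_depth_bins: int = 12
    values: dict[tuple[str, str, int, int], float] = field(default_factory=dict)
    provenance: str = "all-zero placeholder"

    def depth_bin(self, z: float) -> int:
        return int(np.clip((z - self.depth_z_min) // self.depth_bin_width,
                           0, self.n_depth_bins - 1))

    def lookup(self, aa_i: str, aa_j: str, dist: float, z_mid: float) -> float:
        a, b = sorted((aa_i, aa_j))
        key = (a, b, int(dist // self.dist_bin_width), self.depth_bin(z_mid))
        return self.values.get(key, 0.0)

    def to_text(self) -> str:
        lines = [
            f"# provenance: {self.provenance}",
            f"# dist_bin_width: {self.dist_bin_width}",
            f"# depth_z_min: {self.depth_z_min}",
            f"# depth_bin_width: {self.depth_bin_width}",
            f"# n_depth_bins: {self.n_depth_bins}",
        ]
        for (a, b, db, zb), v in sorted(self.values.items()):
            lines.append(f"{a}\t{b}\t{db}\t{zb}\t{v:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PairDepthTable":
        meta, rows = _parse_table_text(text)
        values = {}
        for r in rows:
            a, b = sorted((r[0], r[1]))
            values[(a, b, int(r[2]), int(r[3]))] = float(r[4])
        return cls(
            float(meta.get("dist_bin_width", 2.0)),
            float(meta.get("depth_z_min", -36.0)),
            float(meta.get("depth_bin_width", 6.0)),
            int(meta.get("n_depth_bins", 12)),
            values,
            meta.get("provenance", ""),
        )


@dataclass(frozen=True)
class CbetaTable:
    """Neighbor-count density potential: score = table[#CB within radius]."""

    values: tuple[float, ...] = (0.0,)
    radius: float = 10.0
    provenance: str = "all-zero placeholder"

    def lookup(self, count: int) -> float:
        return self.values[min(count, len(self.values) - 1)]

    def to_text(self) -> str:
        lines = [f"# provenance: {self.provenance}", f"# radius: {self.radius}"]
        lines += [f"{i}\t{v:.6f}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CbetaTable":
        meta, rows = _parse_table_text(text)
        vals = [0.0] * (max(int(r[0]) for r in rows) + 1) if rows else [0.0]
        for r in rows:
            vals[int(r[0])] = float(r[1])
        return cls(tuple(vals), float(meta.get("radius", 10.0)),
                   meta.get("provenance", ""))


TERM_NAMES = (
    "env_atom", "solv", "hbond", "packing",
    "env_res", "pair", "cbeta", "nonhelix", "termini", "tmproj",
)
HIGHRES_TERMS = ("env_atom", "solv", "hbond", "packing")
LOWRES_TERMS = ("env_res", "pair", "cbeta", "nonhelix", "termini", "tmproj")


@dataclass(frozen=True)
class ScoreWeights:
    """Per-term weights; unknown term names are rejected."""

    weights: dict[str, float] = field(default_factory=lambda: {t: 1.0 for t in TERM_NAMES})

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown score terms: {sorted(unknown)}")

    def get(self, term: str) -> float:
        return self.weights.get(term, 0.0)

    def replacing(self, **kw: float) -> "ScoreWeights":
        return ScoreWeights({**self.weights, **kw})

    @classmethod
    def only(cls, **kw: float) -> "ScoreWeights":
        """Weights that zero every term except the given ones."""
        w = {t: 0.0 for t in TERM_NAMES}
        w.update(kw)
        return cls(w)

    def to_text(self) -> str:
        return "\n".join(f"{t} {w}" for t, w in self.weights.items()) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScoreWeights":
        _, rows = _parse_table_text(text)
        return cls({r[0]: float(r[1]) for r in rows})


@dataclass(frozen=True)
class ScoreTables:
    """Bundle of all tables and fixed parameters the score function reads."""

    transfer: AtomTransferTable
    solvation: SolvationParams
    vdw: VdwParams
    env_res: ResidueDepthTable
    pair: PairDepthTable
    cbeta: CbetaTable
    hbond_w_memb: float = 2.0       # membrane-core hydrogen-bond strengthening
    hbond_dist_max: float = 3.5     # donor-acceptor heavy atom distance gate (Å)
    hbond_angle_min: float = 120.0  # base-acceptor-donor angle gate (deg)
    hbond_energy: float = -1.0      # energy of one geometric hydrogen bond
    pack_cutoff: float = 6.0        # packing pair cutoff (Å)
    solv_cutoff: float = 9.0        # solvation pair cutoff (Å)
    termini_outside: bool = False   # literal reading: penalize termini outside


def default_tables() -> ScoreTables:
    return ScoreTables(
        transfer=AtomTransferTable.default(),
        solvation=SolvationParams.default(),
        vdw=VdwParams.default(),
        env_res=ResidueDepthTable.hydrophobicity_default(),
        pair=PairDepthTable(),
        cbeta=CbetaTable(),
    )
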