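"""PDB ATOM-record subset reader and writer.

The dialect is deliberately strict and small: ATOM and TER records of the
first MODEL only; altloc blank or 'A'; HETATM ignored; insertion codes
rejected with a clear error; chain ids, author residue numbers and atom
names preserved verbatim.  Coordinates round-trip at the format's 3-decimal
precision.  Occupancy and B-factor are ignored on read and written as
1.00/0.00.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import Atom, Residue, Structure
from .sidechains import STANDARD_AA, atom_category

__all__ = ["PdbFormatError", "read_pdb", "parse_pdb_text", "write_pdb", "format_pdb"]


class PdbFormatError(ValueError):
    """Malformed PDB input; the message names the offending line."""


def _element_of(line: str, atom_name: str) -> str:
    element = line[76:78].strip() if len(line) >= 78 else ""
    if element:
        return element.capitalize()
    name = atom_name.strip()
    return name[:1] if name[:1].isalpha() else name[1:2]


def parse_pdb_text(text: str) -> Structure:
    chains: dict[str, list[Residue]] = {}
    order: list[str] = []
    current: tuple[str, int, str] | None = None
    residue: Residue | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            break  # first MODEL only
        if not rec.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PdbFormatError(f"line {lineno}: ATOM record shorter than 54 columns")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        icode = line[26]
        if icode != " ":
            raise PdbFormatError(
                f"line {lineno}: insertion codes are not supported (got {icode!r})"
            )
        try:
            seq_id = int(line[22:26])
            pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError:
            raise PdbFormatError(f"line {lineno}: malformed ATOM numeric fields") from None
        name = line[12:16].strip()
        aa = line[17:20].strip()
        chain_id = line[21] if line[21] != " " else "A"
        element = _element_of(line, line[12:16])
        key = (chain_id, seq_id, aa)
        if key != current:
            if chain_id not in chains:
                chains[chain_id] = []
                order.append(chain_id)
            residue = Residue(seq_id, chain_id, aa, [])
            chains[chain_id].append(residue)
            current = key
        try:
            category = atom_category(aa, name, element) if aa in STANDARD_AA else "backbone"
        except ValueError:
            category = "backbone"
        residue.atoms.append(Atom(name, element, pos, category))
    if not chains:
        raise PdbFormatError("no ATOM records found")
    return Structure([(cid, chains[cid]) for cid in order])


def read_pdb(path: str | Path) -> Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    return parse_pdb_text(path.read_text())


def format_pdb(structure: Structure) -> str:
    lines = []
    serial = 1
    for chain_id, residues in structure.chains:
        for r in residues:
            for a in r.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:>5d} {name:<4.4s} {r.aa:>3s} {chain_id}"
                    f"{r.seq_id:>4d}    "
                    f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      {residues[-1].aa:>3s} "
                     f"{chain_id}{residues[-1].seq_id:>4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: Structure, path: str | Path) -> None:
    Path(path).write_text(format_pdb(structure))
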