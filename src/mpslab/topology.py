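"""Transmembrane span model, span-file parsing, and structure-based detection.

A span is a contiguous run of residues whose CA atoms sit inside the
hydrophobic slab and whose flanks exit the slab on opposite sides — i.e. the
run actually crosses the membrane.  Span files use a small text dialect:

    <free-text comment line>
    <n_spans> <n_residues>
    <start_seq_id> <end_seq_id> [chain]     (one line per span)

Lines consisting of the historical marker words ``antiparallel``/``parallel``
or ``n2c``/``c2n`` are tolerated and skipped on read, for interoperability
with older span files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core import MembraneGeometry, Structure, signed_depth

__all__ = ["Span", "SpanningTopology", "SpanFileError", "read_span_file", "parse_span_text",
           "write_span_file", "detect_spans"]

_MARKER_WORDS = {"antiparallel", "parallel", "n2c", "c2n"}


class SpanFileError(ValueError):
    """Malformed span file; message names the offending line."""


@dataclass(frozen=True)
class Span:
    """One transmembrane crossing: (chain, start) .. (chain, end), inclusive.

    ``orientation`` is ``n2c_up`` when the chain runs from the lower to the
    upper membrane leaflet over the span, ``n2c_down`` otherwise.
    """

    chain: str
    start: int
    end: int
    orientation: str = "n2c_up"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} after end {self.end}")
        if self.orientation not in ("n2c_up", "n2c_down"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SpanningTopology:
    spans: tuple[Span, ...]
    n_residues: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", tuple(self.spans))
        by_chain: dict[str, list[Span]] = {}
        for s in self.spans:
            by_chain.setdefault(s.chain, []).append(s)
        for chain, spans in by_chain.items():
            spans = sorted(spans, key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping spans in chain {chain}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def __len__(self) -> int:
        return len(self.spans)

    def validate_against(self, structure: Structure) -> None:
        for s in self.spans:
            structure.residue(s.chain, s.start)
            structure.residue(s.chain, s.end)


def parse_span_text(text: str, default_chain: str = "A") -> SpanningTopology:
    lines = text.splitlines()
    if len(lines) < 2:
        raise SpanFileError("span file needs a comment line and a header line")
    header = lines[1].split()
    if len(header) != 2:
        raise SpanFileError(f"line 2: header must be '<n_spans> <n_residues>', got {lines[1]!r}")
    try:
        n_spans, n_residues = int(header[0]), int(header[1])
    except ValueError:
        raise SpanFileError(f"line 2: non-integer header fields in {lines[1]!r}") from None
    spans: list[Span] = []
    for lineno, raw in enumerate(lines[2:], start=3):
        fields = raw.split()
        if not fields:
            continue
        if len(fields) == 1 and fields[0].lower() in _MARKER_WORDS:
            continue  # historical Rosetta marker lines
        if len(fields) not in (2, 3):
            raise SpanFileError(f"line {lineno}: expected '<start> <end> [chain]', got {raw!r}")
        try:
            start, end = int(fields[0]), int(fields[1])
        except ValueError:
            raise SpanFileError(f"line {lineno}: non-integer span bounds in {raw!r}") from None
        if start > end:
            raise SpanFileError(f"line {lineno}: span start {start} after end {end}")
        chain = fields[2] if len(fields) == 3 else default_chain
        spans.append(Span(chain, start, end))
    if len(spans) != n_spans:
        raise SpanFileError(
            f"header declares {n_spans} spans but {len(spans)} span lines were found"
        )
    try:
        return SpanningTopology(tuple(spans), n_residues)
    except ValueError as exc:
        raise SpanFileError(str(exc)) from None


def read_span_file(path: str | Path, default_chain: str = "A") -> SpanningTopology:
    return parse_span_text(Path(path).read_text(), default_chain=default_chain)


def write_span_file(topology: SpanningTopology, comment: str = "mpslab span file") -> str:
    lines = [comment, f"{len(topology.spans)} {topology.n_residues}"]
    for s in topology.spans:
        lines.append(f"{s.start} {s.end} {s.chain}")
    return "\n".join(lines) + "\n"


def detect_spans(
    structure: Structure,
    geom: MembraneGeometry,
    min_len: int = 4,
    require_crossing: bool = True,
) -> SpanningTopology:
    """Find transmembrane spans of a structure already in membrane coordinates.

    A residue is membrane-embedded iff its CA depth satisfies
    ``|z| <= thickness/2``.  Each maximal consecutive embedded run within one
    chain becomes a span iff the run crosses the slab: the CA depths flanking
    the run (or, at chain termini, the run's own end residues) lie on opposite
    sides of the midplane.  Runs shorter than ``min_len`` are discarded.
    Orientation follows the sign of ``z(end CA) - z(start CA)``.
    """
    half = geom.half_thickness
    missing = [
        f"{r.chain}{r.seq_id}" for r in structure.residues() if not r.has_atom("CA")
    ]
    if missing:
        raise ValueError(f"residues missing CA atoms: {', '.join(missing)}")
    spans: list[Span] = []
    for chain_id, residues in structure.chains:
        z = [signed_depth(geom, r.ca) for r in residues]
        inside = [abs(d) <= half for d in z]
        i = 0
        while i < len(residues):
            if not inside[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(residues) and inside[j + 1]:
                j += 1
            z_before = z[i - 1] if i > 0 else z[i]
            z_after = z[j + 1] if j + 1 < len(residues) else z[j]
            crosses = z_before * z_after < 0
            if (j - i + 1) >= min_len and (crosses or not require_crossing):
                orientation = "n2c_up" if z[j] - z[i] >= 0 else "n2c_down"
                spans.append(Span(chain_id, residues[i].seq_id, residues[j].seq_id, orientation))
            i = j + 1
    return SpanningTopology(tuple(spans), structure.n_residues)
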