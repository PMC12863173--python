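"""GAF alignment records: parsing, writing, best-hit selection.

GAF (graph alignment format) is the graph analogue of PAF: 12 mandatory
tab-separated columns, with the path column written in oriented-segment
syntax (``>12<13`` = node 12 forward then node 13 reverse). Coordinates are
0-based half-open on both the read and the concatenated path sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TYPE_CHECKING

if TYPE_CHECKING:
    from .graph_model import SuperGraph

__all__ = ["GafRecord", "GafParseError", "read_gaf", "write_gaf",
           "best_alignment_per_read"]

Step = tuple[int, str]

MISSING_MAPQ = 255


class GafParseError(ValueError):
    pass


@dataclass
class GafRecord:
    """One read-to-graph alignment."""

    read_id: str
    read_length: int
    read_start: int
    read_end: int
    strand: str  # '+' or '-'; GAF column 5 (relative to the stated path)
    path_steps: list[Step]  # empty <=> unmapped ('*' path)
    path_length: int
    path_start: int
    path_end: int
    residue_matches: int
    block_length: int
    mapq: int
    tags: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path_steps:
            if not (0 <= self.read_start < self.read_end <= self.read_length):
                raise ValueError(
                    f"{self.read_id}: bad read interval "
                    f"[{self.read_start},{self.read_end}) / {self.read_length}")
            if not (0 <= self.path_start < self.path_end <= self.path_length):
                raise ValueError(
                    f"{self.read_id}: bad path interval "
                    f"[{self.path_start},{self.path_end}) / {self.path_length}")

    @property
    def is_mapped(self) -> bool:
        return bool(self.path_steps)

    @property
    def align_score(self) -> int:
        """AS tag when present; residue matches otherwise."""
        if "AS" in self.tags:
            return int(self.tags["AS"][1])
        return self.residue_matches

    @property
    def effective_mapq(self) -> int:
        """MAPQ with the 255 'missing' sentinel demoted to 0."""
        return 0 if self.mapq == MISSING_MAPQ else self.mapq

    @property
    def path_string(self) -> str:
        if not self.path_steps:
            return "*"
        return "".join((">" if o == "+" else "<") + str(v)
                       for v, o in self.path_steps)


def _parse_path(text: str, line_no: int) -> list[Step]:
    if text == "*":
        return []
    steps: list[Step] = []
    i = 0
    while i < len(text):
        mark = text[i]
        if mark not in "><":
            raise GafParseError(f"line {line_no}: bad path syntax {text!r}")
        j = i + 1
        while j < len(text) and text[j] not in "><":
            j += 1
        name = text[i + 1:j]
        if not name.isdigit():
            raise GafParseError(
                f"line {line_no}: non-integer segment name {name!r} "
                f"(graphs are renumbered to integer ids on load)")
        steps.append((int(name), "+" if mark == ">" else "-"))
        i = j
    return steps


def _int_field(value: str, what: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise GafParseError(
            f"line {line_no}: non-integer {what} {value!r}") from None


def read_gaf(source) -> Iterator[GafRecord]:
    """Stream records from a GAF file (path or open handle).

    Unknown tags are preserved verbatim; a ``*`` path column yields an
    unmapped record (``is_mapped`` False).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    for line_no, line in enumerate(lines, 1):
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise GafParseError(
                f"line {line_no}: expected >= 12 columns, got {len(f)}")
        tags: dict[str, tuple[str, str]] = {}
        for tag in f[12:]:
            parts = tag.split(":", 2)
            if len(parts) == 3:
                tags[parts[0]] = (parts[1], parts[2])
        steps = _parse_path(f[5], line_no)

        def num(col: int, what: str) -> int:
            # unmapped records commonly carry '*' in numeric columns
            if not steps and f[col] == "*":
                return 0
            return _int_field(f[col], what, line_no)

        yield GafRecord(
            read_id=f[0],
            read_length=_int_field(f[1], "read length", line_no),
            read_start=num(2, "read start"),
            read_end=num(3, "read end"),
            strand=f[4] if f[4] in "+-" else "+",
            path_steps=steps,
            path_length=num(6, "path length"),
            path_start=num(7, "path start"),
            path_end=num(8, "path end"),
            residue_matches=num(9, "residue matches"),
            block_length=num(10, "block length"),
            mapq=num(11, "mapq"),
            tags=tags,
        )


def write_gaf(records: Iterable[GafRecord], dest=None) -> str:
    """Serialize records to GAF text in input order, AS tag included."""
    lines = []
    for r in records:
        if r.is_mapped:
            cols = [r.read_id, r.read_length, r.read_start, r.read_end,
                    r.strand, r.path_string, r.path_length, r.path_start,
                    r.path_end, r.residue_matches, r.block_length, r.mapq]
        else:
            cols = [r.read_id, r.read_length, 0, 1, "+", "*",
                    0, 0, 0, 0, 0, r.mapq]
        tag_text = [f"{k}:{t}:{v}" for k, (t, v) in sorted(r.tags.items())]
        if "AS" not in r.tags:
            tag_text.append(f"AS:i:{r.align_score}")
        lines.append("\t".join(str(c) for c in cols + tag_text))
    text = "\n".join(lines) + ("\n" if lines else "")
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


def best_alignment_per_read(
    records: Iterable[GafRecord],
    supergraph: Optional["SuperGraph"] = None,
) -> dict[str, GafRecord]:
    """Keep exactly one optimal alignment per mapped read.

    A read aligning to several species graphs keeps only its best alignment,
    so each read contributes to a single species. Unmapped records are
    dropped. The selection key, in order: higher alignment score, higher
    MAPQ, smaller species taxid of the path's first node (when a super-graph
    is supplied), lexicographically smaller path string — fully
    deterministic and independent of input order.
    """
    def key(r: GafRecord) -> tuple:
        taxid = (supergraph.species_of_node(r.path_steps[0][0])
                 if supergraph is not None else 0)
        return (-r.align_score, -r.effective_mapq, taxid, r.path_string)

    best: dict[str, GafRecord] = {}
    for r in records:
        if not r.is_mapped:
            continue
        cur = best.get(r.read_id)
        if cur is None or key(r) < key(cur):
            best[r.read_id] = r
    return best
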