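"""Per-base read-depth tables (``contig<TAB>pos<TAB>depth``, 1-based pos)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from snbp.errors import ParseError


class DepthTable:
    """Depths per contig as dense arrays indexed by 0-based position.

    Positions absent from the file are 0. ``lengths`` may extend a contig
    beyond its last covered base.
    """

    def __init__(self, depths: dict[str, np.ndarray]):
        self._depths = {c: np.asarray(d, dtype=np.int64) for c, d in depths.items()}
        for c, d in self._depths.items():
            if (d < 0).any():
                raise ValueError(f"negative depth on contig {c!r}")

    @property
    def contigs(self) -> list[str]:
        return sorted(self._depths)

    def depth(self, contig: str) -> np.ndarray:
        return self._depths[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._depths

    def __len__(self) -> int:
        return len(self._depths)


def read_depth(path, lengths: dict[str, int] | None = None) -> DepthTable:
    """Read a depth TSV. ``lengths`` optionally fixes each contig's length."""
    path = Path(path)
    raw: dict[str, list[tuple[int, int]]] = {}
    seen: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 columns, got {len(fields)}", path=path, line=lineno
                )
            contig, pos_s, depth_s = fields
            try:
                pos1 = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise ParseError(
                    f"non-numeric field {pos_s!r}/{depth_s!r}", path=path, line=lineno
                ) from None
            if pos1 < 1:
                raise ParseError(f"position {pos1} must be >= 1", path=path, line=lineno)
            if depth < 0:
                raise ParseError(f"negative depth {depth}", path=path, line=lineno)
            if pos1 in seen.setdefault(contig, set()):
                raise ParseError(
                    f"duplicate position {pos1} on contig {contig!r}",
                    path=path,
                    line=lineno,
                )
            seen[contig].add(pos1)
            raw.setdefault(contig, []).append((pos1 - 1, depth))
    depths: dict[str, np.ndarray] = {}
    for contig, pairs in raw.items():
        max_pos = max(p for p, _ in pairs) + 1
        length = max(max_pos, (lengths or {}).get(contig, 0))
        arr = np.zeros(length, dtype=np.int64)
        for p, d in pairs:
            arr[p] = d
        depths[contig] = arr
    if lengths:
        for contig, length in lengths.items():
            if contig not in depths:
                depths[contig] = np.zeros(length, dtype=np.int64)
    return DepthTable(depths)


def write_depth(table: DepthTable, path, omit_zero: bool = False) -> None:
    with open(path, "w") as fh:
        for contig in table.contigs:
            arr = table.depth(contig)
            for i, d in enumerate(arr):
                if omit_zero and d == 0:
                    continue
                fh.write(f"{contig}\t{i + 1}\t{int(d)}\n")
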