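"""UCSC chain-format parsing and point coordinate liftover.

A chain describes a blockwise alignment between a source ("target" in chain
nomenclature — the assembly the query coordinates live in) and a destination
("query") assembly.  Only point lifting is implemented: a 1-based position
inside an aligned block maps by offset arithmetic; positions falling in a
gap of the best covering chain are unmapped, mirroring how editing-database
coordinates published on an older assembly are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


class ChainParseError(ValueError):
    pass


@dataclass(frozen=True)
class Chain:
    score: int
    t_name: str
    t_size: int
    t_start: int  # 0-based half-open on source
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int  # 0-based on q_strand
    q_end: int
    blocks: tuple  # ((t_block_start0, q_block_start0, size), ...)


class ChainMap:
    """All chains of a chain file, ordered by score (highest first)."""

    def __init__(self, chains):
        self.chains = sorted(chains, key=lambda c: -c.score)
        self._by_source: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_source.setdefault(c.t_name, []).append(c)

    def __len__(self):
        return len(self.chains)

    @classmethod
    def from_file(cls, path: str) -> "ChainMap":
        chains = []
        header = None
        blocks: list[tuple] = []
        t_cursor = q_cursor = 0

        def finish(lineno):
            nonlocal header, blocks
            if header is None:
                return
            c = Chain(*header, blocks=tuple(blocks))
            if t_cursor != c.t_end or q_cursor != c.q_end:
                raise ChainParseError(
                    f"{path}:{lineno}: chain blocks do not sum to the "
                    f"declared spans"
                )
            chains.append(c)
            header = None
            blocks = []

        lineno = 0
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line:
                    continue
                fields = line.split()
                if fields[0] == "chain":
                    finish(lineno)
                    if len(fields) not in (12, 13):
                        raise ChainParseError(
                            f"{path}:{lineno}: malformed chain header"
                        )
                    (score, t_name, t_size, t_strand, t_start, t_end,
                     q_name, q_size, q_strand, q_start, q_end) = fields[1:12]
                    if t_strand != "+":
                        raise ChainParseError(
                            f"{path}:{lineno}: source strand must be '+'"
                        )
                    if q_strand not in ("+", "-"):
                        raise ChainParseError(
                            f"{path}:{lineno}: bad destination strand"
                        )
                    header = (int(score), t_name, int(t_size), int(t_start),
                              int(t_end), q_name, int(q_size), q_strand,
                              int(q_start), int(q_end))
                    t_cursor = int(t_start)
                    q_cursor = int(q_start)
                elif header is not None:
                    try:
                        nums = [int(x) for x in fields]
                    except ValueError as exc:
                        raise ChainParseError(
                            f"{path}:{lineno}: non-integer block line"
                        ) from exc
                    if len(nums) == 1:
                        size = nums[0]
                        dt = dq = 0
                    elif len(nums) == 3:
                        size, dt, dq = nums
                    else:
                        raise ChainParseError(
                            f"{path}:{lineno}: block line needs 1 or 3 fields"
                        )
                    blocks.append((t_cursor, q_cursor, size))
                    t_cursor += size + dt
                    q_cursor += size + dq
                else:
                    raise ChainParseError(
                        f"{path}:{lineno}: data outside a chain"
                    )
            finish(lineno)
        return cls(chains)

    def chains_for(self, chrom: str):
        return self._by_source.get(chrom, [])


def liftover_point(
    chrom: str, pos: int, chain_map: ChainMap
) -> Optional[tuple[str, int, bool]]:
    """Lift a 1-based point; returns (chrom, pos, strand_flipped) or None.

    The highest-scoring chain whose source span covers the point decides:
    inside one of its aligned blocks the point maps by offset (with
    reverse-coordinate arithmetic for '-'-strand destinations); inside a gap
    it is unmapped.
    """
    p0 = pos - 1
    for c in chain_map.chains_for(chrom):
        if not (c.t_start <= p0 < c.t_end):
            continue
        for t_bs, q_bs, size in c.blocks:
            if t_bs <= p0 < t_bs + size:
                q0 = q_bs + (p0 - t_bs)
                if c.q_strand == "-":
                    q_plus0 = c.q_size - 1 - q0
                    return (c.q_name, q_plus0 + 1, True)
                return (c.q_name, q0 + 1, False)
        return None  # in a gap of the best covering chain
    return None


def finishing_check(chain: Chain) -> None:
    """Validate the within-chain invariants (disjoint, increasing blocks)."""
    prev_end = -1
    for t_bs, _q_bs, size in chain.blocks:
        if t_bs <= prev_end:
            raise ChainParseError("chain blocks overlap or are unordered")
        prev_end = t_bs + size - 1
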