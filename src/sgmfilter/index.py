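"""Protein database index: discretized residue-mass text and its suffix tree.

Every database protein is rendered as its sequence of discretized residue
masses; all proteins are concatenated into a single integer text, with a
*unique* negative separator symbol at each junction so that no substring can
bridge two proteins and no artificial repeat enters the tree.  The suffix
tree over this text (Ukkonen's linear-time construction, dictionary
transitions suited to the 19-symbol integer alphabet) supports the
cursor-at-a-time descent that the graph search needs: a cursor pinpoints a
position inside the tree — possibly in the middle of a compressed edge — and
advances one symbol at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Tuple

from Bio import SeqIO

from .alphabet import ResidueAlphabet

__all__ = [
    "ProteinText",
    "SuffixTree",
    "Cursor",
    "build_protein_text",
    "build_suffix_tree",
    "occurrences",
]

logger = logging.getLogger(__name__)

# letters whose residue mass is undefined; they break matchable runs
_AMBIGUOUS = set("BZJXUO*")


@dataclass
class ProteinText:
    """Concatenated discretized protein database with boundary bookkeeping."""

    symbols: List[int]
    #: original database letter per position (None at separators)
    letters: List[Optional[str]]
    #: per position: (protein index, within-protein offset); (-1, -1) at separators
    positions: List[Tuple[int, int]]
    protein_ids: List[str]
    sequences: List[str]
    alphabet: ResidueAlphabet

    @property
    def n(self) -> int:
        return len(self.symbols)

    def locate(self, pos: int) -> Tuple[str, int]:
        """Map a text position to (protein id, within-protein offset)."""
        p, off = self.positions[pos]
        if p < 0:
            raise ValueError(f"position {pos} is a separator")
        return self.protein_ids[p], off

    def render(self, pos: int, length: int) -> str:
        """Original database letters of text[pos : pos + length]."""
        out = self.letters[pos : pos + length]
        if any(c is None for c in out):
            raise ValueError("substring spans a separator")
        return "".join(out)  # type: ignore[arg-type]


def build_protein_text(
    fasta: str | Path | Sequence[Tuple[str, str]],
    alphabet: ResidueAlphabet,
) -> ProteinText:
    """Discretize a FASTA database (or a list of (id, sequence) pairs).

    Proteins are concatenated in file order.  Each junction gets a fresh
    negative separator symbol; ambiguity letters (B/Z/J/X/U/O) also become
    separators since their residue masses are undefined.
    """
    if isinstance(fasta, (str, Path)):
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records found in {fasta}")
    else:
        records = list(fasta)
        if not records:
            raise ValueError("empty protein database")
    mass_of = alphabet.int_mass_of
    symbols: List[int] = []
    letters: List[Optional[str]] = []
    positions: List[Tuple[int, int]] = []
    protein_ids: List[str] = []
    sequences: List[str] = []
    next_sep = -1

    def sep() -> int:
        nonlocal next_sep
        s = next_sep
        next_sep -= 1
        return s

    for p_idx, (pid, seq) in enumerate(records):
        if p_idx > 0:
            symbols.append(sep())
            letters.append(None)
            positions.append((-1, -1))
        protein_ids.append(pid)
        sequences.append(seq)
        for off, aa in enumerate(seq.upper()):
            m = mass_of.get(aa)
            if m is None:
                if aa not in _AMBIGUOUS:
                    logger.warning("protein %s: unknown residue %r treated as break",
                                   pid, aa)
                symbols.append(sep())
                letters.append(None)
                positions.append((-1, -1))
            else:
                symbols.append(m)
                letters.append(aa)
                positions.append((p_idx, off))
    return ProteinText(
        symbols=symbols,
        letters=letters,
        positions=positions,
        protein_ids=protein_ids,
        sequences=sequences,
        alphabet=alphabet,
    )


class Cursor(NamedTuple):
    """A position in the suffix tree: ``node`` whose incoming edge has been
    matched through ``off`` symbols (``off`` equals the edge length when the
    cursor sits exactly on the node; the root is ``(root, 0)``)."""

    node: int
    off: int


class SuffixTree:
    """Ukkonen suffix tree over an integer sequence.

    A unique sentinel symbol is appended so that every suffix ends at a leaf.
    Nodes are integers; per-node arrays hold edge start, edge end, parent,
    suffix link and children (dict keyed by first edge symbol).  Leaves store
    the start position of their suffix.
    """

    def __init__(self, text: Sequence[int]) -> None:
        if len(text) == 0:
            raise ValueError("cannot index an empty text")
        sentinel = min(min(text), 0) - 1
        self.text: List[int] = list(text) + [sentinel]
        self.sentinel = sentinel
        # node arrays; node 0 is the root
        self.start = [0]
        self.end = [0]          # exclusive end; open leaves hold _OPEN until frozen
        self.children: List[Dict[int, int]] = [{}]
        self.slink = [0]
        self._build()
        self._leaf_suffix: Dict[int, int] = {}
        self._depth = [0] * len(self.start)
        self._assign_depths_and_suffixes()

    # -- construction ---------------------------------------------------

    _OPEN = 1 << 60

    def _new_node(self, start: int, end: int) -> int:
        self.start.append(start)
        self.end.append(end)
        self.children.append({})
        self.slink.append(0)
        return len(self.start) - 1

    def _edge_len(self, v: int) -> int:
        return self.end[v] - self.start[v]

    def _build(self) -> None:
        text = self.text
        n = len(text)
        OPEN = self._OPEN
        active_node = 0
        active_edge = 0   # index into text of the first symbol on the active edge
        active_len = 0
        remainder = 0
        for i in range(n):
            remainder += 1
            last_internal = -1
            while remainder > 0:
                if active_len == 0:
                    active_edge = i
                first = text[active_edge]
                nxt = self.children[active_node].get(first)
                if nxt is None:
                    leaf = self._new_node(i, OPEN)
                    self.children[active_node][first] = leaf
                    if last_internal != -1:
                        self.slink[last_internal] = active_node
                        last_internal = -1
                else:
                    span = min(self.end[nxt], i + 1) - self.start[nxt]
                    if active_len >= span:
                        active_edge += span
                        active_len -= span
                        active_node = nxt
                        continue
                    if text[self.start[nxt] + active_len] == text[i]:
                        active_len += 1
                        if last_internal != -1:
                            self.slink[last_internal] = active_node
                            last_internal = -1
                        break
                    split = self._new_node(self.start[nxt], self.start[nxt] + active_len)
                    self.children[active_node][first] = split
                    leaf = self._new_node(i, OPEN)
                    self.children[split][text[i]] = leaf
                    self.start[nxt] += active_len
                    self.children[split][text[self.start[nxt]]] = nxt
                    if last_internal != -1:
                        self.slink[last_internal] = split
                    last_internal = split
                remainder -= 1
                if active_node == 0 and active_len > 0:
                    active_len -= 1
                    active_edge = i - remainder + 1
                elif active_node != 0:
                    active_node = self.slink[active_node]
        for v in range(len(self.start)):
            if self.end[v] == OPEN:
                self.end[v] = n

    def _assign_depths_and_suffixes(self) -> None:
        n = len(self.text)
        stack = [(0, 0)]
        while stack:
            v, parent_depth = stack.pop()
            d = parent_depth + self._edge_len(v) if v != 0 else 0
            self._depth[v] = d
            if not self.children[v]:
                self._leaf_suffix[v] = n - d
            else:
                for c in self.children[v].values():
                    stack.append((c, d))

    # -- cursor interface ------------------------------------------------

    @property
    def root(self) -> Cursor:
        return Cursor(0, 0)

    def depth(self, cur: Cursor) -> int:
        """Number of symbols spelled from the root to the cursor."""
        v = cur.node
        if v == 0:
            return 0
        return self._depth[v] - self._edge_len(v) + cur.off

    def advance(self, cur: Cursor, symbol: int) -> Optional[Cursor]:
        """Advance one symbol; None if the tree has no such continuation."""
        v, off = cur
        if v == 0 or off == self._edge_len(v):
            child = self.children[v].get(symbol)
            if child is None:
                return None
            return Cursor(child, 1)
        if self.text[self.start[v] + off] == symbol:
            return Cursor(v, off + 1)
        return None

    def next_symbols(self, cur: Cursor) -> Iterator[Tuple[int, Cursor]]:
        """All (symbol, advanced cursor) continuations, sorted by symbol."""
        v, off = cur
        if v == 0 or off == self._edge_len(v):
            for sym in sorted(self.children[v]):
                yield sym, Cursor(self.children[v][sym], 1)
        else:
            yield self.text[self.start[v] + off], Cursor(v, off + 1)

    def walk(self, symbols: Sequence[int]) -> Optional[Cursor]:
        cur: Optional[Cursor] = self.root
        for s in symbols:
            cur = self.advance(cur, s)
            if cur is None:
                return None
        return cur

    def leaf_positions(self, cur: Cursor) -> List[int]:
        """Suffix start positions of all leaves below the cursor, sorted."""
        out: List[int] = []
        stack = [cur.node]
        if cur.node == 0 and cur.off == 0:
            stack = [0]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(self._leaf_suffix[v])
            else:
                stack.extend(self.children[v].values())
        out.sort()
        return out

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_suffix)


@dataclass
class ProteinIndex:
    """A protein text together with its suffix tree, ready for search."""

    text: ProteinText
    tree: SuffixTree

    @classmethod
    def build(
        cls,
        fasta: str | Path | Sequence[Tuple[str, str]],
        alphabet: ResidueAlphabet,
    ) -> "ProteinIndex":
        text = build_protein_text(fasta, alphabet)
        return cls(text=text, tree=build_suffix_tree(text))


def build_suffix_tree(text: ProteinText | Sequence[int]) -> SuffixTree:
    """Suffix tree over a :class:`ProteinText` (or a raw integer sequence)."""
    symbols = text.symbols if isinstance(text, ProteinText) else list(text)
    return SuffixTree(symbols)


def occurrences(tree: SuffixTree, query: Sequence[int]) -> List[int]:
    """All start positions where ``query`` occurs in the indexed text."""
    if len(query) == 0:
        return list(range(len(tree.text) - 1))
    cur = tree.walk(query)
    if cur is None:
        return []
    return tree.leaf_positions(cur)
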