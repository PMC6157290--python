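"""Spectrum-graph matching against a suffix-tree protein index.

The restricted search (:func:`rsgm`) fixes a start node of the spectrum graph
and propagates sets ``B_i`` of suffix-tree cursors — one per *identifiable*
prefix text string of node ``v_i``, i.e. per candidate spelling that actually
occurs somewhere in the database.  An edge labeled with integer mass ``e`` is
traversed by walking each cursor down the tree along every residue string
whose mass lies within the integer tolerance of ``e``; spellings absent from
the database die immediately, which is what makes the search fast.  The full
search (:func:`sgm`) unions the restricted searches over all admissible start
nodes (within ``beta`` Da of the lightest node) and reports matches ending
within ``beta`` Da of the heaviest node.

Candidate proteins are ranked by similarity score (best path score of any
matching pattern) and, by default, re-scored with the extended similarity
score, which aligns the whole shifted theoretical fragment ladder with the
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .alphabet import CompositionTable, ResidueAlphabet
from .graph import SpectrumGraph, build_spectrum_graph, terminal_sets
from .index import Cursor, ProteinIndex, ProteinText, SuffixTree
from .intervals import reverse_interval, select_intervals
from .spectrum import DeconvolutedSpectrum, FragmentScores, filter_noise, score_fragments

__all__ = [
    "GraphMatch",
    "CandidateScore",
    "CandidateRanking",
    "SGMParams",
    "rsgm",
    "sgm",
    "naive_sgm",
    "similarity_score",
    "extended_similarity_score",
    "filter_database",
    "filtration_efficiency",
]

_NAIVE_PATH_LIMIT = 100_000


@dataclass(frozen=True)
class GraphMatch:
    """One database substring matched by a spectrum-graph path."""

    protein_id: str
    start_offset: int
    matched_residues: str
    path_nodes: int
    path_score: float
    orientation: str = "forward"
    graph_id: str = "g0"
    #: experimental mass of the first node on the matching path (graph frame)
    first_node_mass: float = 0.0

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.protein_id, self.start_offset, self.matched_residues)


@dataclass
class CandidateScore:
    protein_id: str
    similarity: float
    extended: Optional[float] = None
    best_match: Optional[GraphMatch] = None


@dataclass
class CandidateRanking:
    """Top-K candidate proteins for one spectrum, best first."""

    spectrum_id: str
    entries: List[CandidateScore]
    top_k: int

    def protein_ids(self) -> List[str]:
        return [e.protein_id for e in self.entries]


@dataclass
class SGMParams:
    """Tunable parameters of the filtering pipeline (all masses in Da)."""

    alpha: float = 350.0        # max explained gap between connected nodes
    beta: float = 250.0         # terminal-set bound from the graph extremes
    delta: float = 900.0        # mass-interval width
    gamma: int = 20             # max intervals per spectrum
    rho: float = 0.2            # max interval overlap ratio
    lam: float = 8              # noise-filter rank cutoff (math.inf disables)
    epsilon: float = 0.02       # fragment mass tolerance
    scale: int = 100            # discretization scale factor
    max_out_degree: int = 3     # spectrum-graph out-degree cap d
    top_k: int = 20             # candidates reported per spectrum
    score_scheme: str = "mass_count"
    extended: bool = True       # rank by extended similarity score
    use_reversed: bool = True   # also search reversed mass intervals


def _extend_cursor(
    tree: SuffixTree, cursor: Cursor, label: int, tol: int, min_mass: int
) -> List[Cursor]:
    """All cursors reached from ``cursor`` by spelling a residue string whose
    total mass lies within ``tol`` of ``label`` (depth-first, mass-pruned)."""
    out: List[Cursor] = []
    stack: List[Tuple[Cursor, int]] = [(cursor, 0)]
    hi = label + tol
    lo = label - tol
    while stack:
        cur, acc = stack.pop()
        for sym, nxt in tree.next_symbols(cur):
            if sym <= 0:  # separator / sentinel: not a residue
                continue
            a = acc + sym
            if a > hi:
                continue
            if a >= lo:
                out.append(nxt)
            if a + min_mass <= hi:
                stack.append((nxt, a))
    return out


def rsgm(
    graph: SpectrumGraph,
    start: int,
    tree: SuffixTree,
    table: CompositionTable,
    ends: Set[int],
    text: ProteinText,
) -> List[GraphMatch]:
    """Restricted search: matches for paths from ``start`` to any node in
    ``ends``, via identifiable-prefix pruning on the suffix tree."""
    if not 0 <= start < graph.n_nodes:
        raise ValueError(f"start node {start} not in graph")
    tol = table.tol
    min_mass = table.alphabet.min_int_mass
    # B[i]: cursor -> (best path score, node count of that path)
    B: List[Dict[Cursor, Tuple[float, int]]] = [dict() for _ in range(graph.n_nodes)]
    B[start][tree.root] = (float(graph.scores[start]), 1)
    for j in range(start, graph.n_nodes):
        if not B[j]:
            continue
        for i, label in graph.edges[j]:
            tgt = B[i]
            score_i = float(graph.scores[i])
            for cur, (sc, cnt) in B[j].items():
                for nxt in _extend_cursor(tree, cur, label, tol, min_mass):
                    cand = (sc + score_i, cnt + 1)
                    old = tgt.get(nxt)
                    if old is None or cand > old:
                        tgt[nxt] = cand
    best: Dict[Tuple[str, int, str], GraphMatch] = {}
    first_mass = float(graph.masses[start])
    for i in ends:
        if i <= start or not B[i]:
            continue
        for cur, (sc, cnt) in B[i].items():
            depth = tree.depth(cur)
            for pos in tree.leaf_positions(cur):
                pid, off = text.locate(pos)
                m = GraphMatch(
                    protein_id=pid,
                    start_offset=off,
                    matched_residues=text.render(pos, depth),
                    path_nodes=cnt,
                    path_score=sc,
                    orientation=graph.orientation,
                    graph_id=graph.graph_id,
                    first_node_mass=first_mass,
                )
                old = best.get(m.key)
                if old is None or (m.path_score, m.path_nodes) > (
                    old.path_score,
                    old.path_nodes,
                ):
                    best[m.key] = m
    return list(best.values())


def _merge_matches(matches: Iterable[GraphMatch]) -> List[GraphMatch]:
    best: Dict[Tuple[str, int, str], GraphMatch] = {}
    for m in matches:
        old = best.get(m.key)
        if old is None or (m.path_score, m.path_nodes) > (old.path_score, old.path_nodes):
            best[m.key] = m
    return sorted(
        best.values(), key=lambda m: (m.protein_id, m.start_offset, m.matched_residues)
    )


def sgm(
    graph: SpectrumGraph,
    tree: SuffixTree,
    table: CompositionTable,
    beta: float,
    text: ProteinText,
) -> List[GraphMatch]:
    """Full search: union of restricted searches from every admissible start
    node, deduplicated by (protein, offset, residues) keeping the best score."""
    if graph.n_nodes < 2:
        return []
    ts = terminal_sets(graph, beta)
    all_matches: List[GraphMatch] = []
    for s in sorted(ts.V_s):
        all_matches.extend(rsgm(graph, s, tree, table, ts.V_t, text))
    return _merge_matches(all_matches)


def _enumerate_paths(graph: SpectrumGraph, s: int, t: int) -> List[List[int]]:
    """All s -> t paths as node-index lists (labels recoverable from nodes)."""
    out: List[List[int]] = []
    path = [s]

    def dfs(u: int) -> None:
        if u == t:
            out.append(list(path))
            return
        if len(out) > _NAIVE_PATH_LIMIT:
            raise RuntimeError("path explosion in naive search; use smaller fixtures")
        for v, _lab in graph.edges[u]:
            if v > t:
                continue
            path.append(v)
            dfs(v)
            path.pop()

    dfs(s)
    return out


def _pattern_matches_at(
    symbols: Sequence[int], pos: int, pattern: Sequence[int], tol: int
) -> List[int]:
    """End positions of partitions of text starting at ``pos`` whose
    consecutive-substring masses equal ``pattern`` within ``tol`` per element."""
    ends: List[int] = []
    n = len(symbols)

    def rec(p: int, k: int) -> None:
        if k == len(pattern):
            ends.append(p)
            return
        target = pattern[k]
        acc = 0
        q = p
        while q < n:
            s = symbols[q]
            if s <= 0:
                break
            acc += s
            q += 1
            if acc > target + tol:
                break
            if acc >= target - tol:
                rec(q, k + 1)

    rec(pos, 0)
    return ends


def naive_sgm(
    graph: SpectrumGraph,
    text: ProteinText,
    beta: float,
    table: CompositionTable,
) -> List[GraphMatch]:
    """Brute-force reference search: enumerate every admissible path and scan
    the text position by position.  Equivalent to :func:`sgm` by construction;
    only usable on small inputs."""
    if graph.n_nodes < 2:
        return []
    ts = terminal_sets(graph, beta)
    tol = table.tol
    symbols = text.symbols
    matches: List[GraphMatch] = []
    for s in sorted(ts.V_s):
        for t in sorted(ts.V_t):
            if t <= s:
                continue
            for path in _enumerate_paths(graph, s, t):
                pattern = [
                    int(graph.int_masses[b] - graph.int_masses[a])
                    for a, b in zip(path, path[1:])
                ]
                sc = float(graph.scores[path].sum())
                for pos in range(len(symbols)):
                    if symbols[pos] <= 0:
                        continue
                    for end in _pattern_matches_at(symbols, pos, pattern, tol):
                        pid, off = text.locate(pos)
                        matches.append(
                            GraphMatch(
                                protein_id=pid,
                                start_offset=off,
                                matched_residues=text.render(pos, end - pos),
                                path_nodes=len(path),
                                path_score=sc,
                                orientation=graph.orientation,
                                graph_id=graph.graph_id,
                                first_node_mass=float(graph.masses[s]),
                            )
                        )
    return _merge_matches(matches)


def similarity_score(matches: Iterable[GraphMatch]) -> Dict[str, float]:
    """Per protein, the best path score over all matches from all graphs."""
    out: Dict[str, float] = {}
    for m in matches:
        if m.path_score > out.get(m.protein_id, 0.0):
            out[m.protein_id] = m.path_score
    return out


def _prefix_masses(protein_seq: str, alphabet: ResidueAlphabet) -> np.ndarray:
    masses = np.array([alphabet.residues[aa] for aa in protein_seq])
    return np.concatenate([[0.0], np.cumsum(masses)])


def extended_similarity_score(
    spectrum: DeconvolutedSpectrum,
    protein_seq: str,
    best_match: GraphMatch,
    epsilon: float,
    alphabet: ResidueAlphabet,
    scores: Optional[FragmentScores] = None,
) -> float:
    """Similarity score after aligning the whole shifted theoretical ladder.

    The mass shift is fixed by the first node of the best match: it is the
    difference between that node's experimental mass and the theoretical
    prefix mass of the protein at the match's start offset.  All theoretical
    cleavage masses are shifted by it and every experimental fragment mass
    within ``epsilon`` of a shifted value is counted once (or its fragment
    score summed, when a scoring scheme is active).  For reversed-orientation
    matches the spectrum is mirrored through the precursor mass first, which
    turns its suffix-fragment ladder back into the prefix frame.
    """
    k = best_match.start_offset
    sub = protein_seq[k : k + len(best_match.matched_residues)]
    if sub != best_match.matched_residues:
        raise ValueError(
            f"match residues {best_match.matched_residues!r} are not found at "
            f"offset {k} of protein {best_match.protein_id}"
        )
    if len(spectrum) == 0 or len(protein_seq) < 2:
        return 0.0
    prefix = _prefix_masses(protein_seq, alphabet)
    ladder = prefix[1:-1]  # internal cleavage sites
    shift = best_match.first_node_mass - prefix[k]
    if best_match.orientation == "reversed":
        exp = spectrum.precursor_mass - spectrum.masses
    else:
        exp = spectrum.masses
    theo = ladder + shift
    hit = np.abs(exp[:, None] - theo[None, :]).min(axis=1) <= epsilon
    if scores is not None and scores.scheme != "mass_count":
        return float(np.asarray(scores.scores)[hit].sum())
    return float(hit.sum())


def filter_database(
    spectrum: DeconvolutedSpectrum,
    index: ProteinIndex,
    table: CompositionTable,
    params: SGMParams | None = None,
) -> CandidateRanking:
    """Run the full filtering pipeline for one spectrum.

    Noise filtering, fragment scoring, interval selection (plus reversed
    intervals), one spectrum graph per interval, suffix-tree search per graph,
    per-protein similarity scoring and (by default) extended-score re-ranking.
    Deterministic for fixed inputs and parameters.
    """
    params = params or SGMParams()
    sp = filter_noise(spectrum, params.lam)
    empty = CandidateRanking(spectrum_id=spectrum.spectrum_id, entries=[],
                             top_k=params.top_k)
    if len(sp) == 0:
        return empty
    scores = score_fragments(sp, params.score_scheme)
    intervals = select_intervals(sp, params.delta, params.gamma, params.rho)
    if not intervals:
        return empty
    graphs: List[SpectrumGraph] = []
    for gi, itv in enumerate(intervals):
        graphs.append(
            build_spectrum_graph(itv, table, params.alpha, params.epsilon,
                                 params.max_out_degree, scores, graph_id=f"g{gi}f")
        )
        if params.use_reversed and sp.precursor_mass > itv.hi:
            rev = reverse_interval(itv, sp.precursor_mass)
            graphs.append(
                build_spectrum_graph(rev, table, params.alpha, params.epsilon,
                                     params.max_out_degree, scores,
                                     graph_id=f"g{gi}r")
            )
    matches: List[GraphMatch] = []
    for g in graphs:
        matches.extend(sgm(g, index.tree, table, params.beta, index.text))
    if not matches:
        return empty
    best_per_protein: Dict[str, GraphMatch] = {}
    for m in matches:
        old = best_per_protein.get(m.protein_id)
        if old is None or (m.path_score, m.path_nodes) > (old.path_score, old.path_nodes):
            best_per_protein[m.protein_id] = m
    db_order = {pid: i for i, pid in enumerate(index.text.protein_ids)}
    seq_of = dict(zip(index.text.protein_ids, index.text.sequences))
    entries: List[CandidateScore] = []
    for pid, m in best_per_protein.items():
        ext = None
        if params.extended:
            ext = extended_similarity_score(
                sp, seq_of[pid], m, params.epsilon, table.alphabet, scores
            )
        entries.append(CandidateScore(protein_id=pid, similarity=m.path_score,
                                      extended=ext, best_match=m))
    if params.extended:
        entries.sort(key=lambda e: (-e.extended, -e.similarity, db_order[e.protein_id]))
    else:
        entries.sort(key=lambda e: (-e.similarity, db_order[e.protein_id]))
    return CandidateRanking(
        spectrum_id=spectrum.spectrum_id,
        entries=entries[: params.top_k],
        top_k=params.top_k,
    )


def filtration_efficiency(
    rankings: Iterable[CandidateRanking],
    truth: Mapping[str, str],
    top_k: int,
) -> float:
    """Fraction of spectra whose true protein appears in the top ``top_k``."""
    if not truth:
        raise ValueError("truth mapping is empty")
    by_id = {r.spectrum_id: r for r in rankings}
    hits = 0
    for sid, pid in truth.items():
        r = by_id.get(sid)
        if r is not None and pid in r.protein_ids()[:top_k]:
            hits += 1
    return hits / len(truth)
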