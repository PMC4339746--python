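"""Evidence graph: cluster split-read and paired-end observations into
indel calls.

Every piece of evidence is a vertex.  Two split-read vertices are joined
iff they support the identical left-aligned breakpoints; two paired-end
vertices are joined iff a single event placement satisfies both pairs'
outer-distance constraints.  Split-read vertices are never joined to
paired-end vertices.  Each connected component is one putative variant;
its breakpoints come from a greedily grown maximal clique, while the
whole component counts as support.  A final sorted sweep merges adjacent
split-read-only and paired-end-only calls describing the same event.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from .pairs import PairedEndEvidence
from .splitread import SplitReadEvidence

Evidence = Union[SplitReadEvidence, PairedEndEvidence]


@dataclass
class IndelCall:
    """A resolved variant.

    Breakpoints are exact (confidence intervals of width zero) whenever at
    least one split read supports the call; paired-end-only calls place
    the breakpoints at interval midpoints with ``ci_left``/``ci_right``
    recording the admissible ranges as offsets relative to the point.
    """

    kind: str
    chrom: str
    bp_left: int
    bp_right: int
    ci_left: Tuple[int, int] = (0, 0)
    ci_right: Tuple[int, int] = (0, 0)
    ins_seq: Optional[str] = None
    n_sr: int = 0
    n_pe: int = 0
    size_min: Optional[int] = None
    size_max: Optional[int] = None
    evidence: List[Evidence] = field(default_factory=list)
    annotations: Optional[object] = None
    info: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sr + self.n_pe < 1:
            raise ValueError("a call needs at least one supporting observation")
        if self.n_sr >= 1 and (self.ci_left != (0, 0) or self.ci_right != (0, 0)):
            raise ValueError("split-read-resolved calls have zero-width intervals")

    @property
    def size(self) -> Optional[int]:
        if self.kind == "DEL":
            return self.bp_right - self.bp_left
        if self.ins_seq is not None:
            return len(self.ins_seq)
        if self.size_min is not None and self.size_max is not None:
            return (self.size_min + self.size_max) // 2
        return None

    @property
    def support(self) -> int:
        return self.n_sr + self.n_pe


def _is_sr(e: Evidence) -> bool:
    return isinstance(e, SplitReadEvidence)


def pe_compatible(e1: PairedEndEvidence, e2: PairedEndEvidence) -> bool:
    """True iff one event placement satisfies both pairs' constraints
    (2-D box intersection over breakpoint position and event size)."""
    if e1.kind != e2.kind or e1.chrom != e2.chrom:
        return False
    smin = max(e1.size_min, e2.size_min)
    smax = min(e1.size_max, e2.size_max)
    if smin > smax:
        return False
    L = max(e1.inner_left, e2.inner_left)
    R = min(e1.inner_right, e2.inner_right)
    if e1.kind == "DEL":
        return L + smin <= R
    return L <= R


def build_graph(evidences: Sequence[Evidence]) -> nx.Graph:
    """Build the evidence graph over one chromosome's observations.

    Vertices are indices into ``evidences`` (stored as the ``ev`` node
    attribute); no edge ever joins a split-read vertex to a paired-end
    vertex.
    """
    G = nx.Graph()
    for idx, ev in enumerate(evidences):
        G.add_node(idx, ev=ev)

    sr_groups: Dict[tuple, List[int]] = {}
    pe_idx: List[int] = []
    for idx, ev in enumerate(evidences):
        if _is_sr(ev):
            sr_groups.setdefault((ev.chrom,) + ev.key(), []).append(idx)
        else:
            pe_idx.append(idx)

    for group in sr_groups.values():
        for u, v in itertools.combinations(group, 2):
            G.add_edge(u, v)

    pe_idx.sort(key=lambda i: (evidences[i].inner_left, evidences[i].inner_right))
    for ai in range(len(pe_idx)):
        u = pe_idx[ai]
        eu = evidences[u]
        for bi in range(ai + 1, len(pe_idx)):
            v = pe_idx[bi]
            ev = evidences[v]
            if ev.inner_left > eu.inner_right:
                break
            if pe_compatible(eu, ev):
                G.add_edge(u, v)
    return G


def connected_components(G: nx.Graph) -> List[Set[int]]:
    """Partition the graph into maximal connected vertex sets, ordered by
    smallest member for determinism."""
    return sorted(nx.connected_components(G), key=min)


def _vertex_pos(ev: Evidence) -> int:
    return ev.bp_left if _is_sr(ev) else ev.inner_left


def greedy_clique(G: nx.Graph, component: Set[int]) -> List[int]:
    """Grow a maximal clique: seed with the highest-degree vertex, then
    repeatedly add the highest-degree vertex adjacent to every member
    (ties: leftmost breakpoint, then index)."""
    def key(v: int):
        ev = G.nodes[v].get("ev")
        return (-G.degree(v), _vertex_pos(ev) if ev is not None else 0, v)

    members = sorted(component, key=key)
    clique = [members[0]]
    in_clique = {members[0]}
    changed = True
    while changed:
        changed = False
        for v in members:
            if v in in_clique:
                continue
            if all(G.has_edge(v, u) for u in clique):
                clique.append(v)
                in_clique.add(v)
                changed = True
                break
    return clique


def clique_breakpoints(component: Set[int], G: nx.Graph, chrom: str = "") -> IndelCall:
    """Resolve one component to a call.

    Breakpoints come from the greedy maximal clique; support counts come
    from the whole component.  Split-read cliques share exact breakpoints;
    paired-end cliques place the call at the midpoint of the intersection
    of all members' admissible intervals, which also defines the
    confidence intervals.
    """
    if not component:
        raise ValueError("empty component")
    clique = greedy_clique(G, component)
    evs = [G.nodes[v]["ev"] for v in sorted(component)]
    cl_evs = [G.nodes[v]["ev"] for v in clique]
    e0 = cl_evs[0]
    chrom = chrom or e0.chrom

    if _is_sr(e0):
        return IndelCall(
            kind=e0.kind,
            chrom=chrom,
            bp_left=e0.bp_left,
            bp_right=e0.bp_right,
            ins_seq=e0.ins_seq if e0.kind == "INS" else None,
            n_sr=len(evs),
            n_pe=0,
            size_min=e0.size,
            size_max=e0.size,
            evidence=evs,
        )

    L = max(e.inner_left for e in cl_evs)
    R = min(e.inner_right for e in cl_evs)
    smin = max(e.size_min for e in cl_evs)
    smax = min(e.size_max for e in cl_evs)
    if smax < smin:  # defensive: pairwise consistency does not imply joint
        smax = smin
    if e0.kind == "DEL":
        smax = min(smax, max(smin, R - L))
        lo_l, hi_l = L, max(L, R - smin)
        lo_r, hi_r = L + smin, max(L + smin, R)
        s_star = (smin + smax) // 2
        bp_left = (lo_l + hi_l) // 2
        bp_right = bp_left + s_star
        if bp_right > hi_r:
            shift = bp_right - hi_r
            bp_left = max(lo_l, bp_left - shift)
            bp_right = bp_left + s_star
        return IndelCall(
            kind="DEL",
            chrom=chrom,
            bp_left=bp_left,
            bp_right=bp_right,
            ci_left=(lo_l - bp_left, hi_l - bp_left),
            ci_right=(lo_r - bp_right, hi_r - bp_right),
            n_sr=0,
            n_pe=len(evs),
            size_min=smin,
            size_max=smax,
            evidence=evs,
        )
    p = (L + R) // 2
    return IndelCall(
        kind="INS",
        chrom=chrom,
        bp_left=p,
        bp_right=p,
        ci_left=(L - p, R - p),
        ci_right=(L - p, R - p),
        n_sr=0,
        n_pe=len(evs),
        size_min=smin,
        size_max=smax,
        evidence=evs,
    )


def calls_from_evidence(evidences: Sequence[Evidence], chrom: str = "") -> List[IndelCall]:
    """Convenience: graph -> components -> calls, sorted by breakpoint."""
    G = build_graph(evidences)
    calls = [clique_breakpoints(c, G, chrom) for c in connected_components(G)]
    calls.sort(key=lambda c: (c.chrom, c.bp_left, c.bp_right))
    return calls


def _merge_ok(sr: IndelCall, pe: IndelCall) -> bool:
    if sr.chrom != pe.chrom or sr.kind != pe.kind:
        return False
    if not (sr.n_sr >= 1 and sr.n_pe == 0 and pe.n_pe >= 1 and pe.n_sr == 0):
        return False
    size = sr.size
    assert size is not None
    lo_l = pe.bp_left + pe.ci_left[0]
    hi_l = pe.bp_left + pe.ci_left[1]
    lo_r = pe.bp_right + pe.ci_right[0]
    hi_r = pe.bp_right + pe.ci_right[1]
    if not (lo_l <= sr.bp_left <= hi_l and lo_r <= sr.bp_right <= hi_r):
        return False
    # the exact event must satisfy every supporting pair's own constraint
    for e in pe.evidence:
        if not (e.size_min <= size <= e.size_max):
            return False
        if sr.kind == "DEL" and not (e.inner_left <= sr.bp_left and sr.bp_right <= e.inner_right):
            return False
        if sr.kind == "INS" and not (e.inner_left <= sr.bp_left <= e.inner_right):
            return False
    return True


def merge_sr_pe(calls_sorted: List[IndelCall]) -> List[IndelCall]:
    """Single left-to-right pass merging adjacent split-read-only and
    paired-end-only calls for the same event.  The merged call keeps the
    exact split-read breakpoints and pools support; idempotent."""
    out: List[IndelCall] = []
    i = 0
    n = len(calls_sorted)
    while i < n:
        cur = calls_sorted[i]
        if i + 1 < n:
            nxt = calls_sorted[i + 1]
            pair = None
            if _merge_ok(cur, nxt):
                pair = (cur, nxt)
            elif _merge_ok(nxt, cur):
                pair = (nxt, cur)
            if pair is not None:
                sr, pe = pair
                merged = IndelCall(
                    kind=sr.kind,
                    chrom=sr.chrom,
                    bp_left=sr.bp_left,
                    bp_right=sr.bp_right,
                    ins_seq=sr.ins_seq,
                    n_sr=sr.n_sr,
                    n_pe=pe.n_pe,
                    size_min=sr.size,
                    size_max=sr.size,
                    evidence=list(sr.evidence) + list(pe.evidence),
                )
                out.append(merged)
                i += 2
                continue
        out.append(cur)
        i += 1
    return out
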