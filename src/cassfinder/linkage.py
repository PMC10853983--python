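"""35S-5S rDNA arrangement classification from low-coverage reads.

Builds a k-mer overlap graph from the reads, compresses it into unitigs,
colors nodes by exact k-mer hits against the rRNA gene references (18S,
5.8S, 26S subunits of the 35S transcript, and the 5S gene), extracts a
neighborhood around the colored nodes, and calls the arrangement:

* L (linked): one connected component carries both a 35S-subunit color and
  the 5S color — the 5S gene sits inside the 35S monomer.
* S (separated): 5S-colored components carry no 35S color and vice versa —
  the two rDNAs live in independent tandem arrays.
* ambiguous: a required color is missing or colors are split across more
  than two components.

A perfect tandem array collapses to a cyclic component whose total unitig
length equals the monomer length (up to k-1).  Circularity is reported but
not required for an L call.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

from cassfinder.seqtypes import SequenceRecord

_35S_COLORS = frozenset({"18S", "5.8S", "26S"})
_5S_COLOR = "5S"


@dataclass
class Unitig:
    uid: int
    seq: str  # spelled sequence, length = #kmers + k - 1
    n_kmers: int
    mean_coverage: float
    colors: set = field(default_factory=set)


@dataclass
class KmerGraph:
    k: int
    unitigs: dict[int, Unitig]
    links: dict[int, set]  # undirected unitig adjacency

    def n_nodes(self) -> int:
        return len(self.unitigs)


@dataclass
class ArrangementCall:
    label: str  # L / S / ambiguous
    components: int  # connected components containing colored nodes
    colors_per_component: list
    cyclic: list  # cyclic flag per colored component
    reason: str = ""


def build_kmer_graph(reads: list[SequenceRecord], k: int = 31, min_count: int = 2) -> KmerGraph:
    """K-mer graph of the read set: nodes are k-mers occurring >= min_count,
    edges are (k-1)-overlaps, compressed into maximal non-branching unitigs."""
    if reads and any(len(r.residues) < k for r in reads):
        raise ValueError("k larger than the shortest read")
    counts: Counter = Counter()
    for read in reads:
        s = read.residues
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    kmers = {km: c for km, c in counts.items() if c >= min_count}

    def successors(km: str) -> list[str]:
        suffix = km[1:]
        return [suffix + b for b in "ACGT" if suffix + b in kmers]

    def predecessors(km: str) -> list[str]:
        prefix = km[:-1]
        return [b + prefix for b in "ACGT" if b + prefix in kmers]

    # unitigs: maximal paths through nodes with in/out degree 1
    visited: set[str] = set()
    unitigs: dict[int, Unitig] = {}
    kmer_unitig: dict[str, int] = {}
    uid = 0
    for start in kmers:
        if start in visited:
            continue
        preds = predecessors(start)
        # begin only at path starts (branch points or sources), handle cycles later
        if len(preds) == 1 and len(successors(preds[0])) == 1:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if nxt in visited or len(predecessors(nxt)) != 1:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(kmers[p] for p in path) / len(path)
        unitigs[uid] = Unitig(uid=uid, seq=seq, n_kmers=len(path), mean_coverage=cov)
        for p in path:
            kmer_unitig[p] = uid
        uid += 1
    # pure cycles: every node has in/out degree 1
    for start in kmers:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            succ = successors(cur)
            nxt = succ[0] if succ else None
            if nxt is None or nxt == start or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(kmers[p] for p in path) / len(path)
        unitigs[uid] = Unitig(uid=uid, seq=seq, n_kmers=len(path), mean_coverage=cov)
        for p in path:
            kmer_unitig[p] = uid
        uid += 1

    links: dict[int, set] = {u: set() for u in unitigs}
    for km, u in kmer_unitig.items():
        for nxt in successors(km):
            v = kmer_unitig[nxt]
            if v != u:
                links[u].add(v)
                links[v].add(u)
    # self-adjacency of a circular unitig
    for u, unit in unitigs.items():
        first, last = unit.seq[:k], unit.seq[-k:]
        if unit.n_kmers > 1 and last[1:] + first[-1] == first:
            links[u].add(u)
    return KmerGraph(k=k, unitigs=unitigs, links=links)


def color_nodes(graph: KmerGraph, references: list[SequenceRecord]) -> KmerGraph:
    """Color a unitig with reference name r if any of its k-mers occurs
    exactly in reference r."""
    k = graph.k
    ref_kmers: dict[str, set] = {}
    for ref in references:
        s = ref.residues
        ref_kmers[ref.id] = {s[i : i + k] for i in range(len(s) - k + 1)}
    for unit in graph.unitigs.values():
        unit.colors = set()
        s = unit.seq
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            for name, pool in ref_kmers.items():
                if km in pool:
                    unit.colors.add(name)
    return graph


def extract_neighborhood(graph: KmerGraph, distance: int = 25) -> KmerGraph:
    """Subgraph of unitigs within ``distance`` hops of any colored unitig."""
    colored = [u for u, unit in graph.unitigs.items() if unit.colors]
    keep: set[int] = set(colored)
    frontier = deque((u, 0) for u in colored)
    dist = {u: 0 for u in colored}
    while frontier:
        u, d = frontier.popleft()
        if d >= distance:
            continue
        for v in graph.links.get(u, ()):
            if v not in dist or dist[v] > d + 1:
                dist[v] = d + 1
                keep.add(v)
                frontier.append((v, d + 1))
    unitigs = {u: graph.unitigs[u] for u in keep}
    links = {u: {v for v in graph.links[u] if v in keep} for u in keep}
    return KmerGraph(k=graph.k, unitigs=unitigs, links=links)


def _components(graph: KmerGraph) -> list[set]:
    seen: set[int] = set()
    comps = []
    for u in graph.unitigs:
        if u in seen:
            continue
        comp = {u}
        stack = [u]
        seen.add(u)
        while stack:
            x = stack.pop()
            for v in graph.links.get(x, ()):
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def _is_cyclic(graph: KmerGraph, comp: set) -> bool:
    """A component is a simple cycle: one self-linked unitig, or every unitig
    with exactly two distinct neighbors."""
    if len(comp) == 1:
        u = next(iter(comp))
        return u in graph.links.get(u, set())
    return all(len(graph.links[u] - {u}) == 2 for u in comp)


def component_length(graph: KmerGraph, comp: set) -> int:
    """Total unitig k-mer count (cycle length in bases for a cyclic component)."""
    return sum(graph.unitigs[u].n_kmers for u in comp)


def classify_arrangement(graph: KmerGraph) -> ArrangementCall:
    """Call linked (L) vs separated (S) from a colored (sub)graph."""
    comps = _components(graph)
    colored_comps = []
    for comp in comps:
        colors = set()
        for u in comp:
            colors |= graph.unitigs[u].colors
        if colors:
            colored_comps.append((comp, colors))
    if not colored_comps:
        return ArrangementCall("ambiguous", 0, [], [], reason="no rDNA signal")

    colors_per = [sorted(colors) for _, colors in colored_comps]
    cyclic = [_is_cyclic(graph, comp) for comp, _ in colored_comps]
    all_colors = set().union(*(colors for _, colors in colored_comps))
    call = ArrangementCall("ambiguous", len(colored_comps), colors_per, cyclic)

    if _5S_COLOR not in all_colors:
        call.reason = "missing 5S color"
        return call
    if not (all_colors & _35S_COLORS):
        call.reason = "missing 35S colors"
        return call
    if len(colored_comps) > 2:
        call.reason = "colors split across more than two components"
        return call

    mixed = any(_5S_COLOR in c and (set(c) & _35S_COLORS) for c in colors_per)
    pure = all(
        (_5S_COLOR in c) != bool(set(c) & _35S_COLORS) for c in colors_per
    )
    if mixed and len(colored_comps) == 1:
        call.label = "L"
    elif mixed:
        call.reason = "colors co-occur but are split across components"
    elif pure:
        call.label = "S"
    else:
        call.reason = "inconsistent coloring"
    return call


def call_rows(call: ArrangementCall) -> list[dict]:
    return [
        {
            "label": call.label,
            "colored_components": call.components,
            "colors": ";".join(",".join(c) for c in call.colors_per_component),
            "cyclic": ";".join(str(int(c)) for c in call.cyclic),
            "reason": call.reason,
        }
    ]


def graph_rows(graph: KmerGraph) -> list[dict]:
    """GFA-like tabular dump: unitig id, length, coverage, links, colors."""
    rows = []
    for u in sorted(graph.unitigs):
        unit = graph.unitigs[u]
        rows.append(
            {
                "unitig": u,
                "length": len(unit.seq),
                "n_kmers": unit.n_kmers,
                "mean_coverage": f"{unit.mean_coverage:.1f}",
                "links": ",".join(str(v) for v in sorted(graph.links.get(u, ()))),
                "colors": ",".join(sorted(unit.colors)),
            }
        )
    return rows
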