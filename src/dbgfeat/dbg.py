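"""De Bruijn graphs over canonical k-mers and feature-component extraction.

Nodes are canonical k-mers; two nodes are adjacent iff some strand
orientation of one has a (k-1)-suffix equal to a (k-1)-prefix of some
orientation of the other, so every node has at most 8 neighbour
candidates (4 one-base extensions per orientation).  Adjacency is implicit
— neighbour queries generate the candidates and filter by membership — so
the graph is just a node set with abundances.

Components (connected k-mer sets) are the unit of "feature".  Three ways
to carve them out of the graph:

* ``local_search`` — pivot-seeded breadth-first expansion with
  early-stopping (radius, per-direction branch budget, size cap) and
  pruning of pivot-free side branches; the supervised path.
* ``extract_colored_components`` — color every k-mer by the fraction of
  containing samples that belong to each group, then take components of
  the strongly-colored subgraph; limited to 2–3 groups.
* ``condensed_components`` — abundance-threshold splitting with a
  doubling schedule; the unsupervised path.

``component_contigs`` decomposes a component into maximal non-branching
paths (unitigs), each saved as one contig.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._encoding import canonical_code, decode_kmer, rc_code, revcomp
from .kmer_core import KmerCountTable
from .selection import GroupLabels, SelectedKmers, build_presence_matrix, sample_codes

__all__ = [
    "DeBruijnGraph",
    "Component",
    "Contig",
    "ColorVectors",
    "build_graph",
    "local_search",
    "color_vectors",
    "extract_colored_components",
    "condensed_components",
    "component_contigs",
    "components_to_fasta",
    "read_components_fasta",
    "write_gfa",
]

DEFAULT_MAX_RADIUS = 100
DEFAULT_BRANCH_LIMIT = 1
DEFAULT_MAX_COMPONENT_SIZE = 10_000


@dataclass
class Component:
    """A connected set of k-mers carrying its seeding pivots and category."""

    id: str
    category: str
    k: int
    codes: np.ndarray = field(repr=False)  # sorted uint64
    pivot_codes: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.unique(np.asarray(self.codes, dtype=np.uint64))
        if self.pivot_codes is None:
            self.pivot_codes = np.empty(0, dtype=np.uint64)
        self.pivot_codes = np.unique(np.asarray(self.pivot_codes, dtype=np.uint64))
        if not np.isin(self.pivot_codes, self.codes).all():
            raise ValueError("pivots must be a subset of the component's k-mers")

    @property
    def size(self) -> int:
        return int(self.codes.size)

    @property
    def kmers(self) -> set[str]:
        return {decode_kmer(int(c), self.k) for c in self.codes}

    @property
    def pivots(self) -> set[str]:
        return {decode_kmer(int(c), self.k) for c in self.pivot_codes}


@dataclass(frozen=True)
class Contig:
    sequence: str
    component_id: str


class DeBruijnGraph:
    """Implicit-adjacency de Bruijn graph over canonical k-mer codes."""

    def __init__(self, k: int, codes: np.ndarray, abundance: np.ndarray):
        self.k = k
        self.codes = np.asarray(codes, dtype=np.uint64)
        self.abundances = np.asarray(abundance, dtype=np.float64)
        if self.codes.shape != self.abundances.shape:
            raise ValueError("codes and abundances must be parallel")
        self._members: set[int] = set(int(c) for c in self.codes)
        self._abund: dict[int, float] = {
            int(c): float(a) for c, a in zip(self.codes, self.abundances)
        }
        self._mask = (1 << (2 * k)) - 1

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, code: int) -> bool:
        return int(code) in self._members

    def has_kmer(self, kmer: str) -> bool:
        from ._encoding import encode_kmer

        return canonical_code(encode_kmer(kmer), self.k) in self._members

    def kmer_nodes(self) -> set[str]:
        return {decode_kmer(c, self.k) for c in self._members}

    def abundance_of(self, code: int) -> float:
        return self._abund.get(int(code), 0.0)

    def neighbor_directions(
        self, code: int, members: set[int] | None = None
    ) -> tuple[list[int], list[int]]:
        """Neighbour codes grouped by direction (forward / reverse strand)."""
        mem = self._members if members is None else members
        k = self.k
        out: tuple[list[int], list[int]] = ([], [])
        for di, v in enumerate((code, rc_code(code, k))):
            suf = (v << 2) & self._mask
            for b in range(4):
                w = suf | b
                c = min(w, rc_code(w, k))
                if c != code and c in mem:
                    out[di].append(c)
        return out

    def neighbors(self, code: int, members: set[int] | None = None) -> list[int]:
        f, r = self.neighbor_directions(code, members)
        seen = []
        for c in f + r:
            if c not in seen:
                seen.append(c)
        return seen


def build_graph(tables: Sequence[KmerCountTable]) -> DeBruijnGraph:
    """Union graph of sample k-mer sets with summed abundances."""
    if not tables:
        raise ValueError("no samples")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"mixed k across samples: {sorted(ks)}")
    k = ks.pop()
    union = np.unique(np.concatenate([t.codes for t in tables]))
    abund = np.zeros(union.size, dtype=np.float64)
    for t in tables:
        idx = np.searchsorted(union, t.codes)
        abund[idx] += t.counts
    return DeBruijnGraph(k, union, abund)


def connected_components(
    graph: DeBruijnGraph, members: set[int] | None = None
) -> list[np.ndarray]:
    """Plain connected components (sorted code arrays, deterministic order)."""
    mem = graph._members if members is None else members
    seen: set[int] = set()
    comps: list[np.ndarray] = []
    for start in sorted(mem):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        q = deque([start])
        while q:
            u = q.popleft()
            for v in graph.neighbors(u, mem):
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    q.append(v)
        comps.append(np.array(sorted(comp), dtype=np.uint64))
    return comps


# ---------------------------------------------------------------------------
# supervised: pivot-seeded local search


def _prune_pivot_free_branches(
    nodes: set[int],
    parent: dict[int, int | None],
    children: dict[int, list[int]],
    pivot_set: set[int],
    graph: DeBruijnGraph,
    seed: int,
) -> set[int]:
    """Drop BFS-subtrees without pivots that hang off junction nodes.

    A junction is a node of induced degree >= 3 within the explored set;
    plain chain continuations survive, so a pivot in the middle of a path
    keeps its whole explored neighbourhood.
    """
    # does the BFS subtree rooted at v contain a pivot?
    has_pivot = {v: (v in pivot_set) for v in nodes}
    by_depth: dict[int, int] = {seed: 0}
    order = [seed]
    for v in order:
        for c in children.get(v, ()):
            by_depth[c] = by_depth[v] + 1
            order.append(c)
    for v in reversed(order):
        p = parent[v]
        if p is not None and has_pivot[v]:
            has_pivot[p] = True
    degree = {v: len(graph.neighbors(v, nodes)) for v in nodes}
    keep: set[int] = set()
    stack = [seed]
    while stack:
        v = stack.pop()
        keep.add(v)
        junction = degree[v] >= 3
        for c in children.get(v, ()):
            if junction and not has_pivot[c]:
                continue  # prune whole subtree
            stack.append(c)
    return keep


def local_search(
    graph: DeBruijnGraph,
    pivots: SelectedKmers | Iterable[str],
    max_radius: int = DEFAULT_MAX_RADIUS,
    branch_limit: int | float = DEFAULT_BRANCH_LIMIT,
    max_component_size: int = DEFAULT_MAX_COMPONENT_SIZE,
) -> list[Component]:
    """Expand pivot k-mers into graph components with early stopping.

    Breadth-first from each unassigned pivot: pivot-bearing neighbours are
    always taken; at most *branch_limit* non-pivot continuations are taken
    per direction per node; expansion stops at *max_radius* from the seed
    or when the component reaches *max_component_size*.  Pivot-free side
    branches at junctions are pruned at finalisation, and components
    sharing any k-mer are merged, so every pivot lands in exactly one
    component.
    """
    if isinstance(pivots, SelectedKmers):
        category = pivots.category
        pivot_codes = [int(c) for c in pivots.codes]
    else:
        category = "unsupervised"
        from ._encoding import encode_kmer

        pivot_codes = [canonical_code(encode_kmer(s), graph.k) for s in pivots]
    if not pivot_codes:
        raise ValueError("empty pivot set")
    present = sorted(c for c in set(pivot_codes) if c in graph)
    n_absent = len(set(pivot_codes)) - len(present)
    if n_absent:
        warnings.warn(f"{n_absent} pivot k-mers absent from the graph; skipped", stacklevel=2)
    if not present:
        raise ValueError("no pivot k-mer is present in the graph")
    pivot_set = set(present)
    blimit = float(branch_limit)

    comps: list[dict] = []  # {"nodes": set, "pivots": set}
    owner: dict[int, int] = {}

    for seed in present:
        if seed in owner:
            continue
        nodes = {seed}
        parent: dict[int, int | None] = {seed: None}
        children: dict[int, list[int]] = {}
        depth = {seed: 0}
        q = deque([seed])
        while q and len(nodes) < max_component_size:
            u = q.popleft()
            if depth[u] >= max_radius:
                continue
            for dir_nbrs in graph.neighbor_directions(u):
                new = [v for v in dir_nbrs if v not in nodes]
                piv = [v for v in new if v in pivot_set]
                non = sorted(v for v in new if v not in pivot_set)
                take = piv + non[: int(blimit) if blimit != float("inf") else len(non)]
                for v in take:
                    if len(nodes) >= max_component_size:
                        break
                    nodes.add(v)
                    parent[v] = u
                    children.setdefault(u, []).append(v)
                    depth[v] = depth[u] + 1
                    q.append(v)
        kept = _prune_pivot_free_branches(nodes, parent, children, pivot_set, graph, seed)
        overlapping = sorted({owner[v] for v in kept if v in owner})
        if overlapping:
            target = overlapping[0]
            merged_nodes = comps[target]["nodes"]
            merged_piv = comps[target]["pivots"]
            for ci in overlapping[1:]:
                merged_nodes |= comps[ci]["nodes"]
                merged_piv |= comps[ci]["pivots"]
                comps[ci] = None  # type: ignore[call-overload]
            merged_nodes |= kept
            merged_piv |= kept & pivot_set
            for v in merged_nodes:
                owner[v] = target
        else:
            comps.append({"nodes": kept, "pivots": kept & pivot_set})
            target = len(comps) - 1
            for v in kept:
                owner[v] = target
    alive = [c for c in comps if c is not None]
    alive.sort(key=lambda c: min(c["nodes"]))
    return [
        Component(
            id=f"{category}_{i}",
            category=category,
            k=graph.k,
            codes=np.array(sorted(c["nodes"]), dtype=np.uint64),
            pivot_codes=np.array(sorted(c["pivots"]), dtype=np.uint64),
        )
        for i, c in enumerate(alive)
    ]


# ---------------------------------------------------------------------------
# colored mode


class ColorVectors:
    """Per-k-mer group-occurrence probabilities.

    For a k-mer present in s_G samples of group G and s total samples,
    V_G = s_G / s; the vector over groups sums to 1.  Mapping-style access
    by k-mer string returns a plain dict for convenience.
    """

    def __init__(self, k: int, categories: list[str], codes: np.ndarray, values: np.ndarray):
        self.k = k
        self.categories = categories
        self.codes = np.asarray(codes, dtype=np.uint64)
        self.values = np.asarray(values, dtype=np.float64)  # (n, n_groups)

    def __len__(self) -> int:
        return int(self.codes.size)

    def value_of(self, code: int, category: str) -> float:
        j = self.categories.index(category)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and int(self.codes[i]) == int(code):
            return float(self.values[i, j])
        return 0.0

    def __getitem__(self, kmer: str) -> dict[str, float]:
        from ._encoding import encode_kmer

        code = canonical_code(encode_kmer(kmer), self.k)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i >= self.codes.size or int(self.codes[i]) != code:
            raise KeyError(kmer)
        return {c: float(v) for c, v in zip(self.categories, self.values[i])}

    def items(self):
        for i, c in enumerate(self.codes):
            yield decode_kmer(int(c), self.k), {
                cat: float(v) for cat, v in zip(self.categories, self.values[i])
            }


def color_vectors(
    sample_sets: Mapping[str, object],
    labels: GroupLabels,
    k: int | None = None,
    allow_many_groups: bool = False,
) -> ColorVectors:
    """Group-occurrence probability vector for every supported k-mer.

    V_G(km) = (#samples of G containing km) / (#samples containing km).
    Limited to 2 or 3 groups unless *allow_many_groups* overrides.
    """
    if len(labels.categories) > 3 and not allow_many_groups:
        raise ValueError(
            "colored mode supports only two or three groups of samples "
            f"(got {len(labels.categories)}); pass allow_many_groups=True to override"
        )
    pm = build_presence_matrix(sample_sets, labels, k=k)
    totals = pm.presence.sum(axis=1, keepdims=True).astype(np.float64)
    values = pm.presence / totals
    return ColorVectors(pm.k, list(labels.categories), pm.codes, values)


def extract_colored_components(
    graph: DeBruijnGraph,
    colors: ColorVectors,
    mode: str = "threshold",
    n_per_group: int = 100,
    threshold: float = 0.9,
) -> list[Component]:
    """Components of the group-colored subgraph.

    threshold mode: for each group, the subgraph of nodes with V_G >=
    *threshold* (threshold must be in (0.5, 1]); every component returned.
    top_n mode: subgraph of majority-colored nodes (V_G > 0.5); components
    ranked by their best seed (descending V_G, ties by abundance then
    k-mer) and truncated to *n_per_group* per group.
    """
    if mode not in ("threshold", "top_n"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "threshold" and not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    # restrict colors to graph nodes
    in_graph = np.fromiter(
        (int(c) in graph._members for c in colors.codes), dtype=bool, count=len(colors)
    )
    out: list[Component] = []
    for j, group in enumerate(colors.categories):
        v = colors.values[:, j]
        cutoff = threshold if mode == "threshold" else 0.5
        strict = mode == "top_n"
        mask = in_graph & ((v > cutoff) if strict else (v >= cutoff))
        members = set(int(c) for c in colors.codes[mask])
        if not members:
            if mode == "threshold":
                warnings.warn(f"no k-mer passes threshold {threshold} for group {group!r}", stacklevel=2)
            continue
        comps = connected_components(graph, members)
        if mode == "top_n":
            def best_seed_key(codes: np.ndarray):
                vv = colors.values[np.searchsorted(colors.codes, codes), j]
                ab = np.array([graph.abundance_of(int(c)) for c in codes])
                order = np.lexsort((codes, -ab, -vv))
                i = order[0]
                return (-float(vv[i]), -float(ab[i]), int(codes[i]))

            comps.sort(key=best_seed_key)
            comps = comps[:n_per_group]
            comps.sort(key=lambda c: int(c[0]))
        for i, codes in enumerate(comps):
            out.append(
                Component(id=f"{group}_{i}", category=group, k=graph.k, codes=codes)
            )
    return out


# ---------------------------------------------------------------------------
# unsupervised: coverage-threshold condensation


def condensed_components(
    graph: DeBruijnGraph,
    initial_threshold: float = 1.0,
    size_bounds: tuple[int, int] = (5, 10_000),
    max_iterations: int = 10,
) -> list[Component]:
    """Iteratively split the graph into components by abundance thresholds.

    Nodes below the threshold are removed and connected components taken;
    components inside *size_bounds* are accepted as features, oversized
    ones are re-split with a doubled threshold (up to *max_iterations*,
    then accepted as-is), undersized ones are discarded.
    """
    min_size, max_size = size_bounds
    if not min_size < max_size:
        raise ValueError("size_bounds must satisfy min_size < max_size")
    survivors = {
        int(c) for c, a in zip(graph.codes, graph.abundances) if a >= initial_threshold
    }
    if not survivors:
        raise ValueError(
            f"every node falls below the initial abundance threshold {initial_threshold}"
        )
    accepted: list[np.ndarray] = []
    stack: list[tuple[set[int], float, int]] = [(survivors, initial_threshold, 0)]
    while stack:
        members, thr, it = stack.pop()
        for codes in connected_components(graph, members):
            n = codes.size
            if n < min_size:
                continue
            if n <= max_size or it >= max_iterations:
                accepted.append(codes)
                continue
            new_thr = thr * 2.0
            sub = {int(c) for c in codes if graph.abundance_of(int(c)) >= new_thr}
            if not sub:
                accepted.append(codes)  # nothing survives a harder cut; keep as-is
                continue
            stack.append((sub, new_thr, it + 1))
    accepted.sort(key=lambda c: int(c[0]))
    return [
        Component(id=f"unsupervised_{i}", category="unsupervised", k=graph.k, codes=codes)
        for i, codes in enumerate(accepted)
    ]


# ---------------------------------------------------------------------------
# unitig decomposition


def _oriented_succ(code: int, strand: int, k: int, members: set[int], mask: int):
    v = code if strand == 0 else rc_code(code, k)
    out = []
    for b in range(4):
        w = ((v << 2) & mask) | b
        wr = rc_code(w, k)
        c = w if w <= wr else wr
        if c != code and c in members:
            out.append((c, 0 if c == w else 1))
    return out


def component_contigs(component: Component, k: int | None = None) -> list[Contig]:
    """Decompose a component into unitigs (maximal non-branching paths).

    Every k-mer is assigned to exactly one contig; a path of m k-mers
    yields a contig of length k + m - 1.  Self-overlap edges (a k-mer
    adjacent to itself) are ignored for branching decisions.
    """
    k = component.k if k is None else k
    members = set(int(c) for c in component.codes)
    if not members:
        raise ValueError("empty component")
    mask = (1 << (2 * k)) - 1

    def succ(c: int, s: int):
        return _oriented_succ(c, s, k, members, mask)

    def outdeg(c: int, s: int) -> int:
        return len(succ(c, s))

    def indeg(c: int, s: int) -> int:
        return outdeg(c, 1 - s)

    def is_start(c: int, s: int) -> bool:
        if indeg(c, s) != 1:
            return True
        (q, sq) = succ(c, 1 - s)[0]
        return outdeg(q, 1 - sq) != 1

    visited: set[int] = set()
    contigs: list[Contig] = []

    def oriented_seq(c: int, s: int) -> str:
        sq = decode_kmer(c, k)
        return sq if s == 0 else revcomp(sq)

    def walk(c: int, s: int) -> None:
        seq = [oriented_seq(c, s)]
        visited.add(c)
        while True:
            outs = succ(c, s)
            if len(outs) != 1:
                break
            nc, ns = outs[0]
            if nc in visited or indeg(nc, ns) != 1:
                break
            seq.append(oriented_seq(nc, ns)[-1])
            visited.add(nc)
            c, s = nc, ns
        contigs.append(Contig(sequence="".join(seq), component_id=component.id))

    for code in sorted(members):
        if code in visited:
            continue
        for s in (0, 1):
            if is_start(code, s):
                walk(code, s)
                break
    # remaining nodes sit on pure cycles
    for code in sorted(members):
        if code not in visited:
            walk(code, 0)
    return contigs


# ---------------------------------------------------------------------------
# serialization


def components_to_fasta(components: Sequence[Component], path: str | Path) -> None:
    """Write all components as non-overlapping contigs in FASTA."""
    from .io import wrap_fasta

    with open(path, "w", encoding="utf-8") as fh:
        for comp in components:
            for j, contig in enumerate(component_contigs(comp)):
                fh.write(
                    f">component_{comp.id}_contig_{j} "
                    f"category={comp.category} size={comp.size}\n"
                )
                fh.write(wrap_fasta(contig.sequence) + "\n")


def read_components_fasta(path: str | Path, k: int) -> list[Component]:
    """Reconstruct components by re-k-merizing their contigs."""
    import re

    from Bio import SeqIO

    from ._encoding import encode_canonical_windows
    from .io import open_text

    header_re = re.compile(r"^component_(?P<id>.+)_contig_(?P<j>\d+)$")
    chunks: dict[str, list[np.ndarray]] = {}
    cats: dict[str, str] = {}
    bad: list[str] = []
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            m = header_re.match(rec.id)
            if not m:
                bad.append(rec.id)
                continue
            cid = m.group("id")
            cat = "unsupervised"
            for tok in rec.description.split()[1:]:
                if tok.startswith("category="):
                    cat = tok.split("=", 1)[1]
            cats[cid] = cat
            chunks.setdefault(cid, []).append(
                encode_canonical_windows(str(rec.seq).upper(), k)
            )
    if bad:
        raise ValueError(f"malformed component FASTA headers: {', '.join(bad)}")
    if not chunks:
        raise ValueError(f"no components found in {path}")
    comps = []
    for cid in chunks:
        codes = np.unique(np.concatenate(chunks[cid]))
        comps.append(Component(id=cid, category=cats[cid], k=k, codes=codes))
    comps.sort(key=lambda c: c.id)
    return comps


def write_gfa(components: Sequence[Component], path: str | Path) -> None:
    """Minimal GFA1 export of component subgraphs (segments = unitigs)."""
    k = components[0].k if components else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("H\tVN:Z:1.0\n")
        seg_id = 0
        for comp in components:
            segs = []
            for contig in component_contigs(comp):
                seg_id += 1
                name = f"{comp.id}.{seg_id}"
                fh.write(f"S\t{name}\t{contig.sequence}\n")
                segs.append((name, contig.sequence))
            # link segments overlapping by k-1 on any orientation pair
            for i, (na, sa) in enumerate(segs):
                for nb, sb in segs[i:]:
                    for oa, ra in (("+", sa), ("-", revcomp(sa))):
                        for ob, rb in (("+", sb), ("-", revcomp(sb))):
                            if na == nb and oa == "-":
                                continue
                            if ra[-(k - 1):] == rb[: k - 1]:
                                fh.write(f"L\t{na}\t{oa}\t{nb}\t{ob}\t{k-1}M\n")
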