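"""Haplotype network construction and haplogroup labelling.

Aligned mtDNA control-region sequences are collapsed to distinct
haplotypes, connected by a median-joining network (relaxed minimum
spanning network plus inferred median vectors that shorten the network),
post-processed to mask hypermutable columns, and used to assign query
sequences a haplogroup label for pseudo-locus encoding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .io_formats import UNKNOWN_HAPLOGROUP

__all__ = [
    "HaplotypeAlignment",
    "HaplotypeNode",
    "HaplotypeNetwork",
    "read_fasta_alignment",
    "collapse_haplotypes",
    "build_mj_network",
    "network_cost",
    "mask_hypermutable_sites",
    "assign_haplogroup",
    "hamming",
    "write_edge_list",
    "write_dot",
]

logger = logging.getLogger(__name__)

_MISSING_CHARS = frozenset("-N")
_VALID_CHARS = frozenset("ACGT-N")


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Equal-length sequences over {A,C,G,T,-,N} plus a column usage mask."""

    sequences: dict[str, str]
    site_mask: np.ndarray  # bool per column, True = used

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        mask = np.asarray(self.site_mask, dtype=bool)
        if mask.shape != (length,):
            raise ValueError("site_mask length does not match alignment length")
        object.__setattr__(self, "site_mask", mask)
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise ValueError(f"sequence {sid!r} contains invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def masked(self, seq: str) -> str:
        """The unmasked-column substring used for distances."""
        return "".join(c for c, keep in zip(seq.upper(), self.site_mask) if keep)


def read_fasta_alignment(source: str | Path | IO[str]) -> HaplotypeAlignment:
    """Load an aligned FASTA; all columns initially unmasked."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError("no sequences in FASTA input")
    seqs = {r.id: str(r.seq).upper() for r in records}
    length = len(next(iter(seqs.values())))
    return HaplotypeAlignment(sequences=seqs, site_mask=np.ones(length, dtype=bool))


def hamming(a: str, b: str) -> int:
    """Mutational steps between two equal-length strings.

    Columns where either character is a gap or N are skipped: alignments
    of control regions commonly carry indels that are not counted as
    substitutions.
    """
    if len(a) != len(b):
        raise ValueError("sequence length mismatch")
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in _MISSING_CHARS and y not in _MISSING_CHARS
    )


@dataclass(frozen=True)
class HaplotypeNode:
    sequence: str  # unmasked-column string
    members: tuple[str, ...]  # sample ids; empty for inferred medians
    is_median: bool = False

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[HaplotypeNode, ...]
    edges: tuple[tuple[int, int, int], ...]  # (node index, node index, weight)
    epsilon: int = 0

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


def collapse_haplotypes(aln: HaplotypeAlignment) -> list[HaplotypeNode]:
    """Group sequences identical over unmasked columns into nodes."""
    if not aln.site_mask.any():
        raise ValueError("all alignment columns are masked out")
    groups: dict[str, list[str]] = {}
    for sid, seq in aln.sequences.items():
        groups.setdefault(aln.masked(seq), []).append(sid)
    return [
        HaplotypeNode(sequence=key, members=tuple(ids))
        for key, ids in sorted(groups.items())
    ]


def _distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(seqs[i], seqs[j])
    return d


def _mst_edges(d: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Kruskal MST edge list and total length (deterministic tie order)."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = sorted(
        ((int(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
    )
    edges = []
    total = 0
    for w, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            total += w
            if len(edges) == n - 1:
                break
    return edges, total


def _minimax_distances(d: np.ndarray) -> np.ndarray:
    """Minimax path distance between all pairs (max edge minimized).

    Computed on an MST, where the minimax distance is the largest edge on
    the unique tree path.
    """
    n = d.shape[0]
    edges, _ = _mst_edges(d)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, j in edges:
        w = int(d[i, j])
        adj[i].append((j, w))
        adj[j].append((i, w))
    m = np.zeros((n, n), dtype=int)
    for src in range(n):
        seen = {src}
        stack = [(src, 0)]
        while stack:
            node, best = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    m[src, nxt] = max(best, w)
                    stack.append((nxt, max(best, w)))
    return m


def _msn_edges(d: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    """Relaxed minimum spanning network at tolerance ``epsilon``.

    An edge joins two haplotypes when its length does not exceed their
    minimax (connection-level) distance plus ``epsilon``; at epsilon 0
    this is the classic minimum spanning network.
    """
    n = d.shape[0]
    if n == 1:
        return []
    m = _minimax_distances(d)
    return [
        (i, j, int(d[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= m[i, j] + epsilon
    ]


def _median_vector(a: str, b: str, c: str) -> str:
    """Position-wise majority of three sequences (ties keep the first)."""
    out = []
    for x, y, z in zip(a, b, c):
        votes = [ch for ch in (x, y, z) if ch not in _MISSING_CHARS]
        if not votes:
            out.append(x)
            continue
        best = max(set(votes), key=lambda ch: (votes.count(ch), ch == x, ch))
        out.append(best)
    return "".join(out)


def build_mj_network(
    nodes: Sequence[HaplotypeNode], epsilon: int = 0, max_rounds: int = 100
) -> HaplotypeNetwork:
    """Median-joining network over collapsed haplotype nodes.

    Iterates: build the relaxed minimum spanning network; propose median
    (Steiner) vectors from triplets linked in it; greedily add medians
    that strictly reduce the total spanning length; prune medians whose
    removal costs nothing.  The total cost never increases, so the loop
    terminates.
    """
    if not nodes:
        raise ValueError("no haplotype nodes supplied")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    observed = list(nodes)
    medians: list[str] = []
    known = {n.sequence for n in observed}

    def seqs() -> list[str]:
        return [n.sequence for n in observed] + medians

    for _ in range(max_rounds):
        current = seqs()
        d = _distance_matrix(current)
        _, base_cost = _mst_edges(d)
        msn = _msn_edges(d, epsilon)
        adj: dict[int, set[int]] = {}
        for i, j, _w in msn:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)

        best_gain = 0
        best_median: str | None = None
        seen_cand: set[str] = set()
        for v, nbrs in adj.items():
            for u, w in itertools.combinations(sorted(nbrs), 2):
                cand = _median_vector(current[u], current[v], current[w])
                if cand in known or cand in seen_cand:
                    continue
                seen_cand.add(cand)
                d_ext = _extend_distance_matrix(d, current, cand)
                _, cost = _mst_edges(d_ext)
                gain = base_cost - cost
                if gain > best_gain or (
                    gain == best_gain and gain > 0 and (best_median is None or cand < best_median)
                ):
                    best_gain = gain
                    best_median = cand
        if best_median is None or best_gain <= 0:
            break
        medians.append(best_median)
        known.add(best_median)

    # prune medians whose removal leaves the spanning length unchanged
    changed = True
    while changed and medians:
        changed = False
        d = _distance_matrix(seqs())
        _, full_cost = _mst_edges(d)
        for k in range(len(medians) - 1, -1, -1):
            trial = medians[:k] + medians[k + 1 :]
            cur = [n.sequence for n in observed] + trial
            _, cost = _mst_edges(_distance_matrix(cur))
            if cost <= full_cost:
                del medians[k]
                changed = True
                break

    all_nodes = tuple(observed) + tuple(
        HaplotypeNode(sequence=s, members=(), is_median=True) for s in medians
    )
    d = _distance_matrix([n.sequence for n in all_nodes])
    edges = tuple(_msn_edges(d, epsilon))
    return HaplotypeNetwork(nodes=all_nodes, edges=edges, epsilon=epsilon)


def _extend_distance_matrix(d: np.ndarray, seqs: Sequence[str], cand: str) -> np.ndarray:
    n = d.shape[0]
    out = np.zeros((n + 1, n + 1), dtype=int)
    out[:n, :n] = d
    for i, s in enumerate(seqs):
        out[i, n] = out[n, i] = hamming(s, cand)
    return out


def network_cost(network: HaplotypeNetwork) -> int:
    """Total spanning length of the network's node set."""
    d = _distance_matrix([n.sequence for n in network.nodes])
    _, cost = _mst_edges(d)
    return cost


def mask_hypermutable_sites(
    aln: HaplotypeAlignment,
    network: HaplotypeNetwork,
    threshold: int = 3,
) -> np.ndarray:
    """Mask columns whose implied state changes on the network exceed ``threshold``.

    The change count of a column is the minimum number of state-changing
    network edges needed to keep the node set connected (columns where
    either endpoint is missing imply no change).  Returns the new
    full-length site mask; the caller rebuilds the network once on it.
    """
    used_cols = np.nonzero(aln.site_mask)[0]
    new_mask = aln.site_mask.copy()
    n = len(network.nodes)
    for pos, col in enumerate(used_cols):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        comp = n
        for i, j, _w in network.edges:
            ci = network.nodes[i].sequence[pos]
            cj = network.nodes[j].sequence[pos]
            if ci in _MISSING_CHARS or cj in _MISSING_CHARS or ci == cj:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
                    comp -= 1
        changes = comp - 1
        if changes > threshold:
            new_mask[col] = False
    if not new_mask.any():
        raise ValueError(f"hypermutability threshold {threshold} would mask every column")
    return new_mask


def assign_haplogroup(
    query: str,
    references: Mapping[str, Iterable[str]],
    site_mask: np.ndarray | None = None,
) -> str:
    """Label a query by its nearest reference haplotype.

    ``references`` maps labels to collections of aligned sequences.  Ties
    across different labels yield ``unknown`` with a logged ambiguity.
    """
    if not references:
        raise ValueError("no reference sequences supplied")
    query = query.upper()
    if site_mask is not None:
        mask = np.asarray(site_mask, dtype=bool)
        if mask.shape != (len(query),):
            raise ValueError("site_mask length does not match query length")

        def view(s: str) -> str:
            return "".join(c for c, keep in zip(s, mask) if keep)

    else:

        def view(s: str) -> str:
            return s

    q = view(query)
    best = None
    best_labels: set[str] = set()
    for label in sorted(references):
        for ref in references[label]:
            ref = ref.upper()
            if len(ref) != len(query):
                raise ValueError(f"reference length {len(ref)} != query length {len(query)}")
            dist = hamming(q, view(ref))
            if best is None or dist < best:
                best = dist
                best_labels = {label}
            elif dist == best:
                best_labels.add(label)
    if len(best_labels) > 1:
        logger.warning(
            "ambiguous haplogroup: query equidistant (d=%d) from labels %s",
            best,
            sorted(best_labels),
        )
        return UNKNOWN_HAPLOGROUP
    return best_labels.pop()


def write_edge_list(network: HaplotypeNetwork, dest: str | Path | IO[str]) -> None:
    """Tab-separated edges: node_a, node_b, weight, is_median flags."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_edge_list(network, fh)
        return
    dest.write("node_a\tnode_b\tweight\ta_is_median\tb_is_median\n")
    for i, j, w in network.edges:
        a, b = network.nodes[i], network.nodes[j]
        dest.write(
            f"{_node_name(network, i)}\t{_node_name(network, j)}\t{w}"
            f"\t{int(a.is_median)}\t{int(b.is_median)}\n"
        )


def write_dot(network: HaplotypeNetwork, dest: str | Path | IO[str]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_dot(network, fh)
        return
    dest.write("graph haplotypes {\n")
    for i, node in enumerate(network.nodes):
        shape = "point" if node.is_median else "circle"
        label = _node_name(network, i)
        dest.write(f'  n{i} [label="{label}" shape={shape}];\n')
    for i, j, w in network.edges:
        dest.write(f'  n{i} -- n{j} [label="{w}"];\n')
    dest.write("}\n")


def _node_name(network: HaplotypeNetwork, i: int) -> str:
    node = network.nodes[i]
    if node.is_median:
        return f"median_{i}"
    return node.members[0] if node.members else f"node_{i}"
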