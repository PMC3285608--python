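"""SNP p-distances between samples (plus the reference) and neighbor-joining.

The distance between two taxa is the proportion of eligible SNP loci at
which their alleles differ; a heterozygous call contributes a half mismatch
against a homozygous allele it half-matches.  The reference genome enters
as a taxon carrying the reference allele everywhere.  Trees are built with
the Saitou-Nei neighbor-joining algorithm with a deterministic
taxon-name-order tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import build_loci, eligible_loci
from .core import CoverageMask, ResevarError, VariantRecord

REFERENCE_TAXON = "reference"


def _genotype(locus, sample: str, ref: str) -> tuple[str, str]:
    rec = locus.records.get(sample)
    if rec is None:
        return (ref, ref)
    if rec.zygosity == "het":
        return tuple(sorted((ref, rec.alt)))
    return (rec.alt, rec.alt)


def _mismatch(a: tuple[str, str], b: tuple[str, str]) -> float:
    if a == b:
        return 0.0
    return 0.5 if set(a) & set(b) else 1.0


def snp_distance_matrix(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask] | None = None,
    include_reference: bool = True,
    jukes_cantor: bool = False,
) -> pd.DataFrame:
    """Pairwise p-distance over eligible SNP loci.

    ``d(i, j)`` is the summed allele mismatch divided by the number of
    eligible loci.  With ``jukes_cantor=True`` the p-distance is corrected
    as ``-3/4 * ln(1 - 4p/3)``.
    """
    samples = list(variant_sets)
    loci = [l for l in build_loci(variant_sets) if l.category == "SNP"]
    if masks is not None:
        loci, _ = eligible_loci(loci, masks, samples)
    if not loci:
        raise ResevarError("no eligible SNP loci for distance estimation")
    taxa = samples + [REFERENCE_TAXON] if include_reference else list(samples)
    n = len(taxa)
    total = np.zeros((n, n))
    for loc in loci:
        gts = []
        for t in taxa:
            if t == REFERENCE_TAXON:
                gts.append((loc.ref, loc.ref))
            else:
                gts.append(_genotype(loc, t, loc.ref))
        for i in range(n):
            for j in range(i + 1, n):
                m = _mismatch(gts[i], gts[j])
                total[i, j] += m
                total[j, i] += m
    dist = total / len(loci)
    if jukes_cantor:
        p = np.clip(dist, 0, 0.749999)
        dist = np.where(dist > 0, -0.75 * np.log(1.0 - 4.0 * p / 3.0), 0.0)
    return pd.DataFrame(dist, index=taxa, columns=taxa)


def check_distance_axioms(d: pd.DataFrame, atol: float = 1e-9) -> dict:
    """Report symmetry, zero diagonal, non-negativity and triangle-inequality
    violations (the last are allowed but flagged)."""
    m = d.to_numpy()
    n = len(d)
    triangle = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if m[i, j] > m[i, k] + m[k, j] + atol:
                    triangle.append((d.index[i], d.index[j], d.index[k]))
    return {
        "symmetric": bool(np.allclose(m, m.T, atol=atol)),
        "zero_diagonal": bool(np.allclose(np.diag(m), 0.0, atol=atol)),
        "non_negative": bool((m >= -atol).all()),
        "triangle_violations": triangle,
    }


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map ``node -> {neighbor: length}``.

    Leaves are taxon-name strings; internal nodes are integers.  Negative
    branch lengths produced by neighbor joining are clamped to zero and the
    affected edges recorded in ``clamped_edges``.
    """

    adjacency: dict = field(default_factory=dict)
    clamped_edges: list = field(default_factory=list)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.adjacency if isinstance(n, str))

    def _leafset_beyond(self, u, v) -> frozenset:
        """Leaves reachable from ``v`` when the edge to ``u`` is removed."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            for nb in self.adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def splits(self) -> dict[frozenset, float]:
        """Map each edge to its leaf bipartition (canonical side: the one
        not containing the alphabetically first leaf) and branch length."""
        anchor = min(self.leaves())
        out: dict[frozenset, float] = {}
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v, ln in nbrs.items():
                if (v, u) in seen_edges:
                    continue
                seen_edges.add((u, v))
                side = self._leafset_beyond(u, v)
                if anchor in side:
                    side = frozenset(self.leaves()) - side
                out[side] = ln
        return out

    def topology(self) -> set[frozenset]:
        """Non-trivial splits only (sides of size >= 2 on both ends)."""
        nl = len(self.leaves())
        return {
            s for s in self.splits() if 2 <= len(s) <= nl - 2
        }

    def to_newick(self) -> str:
        internals = [n for n in self.adjacency if not isinstance(n, str)]
        root = max(internals) if internals else min(self.leaves())

        def render(node, parent) -> str:
            children = [nb for nb in self.adjacency[node] if nb != parent]
            children.sort(key=lambda c: min(self._leafset_beyond(node, c)))
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:g}" for c in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def neighbor_joining(dist: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the alphabetical order of the
    joined clusters' taxon names.  On an additive distance matrix the
    source tree (topology and branch lengths) is recovered exactly.
    """
    m = dist.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ResevarError("distance matrix is not symmetric")
    if len(dist) < 3:
        raise ResevarError("neighbor joining needs at least 3 taxa")
    tree = PhyloTree({t: {} for t in dist.index})
    # active node -> (sort key, distances to other active nodes)
    keys: dict = {t: (t,) for t in dist.index}
    d: dict = {
        a: {b: float(dist.loc[a, b]) for b in dist.index if b != a}
        for a in dist.index
    }
    next_internal = 0

    def add_edge(u, v, length: float) -> None:
        if length < -1e-12:
            tree.clamped_edges.append((u, v, length))
            length = 0.0
        length = max(length, 0.0)
        tree.adjacency[u][v] = length
        tree.adjacency[v][u] = length

    while len(d) > 3:
        nodes = sorted(d, key=lambda n: keys[n])
        n_active = len(nodes)
        r = {i: sum(d[i].values()) for i in nodes}
        best = None
        for ai, a in enumerate(nodes):
            for b in nodes[ai + 1 :]:
                q = (n_active - 2) * d[a][b] - r[a] - r[b]
                cand = (q, keys[a], keys[b])
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        la = d[a][b] / 2 + (r[a] - r[b]) / (2 * (n_active - 2))
        lb = d[a][b] - la
        u = next_internal
        next_internal += 1
        tree.adjacency[u] = {}
        add_edge(u, a, la)
        add_edge(u, b, lb)
        du = {}
        for k in nodes:
            if k in (a, b):
                continue
            du[k] = (d[a][k] + d[b][k] - d[a][b]) / 2
            d[k][u] = du[k]
            del d[k][a], d[k][b]
        d[u] = du
        keys[u] = tuple(sorted(keys[a] + keys[b]))
        del d[a], d[b]

    a, b, c = sorted(d, key=lambda n: keys[n])
    u = next_internal
    tree.adjacency[u] = {}
    add_edge(u, a, (d[a][b] + d[a][c] - d[b][c]) / 2)
    add_edge(u, b, (d[a][b] + d[b][c] - d[a][c]) / 2)
    add_edge(u, c, (d[a][c] + d[b][c] - d[a][b]) / 2)
    return tree
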