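import numpy as np
import pandas as pd
import pytest

from resevar import phylo
from resevar.core import CoverageMask, ResevarError, VariantRecord


def snp(sample, pos, alt="G", zyg="hom_alt"):
    return VariantRecord(sample, "c", pos, "A", alt, "SNP", zygosity=zyg)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_identical_variant_sets_have_zero_distance():
    sets = {"a": [snp("a", 1), snp("a", 2)], "b": [snp("b", 1), snp("b", 2)]}
    d = phylo.snp_distance_matrix(sets)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "reference"] == 1.0  # every locus differs from ref


def test_distance_is_mismatch_fraction():
    # 5 loci shared by a and b, 5 loci unique to a: 10 eligible loci
    shared = [snp("a", p) for p in range(5)] + [snp("b", p) for p in range(5)]
    unique = [snp("a", p) for p in range(10, 15)]
    sets = {"a": [r for r in shared + unique if r.sample == "a"],
            "b": [r for r in shared if r.sample == "b"]}
    d = phylo.snp_distance_matrix(sets)
    assert d.loc["a", "b"] == pytest.approx(5 / 10)
    assert d.loc["a", "reference"] == pytest.approx(1.0)
    assert d.loc["b", "reference"] == pytest.approx(5 / 10)


def test_het_contributes_half_mismatch():
    sets = {"a": [snp("a", 1, zyg="het")], "b": [snp("b", 1)]}
    d = phylo.snp_distance_matrix(sets)
    assert d.loc["a", "b"] == pytest.approx(0.5)   # A/G vs G/G
    assert d.loc["a", "reference"] == pytest.approx(0.5)  # A/G vs A/A
    assert d.loc["b", "reference"] == pytest.approx(1.0)


def test_distance_matrix_matches_brute_force_on_simulated_data(sim):
    d = phylo.snp_distance_matrix(sim.variant_sets, sim.masks)
    axioms = phylo.check_distance_axioms(d)
    assert axioms["symmetric"] and axioms["zero_diagonal"] and axioms["non_negative"]

    # brute-force locus-by-locus recount for one pair
    samples = list(sim.config.samples)
    alleles: dict[tuple, dict[str, tuple]] = {}
    for s in samples:
        for r in sim.variant_sets[s]:
            if r.vtype != "SNP":
                continue
            gt = (r.alt, r.alt) if r.zygosity == "hom_alt" else tuple(
                sorted((r.ref, r.alt))
            )
            alleles.setdefault((r.chrom, r.pos, r.ref), {})[s] = gt
    total = 0.0
    n = 0
    for (chrom, pos, ref), per in alleles.items():
        if not all(sim.masks[s].is_covered(chrom, pos) for s in samples):
            continue
        n += 1
        a = per.get("R1", (ref, ref))
        b = per.get("R2", (ref, ref))
        if a == b:
            pass
        elif set(a) & set(b):
            total += 0.5
        else:
            total += 1.0
    assert d.loc["R1", "R2"] == pytest.approx(total / n)


def test_samples_cluster_away_from_reference(sim):
    d = phylo.snp_distance_matrix(sim.variant_sets, sim.masks)
    off = d.where(~np.eye(len(d), dtype=bool))
    closest = off.stack().idxmin()
    assert "reference" not in closest


def test_zero_eligible_loci_errors():
    masks = {"a": CoverageMask({}), "b": CoverageMask({})}
    sets = {"a": [snp("a", 1)], "b": []}
    with pytest.raises(ResevarError, match="eligible"):
        phylo.snp_distance_matrix(sets, masks)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxa_closed_form():
    d = pd.DataFrame(
        [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )
    tree = phylo.neighbor_joining(d)
    splits = tree.splits()
    assert splits[frozenset({"B"})] == pytest.approx((5 + 10 - 9) / 2)
    assert splits[frozenset({"C"})] == pytest.approx((9 + 10 - 5) / 2)
    # the A pendant is the complement split
    leaves = frozenset("ABC")
    assert splits[leaves - {"A"}] == pytest.approx((5 + 9 - 10) / 2)


def _random_additive_tree(rng, n):
    """Random binary tree on n leaves with positive branch lengths."""
    names = [f"T{i:02d}" for i in range(n)]
    adj: dict = {}

    def add(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    add(names[0], "i0", rng.uniform(0.1, 1.0))
    add("i0", names[1], rng.uniform(0.1, 1.0))
    add("i0", names[2], rng.uniform(0.1, 1.0))
    for k, leaf in enumerate(names[3:], start=1):
        edges = list({tuple(sorted((str(u), str(v))))
                      for u in adj for v in adj[u]})
        u, v = edges[rng.integers(0, len(edges))]
        ln = adj[u][v]
        w = f"i{k}"
        f = rng.uniform(0.2, 0.8)
        del adj[u][v], adj[v][u]
        add(u, w, ln * f)
        add(w, v, ln * (1 - f))
        add(w, leaf, rng.uniform(0.1, 1.0))
    return names, adj


def _distances(names, adj):
    out = pd.DataFrame(0.0, index=names, columns=names)
    for s in names:
        dist = {s: 0.0}
        stack = [s]
        while stack:
            x = stack.pop()
            for y, ln in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + ln
                    stack.append(y)
        for t in names:
            out.loc[s, t] = dist[t]
    return out


def _splits_of(adj, leaves):
    anchor = min(leaves)
    out = {}
    seen = set()
    for u in adj:
        for v in adj[u]:
            if (v, u) in seen:
                continue
            seen.add((u, v))
            stack, visited, side = [v], {u, v}, set()
            while stack:
                x = stack.pop()
                if x in leaves:
                    side.add(x)
                for y in adj[x]:
                    if y not in visited:
                        visited.add(y)
                        stack.append(y)
            fs = frozenset(side)
            if anchor in fs:
                fs = frozenset(leaves) - fs
            out[fs] = adj[u][v]
    return out


def test_nj_recovers_additive_trees_exactly():
    rng = np.random.default_rng(123)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        names, adj = _random_additive_tree(rng, n)
        want = _splits_of(adj, set(names))
        got = phylo.neighbor_joining(_distances(names, adj)).splits()
        assert set(want) == set(got)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)


def test_nj_matches_dendropy_on_a_random_matrix():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(5)
    names, adj = _random_additive_tree(rng, 6)
    D = _distances(names, adj)
    mine = phylo.neighbor_joining(D)

    csv = "," + ",".join(names) + "\n"
    for a in names:
        csv += a + "," + ",".join(str(D.loc[a, b]) for b in names) + "\n"
    import io as _io
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        _io.StringIO(csv), delimiter=","
    )
    their = pdm.nj_tree()
    their.encode_bipartitions()
    taxa = {t.label: t for t in their.taxon_namespace}
    their_splits = set()
    for edge in their.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if min(names) in side:
            side = frozenset(names) - side
        if 2 <= len(side) <= len(names) - 2:
            their_splits.add(side)
    assert mine.topology() == their_splits


def test_nj_tie_break_is_deterministic():
    # four equidistant taxa: any resolution is valid, output must be stable
    d = pd.DataFrame(1.0, index=list("ABCD"), columns=list("ABCD"))
    np.fill_diagonal(d.values, 0.0)
    t1 = phylo.neighbor_joining(d).to_newick()
    t2 = phylo.neighbor_joining(d.copy()).to_newick()
    assert t1 == t2


def test_nj_rejects_bad_input():
    d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
    with pytest.raises(ResevarError, match="3 taxa"):
        phylo.neighbor_joining(d)
    bad = pd.DataFrame(
        [[0, 1, 2], [9, 0, 1], [2, 1, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )
    with pytest.raises(ResevarError, match="symmetric"):
        phylo.neighbor_joining(bad)
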