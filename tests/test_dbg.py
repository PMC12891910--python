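"""De Bruijn graph construction, component extraction, and unitig contigs."""

import numpy as np
import pytest

import dbgfeat as d
from dbgfeat._encoding import canonical_code, encode_canonical_windows, encode_kmer
from dbgfeat.dbg import Component, connected_components
from dbgfeat.kmer_core import KmerCountTable


def table_from_seqs(seqs, k, sample_id="s", min_count=1):
    return d.count_kmers(seqs, k=k, min_count=min_count, sample_id=sample_id)


def graph_from_seqs(seqs, k):
    return d.build_graph([table_from_seqs(seqs, k)])


def code(s):
    return canonical_code(encode_kmer(s), len(s))


# ---------------------------------------------------------------------------
# graph construction


def test_build_graph_chain_adjacency():
    g = graph_from_seqs(["AAACC"], 3)
    assert g.kmer_nodes() == {"AAA", "AAC", "ACC"}
    assert g.neighbors(code("AAA")) == [code("AAC")]
    assert set(g.neighbors(code("AAC"))) == {code("AAA"), code("ACC")}


def test_build_graph_union_and_additivity():
    t1 = table_from_seqs(["AAAAA"], 3, "s1")
    t2 = table_from_seqs(["CCGCC"], 3, "s2")
    g = d.build_graph([t1, t2])
    assert len(connected_components(g)) == 2  # disjoint k-mer sets
    g2 = d.build_graph([t1, t1])
    assert len(g2) == len(d.build_graph([t1]))
    assert g2.abundance_of(code("AAA")) == 2 * d.build_graph([t1]).abundance_of(code("AAA"))


def test_build_graph_mixed_k_errors():
    with pytest.raises(ValueError, match="mixed k"):
        d.build_graph([table_from_seqs(["AAACC"], 3), table_from_seqs(["AAACCGG"], 5)])


# ---------------------------------------------------------------------------
# local search


def chain_kmers(seq, k):
    return {d.canonical_form(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def test_local_search_chain_around_middle_pivot():
    seq = "AATCGGC"  # 5 distinct 3-mers in a chain
    g = graph_from_seqs([seq], 3)
    assert len(g) == 5
    pivot = d.canonical_form(seq[2:5])
    comps = d.local_search(g, {pivot}, max_radius=2)
    assert len(comps) == 1
    assert comps[0].kmers == chain_kmers(seq, 3)
    assert comps[0].pivots == {pivot}


def test_local_search_merges_connected_pivots():
    seq = "AATCGGC"
    g = graph_from_seqs([seq], 3)
    comps = d.local_search(g, {d.canonical_form(seq[:3]), d.canonical_form(seq[-3:])}, max_radius=10)
    assert len(comps) == 1
    assert len(comps[0].pivots) == 2


def test_local_search_prunes_pivot_free_arm():
    # Y: stem TTACG branching into ...GA-extension and ...GC-extension arms
    stem = "TTACG"
    arm1 = stem + "ATT"  # pivot arm
    arm2 = stem + "CGGCC"  # long pivot-free arm
    g = graph_from_seqs([arm1, arm2], 3)
    pivot = d.canonical_form(arm1[-3:])
    comps = d.local_search(g, {pivot}, max_radius=2, branch_limit=2)
    assert len(comps) == 1
    far = d.canonical_form(arm2[-3:])
    assert far not in comps[0].kmers  # far end of the pivot-free arm excluded
    assert pivot in comps[0].kmers


def test_local_search_radius_and_size_caps():
    seq = "AATCGGCTTAC"
    g = graph_from_seqs([seq], 3)
    pivot = d.canonical_form(seq[:3])
    deg = len(g.neighbors(code(pivot)))
    comps = d.local_search(g, {pivot}, max_radius=1)
    assert comps[0].size <= 1 + deg  # only pivot and its direct neighbors
    assert comps[0].size < len(g)
    comps2 = d.local_search(g, {pivot}, max_radius=100, max_component_size=3)
    assert comps2[0].size <= max(3, 1 + deg)
    assert comps2[0].size < len(g)


def test_local_search_errors_and_warnings():
    g = graph_from_seqs(["AAACC"], 3)
    with pytest.raises(ValueError):
        d.local_search(g, set())
    with pytest.warns(UserWarning, match="absent"):
        comps = d.local_search(g, {"AAA", "CGC"})
    assert len(comps) == 1
    with pytest.raises(ValueError, match="present"):
        d.local_search(g, {"CGC"})


def test_local_search_all_pivots_equals_connected_components():
    rng = np.random.default_rng(12)
    seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, size=25)) for _ in range(6)]
    g = graph_from_seqs(seqs, 5)
    comps = d.local_search(
        g, g.kmer_nodes(), max_radius=10**9, branch_limit=float("inf"),
        max_component_size=10**9,
    )
    expected = {tuple(map(int, c)) for c in connected_components(g)}
    got = {tuple(map(int, c.codes)) for c in comps}
    assert got == expected


# ---------------------------------------------------------------------------
# color vectors


def test_color_vectors_eq1():
    sets = {"a1": {"AAA"}, "a2": {"AAA"}, "b1": {"AAA", "AAC"}}
    lab = d.GroupLabels({"a1": "A", "a2": "A", "b1": "B"})
    colors = d.color_vectors(sets, lab)
    assert colors["AAA"] == pytest.approx({"A": 2 / 3, "B": 1 / 3})
    assert colors["AAC"] == pytest.approx({"A": 0.0, "B": 1.0})
    sums = colors.values.sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-12


def test_color_vectors_group_limit():
    sets = {f"s{i}": {"AAA"} for i in range(4)}
    lab = d.GroupLabels({f"s{i}": f"G{i}" for i in range(4)})
    with pytest.raises(ValueError, match="two or three"):
        d.color_vectors(sets, lab)
    colors = d.color_vectors(sets, lab, allow_many_groups=True)
    assert len(colors.categories) == 4


def test_extract_colored_threshold_finds_pure_marker():
    marker = "TTACGGATC"
    shared = "CCATGCA"
    sets = {
        "a1": chain_kmers(shared, 3),
        "b1": chain_kmers(shared, 3) | chain_kmers(marker, 3),
        "b2": chain_kmers(marker, 3),
    }
    lab = d.GroupLabels({"a1": "A", "b1": "B", "b2": "B"})
    tables = {s: KmerCountTable.from_dict({km: 1 for km in v}, k=3, sample_id=s) for s, v in sets.items()}
    g = d.build_graph(list(tables.values()))
    colors = d.color_vectors(sets, lab)
    comps = d.extract_colored_components(g, colors, mode="threshold", threshold=0.9)
    by_cat = {c.category for c in comps}
    assert by_cat == {"B"}
    recovered = set().union(*(c.kmers for c in comps))
    assert recovered == chain_kmers(marker, 3)


def test_extract_colored_threshold_vacuous():
    sets = {"a1": {"AAA"}, "b1": {"AAA"}}
    lab = d.GroupLabels({"a1": "A", "b1": "B"})
    g = d.build_graph([KmerCountTable.from_dict({"AAA": 1}, sample_id="x")])
    colors = d.color_vectors(sets, lab)
    with pytest.warns(UserWarning):
        comps = d.extract_colored_components(g, colors, mode="threshold", threshold=1.0)
    assert comps == []


def test_extract_colored_top_n_prefers_heavier_seed():
    # two pure-B chains; verify they are disjoint components at k=5, then
    # check that n_per_group=1 keeps exactly the heavier one
    c1, c2 = "TTAACGGAT", "CCCTGTGCC"
    km1, km2 = chain_kmers(c1, 5), chain_kmers(c2, 5)
    sets = {"a1": {"AAAAA"}, "b1": km1 | km2, "b2": km1 | km2}
    lab = d.GroupLabels({"a1": "A", "b1": "B", "b2": "B"})
    t = KmerCountTable.from_dict(
        {**{km: 9 for km in km2}, **{km: 1 for km in km1}, "AAAAA": 1}, k=5, sample_id="x"
    )
    g = d.build_graph([t])
    b_only = d.build_graph([KmerCountTable.from_dict({km: 1 for km in km1 | km2}, k=5)])
    assert len(connected_components(b_only)) == 2  # test premise: truly disjoint
    colors = d.color_vectors(sets, lab)
    comps = d.extract_colored_components(g, colors, mode="top_n", n_per_group=1)
    bs = [c for c in comps if c.category == "B"]
    assert len(bs) == 1
    assert bs[0].kmers == km2


def test_extract_colored_threshold_validation():
    g = d.build_graph([KmerCountTable.from_dict({"AAA": 1}, sample_id="x")])
    sets = {"a1": {"AAA"}, "b1": {"AAA"}}
    colors = d.color_vectors(sets, d.GroupLabels({"a1": "A", "b1": "B"}))
    with pytest.raises(ValueError):
        d.extract_colored_components(g, colors, mode="threshold", threshold=0.4)
    with pytest.raises(ValueError):
        d.extract_colored_components(g, colors, mode="bogus")


# ---------------------------------------------------------------------------
# condensed (unsupervised) components


def chain_graph(seq, k, abundances):
    """Graph over the k-mers of seq with per-position abundances."""
    codes = [code(seq[i : i + k]) for i in range(len(seq) - k + 1)]
    assert len(set(codes)) == len(codes)
    order = np.argsort(np.array(codes, dtype=np.uint64))
    arr = np.array(codes, dtype=np.uint64)[order]
    ab = np.array(abundances, dtype=float)[order]
    return d.DeBruijnGraph(k, arr, ab)


def test_condensed_low_coverage_node_splits_chain():
    g = chain_graph("AATCGGC", 3, [5, 5, 1, 5, 5])
    comps = d.condensed_components(g, initial_threshold=2, size_bounds=(1, 100))
    assert sorted(c.size for c in comps) == [2, 2]


def test_condensed_uniform_chain_single_component():
    g = chain_graph("AATCGGC", 3, [5, 5, 5, 5, 5])
    comps = d.condensed_components(g, initial_threshold=2, size_bounds=(1, 100))
    assert len(comps) == 1 and comps[0].size == 5


def test_condensed_oversized_uniform_accepted_after_max_iterations():
    g = chain_graph("AATCGGC", 3, [5] * 5)
    comps = d.condensed_components(g, initial_threshold=2, size_bounds=(1, 3), max_iterations=4)
    assert len(comps) == 1 and comps[0].size == 5  # cannot split further; kept


def test_condensed_all_filtered_errors():
    g = chain_graph("AATCGGC", 3, [1] * 5)
    with pytest.raises(ValueError):
        d.condensed_components(g, initial_threshold=10, size_bounds=(1, 100))


def test_condensed_undersized_discarded():
    g = chain_graph("AATCGGC", 3, [5, 5, 1, 5, 5])
    comps = d.condensed_components(g, initial_threshold=2, size_bounds=(3, 100))
    assert comps == []


def test_condensed_invariant_to_node_order():
    rng = np.random.default_rng(2)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=60))
    codes = np.array(sorted({code(seq[i : i + 5]) for i in range(len(seq) - 4)}), dtype=np.uint64)
    ab = rng.integers(1, 8, size=codes.size).astype(float)
    perm = rng.permutation(codes.size)
    g1 = d.DeBruijnGraph(5, codes, ab)
    g2 = d.DeBruijnGraph(5, codes[perm], ab[perm])
    c1 = d.condensed_components(g1, initial_threshold=2, size_bounds=(1, 10))
    c2 = d.condensed_components(g2, initial_threshold=2, size_bounds=(1, 10))
    assert [sorted(c.kmers) for c in c1] == [sorted(c.kmers) for c in c2]


# ---------------------------------------------------------------------------
# contigs


def make_component(kmers, k, cid="c0"):
    codes = np.array(sorted({code(km) for km in kmers}), dtype=np.uint64)
    return Component(id=cid, category="unsupervised", k=k, codes=codes)


def test_contigs_chain_merges_to_one():
    comp = make_component({"AAA", "AAC", "ACC"}, 3)
    contigs = d.component_contigs(comp)
    assert [c.sequence for c in contigs] == ["AAACC"]


def test_contigs_single_kmer():
    comp = make_component({"ACT"}, 3)
    (contig,) = d.component_contigs(comp)
    assert contig.sequence in ("ACT", "AGT")
    assert len(contig.sequence) == 3


def test_contigs_y_branch_covers_all_kmers_once():
    seqs = ["TTACGA", "TTACGC"]
    kmers = set().union(*(chain_kmers(s, 3) for s in seqs))
    comp = make_component(kmers, 3)
    contigs = d.component_contigs(comp)
    assert len(contigs) >= 2
    recovered = []
    for c in contigs:
        recovered.extend(
            int(x) for x in encode_canonical_windows(c.sequence, 3)
        )
    assert sorted(recovered) == sorted(int(x) for x in comp.codes)  # each exactly once


def test_contigs_cycle():
    # circular sequence: CACGTGTAC... build a small cycle via repeated seq
    seq = "ACGGTCA" + "ACG"[:2]  # wrap-around windows
    kmers = {d.canonical_form((seq + seq)[i : i + 3]) for i in range(7)}
    comp = make_component(kmers, 3)
    contigs = d.component_contigs(comp)
    recovered = []
    for c in contigs:
        recovered.extend(int(x) for x in encode_canonical_windows(c.sequence, 3))
    assert sorted(set(recovered)) == sorted(int(x) for x in comp.codes)


def test_contigs_empty_component_errors():
    comp = Component(id="e", category="x", k=3, codes=np.empty(0, dtype=np.uint64))
    with pytest.raises(ValueError):
        d.component_contigs(comp)


def test_component_pivot_subset_enforced():
    with pytest.raises(ValueError):
        Component(
            id="x", category="A", k=3,
            codes=np.array([0], dtype=np.uint64),
            pivot_codes=np.array([1], dtype=np.uint64),
        )


def test_components_fasta_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, size=40)) for _ in range(3)]
    g = graph_from_seqs(seqs, 7)
    comps = [
        Component(id=f"A_{i}", category="A", k=7, codes=c)
        for i, c in enumerate(connected_components(g))
    ]
    path = tmp_path / "comps.fasta"
    d.components_to_fasta(comps, path)
    back = d.read_components_fasta(path, 7)
    assert {c.id for c in back} == {c.id for c in comps}
    for c0 in comps:
        c1 = next(c for c in back if c.id == c0.id)
        assert c1.category == "A"
        assert set(map(int, c1.codes)) == set(map(int, c0.codes))


def test_read_components_fasta_malformed_header(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">oops nope\nACGTACG\n")
    with pytest.raises(ValueError, match="oops"):
        d.read_components_fasta(path, 3)
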