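"""Group-specific k-mer selection: unique, chi-squared, and conjunction modes."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import dbgfeat as d
from dbgfeat.kmer_core import KmerCountTable
from dbgfeat.selection import (
    GroupLabels,
    PresenceMatrix,
    _mw_exact_matrix,
    _mw_normal_matrix,
    sample_codes,
)


def make_presence(presence_rows, categories, group_sizes, k=3):
    """Direct PresenceMatrix construction from a list of per-category rows."""
    n = len(presence_rows)
    return PresenceMatrix(
        k=k,
        categories=categories,
        group_sizes=group_sizes,
        codes=np.arange(n, dtype=np.uint64),
        presence=np.array(presence_rows, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# labels and presence


def test_group_labels_validation():
    with pytest.raises(ValueError):
        GroupLabels({"s1": "A"})  # single category
    with pytest.raises(ValueError):
        GroupLabels({"s1": "A", "s2": "B"}, categories=["A", "B", "C"])  # empty C
    lab = GroupLabels({"s1": "A", "s2": "B", "s3": "A"})
    assert lab.categories == ["A", "B"]
    assert lab.group_sizes() == {"A": 2, "B": 1}


def test_presence_matrix_counts():
    sets = {
        "a1": {"AAA", "AAC"},
        "a2": {"AAA"},
        "b1": {"ACC"},
        "c1": {"AAA", "ACC"},
    }
    lab = GroupLabels({"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
    pm = d.build_presence_matrix(sets, lab)
    assert pm.counts_for("AAA") == {"A": 2, "B": 0, "C": 1}
    assert pm.counts_for("ACC") == {"A": 0, "B": 1, "C": 1}
    assert pm.counts_for("AGG") == {"A": 0, "B": 0, "C": 0}  # unsupported -> absent
    assert len(pm) == 3
    # every stored k-mer respects group sizes
    assert (pm.presence <= np.array([2, 1, 1])).all()


def test_presence_matrix_missing_sample_errors():
    lab = GroupLabels({"a1": "A", "b1": "B"})
    with pytest.raises(ValueError, match="b1"):
        d.build_presence_matrix({"a1": {"AAA"}}, lab)


# ---------------------------------------------------------------------------
# unique mode


def test_select_unique_rule():
    pm = make_presence([[3, 0], [3, 1], [2, 0]], ["A", "B"], {"A": 3, "B": 3})
    sel = d.select_unique(pm, "A", G=2)
    assert set(map(int, sel.codes)) == {0, 2}
    sel3 = d.select_unique(pm, "A", G=3)
    assert set(map(int, sel3.codes)) == {0}
    with pytest.raises(ValueError):
        d.select_unique(pm, "A", G=4)  # exceeds group size
    with pytest.raises(ValueError):
        d.select_unique(pm, "Z", G=1)


def test_select_unique_matches_naive_double_loop():
    rng = np.random.default_rng(5)
    labels = GroupLabels({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
    sets = {
        sid: set(
            np.random.default_rng(hash(sid) % 2**31).integers(0, 500, size=200).tolist()
        )
        for sid in labels.sample_ids
    }
    coded = {s: np.array(sorted(v), dtype=np.uint64) for s, v in sets.items()}
    pm = d.build_presence_matrix(coded, labels, k=5)
    for G in (1, 2, 3):
        sel = d.select_unique(pm, "A", G)
        naive = set()
        union = set().union(*sets.values())
        for km in union:
            in_a = sum(km in sets[s] for s in ("s0", "s1", "s2"))
            in_b = sum(km in sets[s] for s in ("s3", "s4", "s5"))
            if in_a >= G and in_b == 0:
                naive.add(km)
        assert set(map(int, sel.codes)) == naive


@pytest.mark.parametrize(
    "counts_by_G,expected",
    [
        ({3: 0, 2: 1500, 1: 20000}, 2),  # inside range at G=2
        ({2: 500, 1: 900}, 1),  # none inside; 900 is closest to lo=1000
        ({3: 1200, 2: 5000, 1: 20000}, 3),  # stringency first: largest in-range G
    ],
)
def test_auto_select_G_policy(counts_by_G, expected):
    # build exclusive k-mers whose presence counts realize counts_by_G
    size = max(counts_by_G)
    rows = []
    prev = 0
    for G in sorted(counts_by_G, reverse=True):
        n_at_least = counts_by_G[G]
        for _ in range(n_at_least - prev):
            rows.append([G, 0])
        prev = n_at_least
    pm = make_presence(rows, ["A", "B"], {"A": size, "B": 3})
    assert d.auto_select_G(pm, "A", target_range=(1000, 10000)) == expected


def test_auto_select_G_all_zero_errors():
    pm = make_presence([[2, 1], [1, 3]], ["A", "B"], {"A": 3, "B": 3})
    with pytest.raises(ValueError, match="chisq or stats"):
        d.auto_select_G(pm, "A")


# ---------------------------------------------------------------------------
# chi-squared


def test_chisq_yates_closed_form():
    stat, p = d.chisq_yates(10, 0, 0, 10)
    assert stat == pytest.approx(16.2, abs=1e-12)  # 20*(100-10)^2/10^4
    assert p == pytest.approx(float(sps.chi2.sf(16.2, 1)), rel=1e-12)
    assert d.chisq_yates(5, 5, 5, 5) == (0.0, 1.0)
    assert d.chisq_yates(3, 0, 3, 0) == (0.0, 1.0)  # zero margin
    with pytest.raises(ValueError):
        d.chisq_yates(-1, 2, 3, 4)


def test_chisq_yates_row_column_swap_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b, c, cc = rng.integers(0, 30, size=4)
        s1, _ = d.chisq_yates(a, b, c, cc)
        s2, _ = d.chisq_yates(cc, c, b, a)
        assert s1 == pytest.approx(s2, abs=1e-12)


def test_select_chisq_single_kmer_and_direction():
    pm = make_presence([[10, 0]], ["A", "B"], {"A": 10, "B": 10})
    sel = d.select_chisq(pm, "A")
    assert len(sel) == 1
    assert sel.p_corrected[0] == pytest.approx(sel.p_raw[0])  # one test, no correction
    assert sel.p_raw[0] == pytest.approx(5.699411623331848e-05, rel=1e-9)
    # the same k-mer is depleted from B's standpoint -> rejected for B
    assert len(d.select_chisq(pm, "B")) == 0


def test_select_chisq_rejects_equal_presence():
    pm = make_presence([[5, 5]], ["A", "B"], {"A": 10, "B": 10})
    assert len(d.select_chisq(pm, "A")) == 0


def test_select_chisq_ranking_and_top_n():
    rows = [[10, 0], [9, 0], [10, 1], [5, 5]]
    pm = make_presence(rows, ["A", "B"], {"A": 10, "B": 10})
    sel = d.select_chisq(pm, "A", alpha=0.05, top_n=2)
    stats = list(sel.statistic)
    assert stats == sorted(stats, reverse=True)
    assert len(sel) == 2


def test_selected_kmers_always_enriched_in_target():
    rng = np.random.default_rng(7)
    rows = rng.integers(0, 11, size=(500, 2))
    pm = make_presence(rows.tolist(), ["A", "B"], {"A": 10, "B": 10})
    for cat in ("A", "B"):
        sel = d.select_chisq(pm, cat, alpha=0.5)
        j = pm.categories.index(cat)
        for code in sel.codes:
            row = pm.presence[int(code)]
            rate_t = row[j] / pm.group_sizes[cat]
            rate_r = (row.sum() - row[j]) / (sum(pm.group_sizes.values()) - pm.group_sizes[cat])
            assert rate_t > rate_r


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_examples():
    u, p = d.mann_whitney_u([5, 6, 7], [1, 2, 3])
    assert u == 9.0  # complete separation: U = n*m
    assert p == pytest.approx(0.1)  # 2/C(6,3)
    u, p = d.mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == 4.5  # nm/2 under symmetry
    assert p == 1.0
    with pytest.raises(ValueError):
        d.mann_whitney_u([], [1])


def test_mann_whitney_matches_scipy_exact_no_ties():
    rng = np.random.default_rng(3)
    for _ in range(30):
        x = rng.permutation(40)[:4].astype(float)
        y = rng.permutation(40)[:5].astype(float) + 0.5
        u, p = d.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_mann_whitney_normal_path_matches_scipy_with_ties():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.integers(0, 5, size=9).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        u, p = d.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_mw_matrix_paths_match_scalar():
    rng = np.random.default_rng(9)
    A = rng.integers(0, 6, size=(40, 10)).astype(float)
    mask = np.array([True] * 5 + [False] * 5)
    u_ex, p_ex = _mw_exact_matrix(A, mask)
    for i in range(A.shape[0]):
        u, p = d.mann_whitney_u(A[i, mask], A[i, ~mask])
        assert u_ex[i] == pytest.approx(u)
        assert p_ex[i] == pytest.approx(p, abs=1e-12)
    A2 = rng.integers(0, 6, size=(20, 14)).astype(float)
    mask2 = np.array([True] * 7 + [False] * 7)
    u_n, p_n = _mw_normal_matrix(A2, mask2)
    for i in range(A2.shape[0]):
        u, p = d.mann_whitney_u(A2[i, mask2], A2[i, ~mask2])
        assert u_n[i] == pytest.approx(u)
        assert p_n[i] == pytest.approx(p, rel=1e-9)


# ---------------------------------------------------------------------------
# stats (conjunction) mode


def _tables_from_abundances(abund: dict[str, dict[str, int]], k=3):
    return {
        sid: KmerCountTable.from_dict(kmers, k=k, sample_id=sid)
        for sid, kmers in abund.items()
    }


def test_select_stats_marker_selected():
    # marker k-mer: abundance 10 in all 5 category samples, absent from rest
    abund = {f"a{i}": {"AAA": 10, "AAC": 7} for i in range(5)}
    abund.update({f"b{i}": {"AAC": 7} for i in range(5)})
    labels = GroupLabels({s: s[0].upper() for s in abund})
    sel = d.select_stats(_tables_from_abundances(abund), labels, "A")
    assert sel.pivots == {"AAA"}


def test_select_stats_rejects_uniform_kmer():
    abund = {f"a{i}": {"AAA": 5} for i in range(5)}
    abund.update({f"b{i}": {"AAA": 5} for i in range(5)})
    labels = GroupLabels({s: s[0].upper() for s in abund})
    sel = d.select_stats(_tables_from_abundances(abund), labels, "A")
    assert len(sel) == 0


def test_select_stats_conjunction_requires_presence_signal():
    # present everywhere at 10x higher abundance in A: chi-squared is null,
    # so the conjunction rejects despite a maximal Mann-Whitney signal
    abund = {f"a{i}": {"AAA": 50} for i in range(5)}
    abund.update({f"b{i}": {"AAA": 5} for i in range(5)})
    labels = GroupLabels({s: s[0].upper() for s in abund})
    sel = d.select_stats(_tables_from_abundances(abund), labels, "A")
    assert len(sel) == 0


def test_selected_kmers_tsv_dump(tmp_path):
    pm = make_presence([[10, 0], [9, 0]], ["A", "B"], {"A": 10, "B": 10})
    sel = d.select_chisq(pm, "A")
    path = tmp_path / "sel.tsv"
    sel.write_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "kmer\tstatistic\tp_raw\tp_corrected"
    stats = [float(ln.split("\t")[1]) for ln in lines[1:]]
    assert stats == sorted(stats, reverse=True)


def test_sample_codes_coercion_consistency():
    table = KmerCountTable.from_dict({"AAA": 2, "TTT": 3})  # TTT folds onto AAA
    codes_t, k = sample_codes(table)
    assert k == 3
    assert codes_t.tolist() == [0] and table.get("AAA") == 5
    codes_s, _ = sample_codes({"AAC", "GTT"})  # same canonical k-mer twice
    assert codes_s.size == 1
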