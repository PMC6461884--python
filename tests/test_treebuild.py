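import itertools

import numpy as np
import pandas as pd
import pytest

from tgcevo import treebuild as tb


def matrix_from_sets(sets: dict, labels=None, chars=None):
    """CharacterMatrix from {group: iterable of characters}."""
    all_chars = sorted(chars or {c for s in sets.values() for c in s})
    data = pd.DataFrame(
        [[1.0 if c in s else 0.0 for c in all_chars] for s in sets.values()],
        index=list(sets), columns=all_chars, dtype=float)
    characters = {c: tb.Character(c, "SNV") for c in all_chars}
    labels = labels or {}
    return tb.CharacterMatrix(
        data, characters,
        {g: frozenset({labels[g]} if g in labels else {"EC"}) for g in sets})


# -- brute-force oracles ----------------------------------------------------


def pairwise_compatible(col_x, col_y):
    """Independent no-loss compatibility check over observed entries."""
    pat = set()
    for x, y in zip(col_x, col_y):
        if not (np.isnan(x) or np.isnan(y)):
            pat.add((int(x), int(y)))
    return not {(1, 1), (1, 0), (0, 1)} <= pat


def brute_force_min_violations(df: pd.DataFrame) -> int:
    """Smallest number of characters to drop for pairwise compatibility,
    by exhaustive subset enumeration."""
    chars = list(df.columns)
    for k in range(len(chars) + 1):
        for drop in itertools.combinations(chars, k):
            keep = [c for c in chars if c not in drop]
            if all(pairwise_compatible(df[x].to_numpy(float),
                                       df[y].to_numpy(float))
                   for x, y in itertools.combinations(keep, 2)):
                return k
    return len(chars)


def expected_clusters(sets: dict) -> set:
    """Closed-form clusters of the unique no-loss phylogeny on complete,
    conflict-free data: carriers of each character, plus the
    superset-closure of each group's genotype."""
    groups = list(sets)
    all_groups = frozenset(groups)
    out = set()
    chars = {c for s in sets.values() for c in s}
    for c in chars:
        out.add(frozenset(g for g in groups if c in sets[g]))
    for g in groups:
        if sets[g]:
            out.add(frozenset(h for h in groups if sets[g] <= sets[h]))
        else:
            out.add(frozenset({g}))  # empty genotype: leaf under the root
    return {c for c in out if 0 < len(c) < len(all_groups)}


def random_no_loss_instance(rng, n_nodes=6, n_chars=8):
    """Random gain-once instance: a random rooted tree, characters gained
    on random edges, groups = the tree's non-root nodes."""
    parents = {0: None}
    for v in range(1, n_nodes):
        parents[v] = int(rng.integers(0, v))
    gains = {v: set() for v in range(n_nodes)}
    for c in range(n_chars):
        gains[int(rng.integers(1, n_nodes))].add(f"c{c}")

    def genotype(v):
        out = set()
        while v is not None:
            out |= gains[v]
            v = parents[v]
        return out

    return {f"g{v}": genotype(v) for v in range(1, n_nodes)}


# -- matrix building --------------------------------------------------------


def _marker_calls(rows):
    return pd.DataFrame(rows, columns=["sample", "marker", "arm", "kind",
                                       "vaf", "state"])


def _allelic_calls(rows):
    return pd.DataFrame(rows, columns=["sample", "target", "arm", "laf",
                                       "state", "retained_haplotype"])


class TestBuildMatrix:
    def test_independent_loh_two_columns(self):
        allelic = _allelic_calls([
            ("s1", "4q", "4q", 0.02, "LOH", "A"),
            ("s2", "4q", "4q", 0.03, "LOH", "B"),
        ])
        cm = tb.build_character_matrix(_marker_calls([]), allelic)
        assert "LOH:4q:A" in cm.data.columns
        assert "LOH:4q:B" in cm.data.columns
        assert cm.data.loc["s1", "LOH:4q:A"] == 1.0
        assert cm.data.loc["s1", "LOH:4q:B"] == 0.0
        assert cm.data.loc["s2", "LOH:4q:B"] == 1.0

    def test_missing_vaf_missing_entry(self):
        markers = _marker_calls([
            ("s1", "m1", "1p", "SNV", np.nan, "MISSING"),
            ("s1", "m2", "2q", "SNV", 0.2, "PRESENT"),
            ("s2", "m1", "1p", "SNV", 0.2, "PRESENT"),
            ("s2", "m2", "2q", "SNV", 0.0, "ABSENT"),
        ])
        cm = tb.build_character_matrix(markers, _allelic_calls([]))
        assert np.isnan(cm.data.loc["s1", "SNV:m1"])
        assert cm.data.loc["s2", "SNV:m1"] == 1.0

    def test_absent_everywhere_zero_row(self):
        markers = _marker_calls([
            ("ctrl", "m1", "1p", "SNV", 0.0, "ABSENT"),
            ("ctrl", "m2", "2q", "SNV", 0.0, "ABSENT"),
            ("tum", "m1", "1p", "SNV", 0.3, "PRESENT"),
            ("tum", "m2", "2q", "SNV", 0.3, "PRESENT"),
        ])
        cm = tb.build_character_matrix(markers, _allelic_calls([]))
        assert cm.data.loc["ctrl"].sum() == 0.0

    def test_subclonal_counts_and_flagged(self):
        markers = _marker_calls([
            ("s1", "m1", "1p", "SNV", 0.04, "SUBCLONAL"),
            ("s2", "m1", "1p", "SNV", 0.3, "PRESENT"),
        ])
        cm = tb.build_character_matrix(markers, _allelic_calls([]))
        assert cm.data.loc["s1", "SNV:m1"] == 1.0
        assert "s1" in cm.characters["SNV:m1"].subclonal_in
        strict = tb.build_character_matrix(markers, _allelic_calls([]),
                                           include_subclonal=False)
        assert strict.data.loc["s1", "SNV:m1"] == 0.0

    def test_absent_masked_on_loh_arm(self):
        markers = _marker_calls([
            ("s1", "m1", "4q", "SNV", 0.0, "ABSENT"),
            ("s2", "m1", "4q", "SNV", 0.3, "PRESENT"),
        ])
        allelic = _allelic_calls([
            ("s1", "4q", "4q", 0.02, "LOH", "A"),
            ("s2", "4q", "4q", 0.45, "BALANCED", "undetermined"),
        ])
        cm = tb.build_character_matrix(markers, allelic)
        assert np.isnan(cm.data.loc["s1", "SNV:m1"])

    def test_sample_mismatch_rejected(self):
        markers = _marker_calls([("s1", "m1", "1p", "SNV", 0.3, "PRESENT")])
        allelic = _allelic_calls([("s9", "4q", "4q", 0.4, "BALANCED",
                                   "undetermined")])
        with pytest.raises(ValueError, match="s9"):
            tb.build_character_matrix(markers, allelic)


class TestGrouping:
    def test_identical_rows_merge(self):
        cm = matrix_from_sets({"a": {"x"}, "b": {"x"}})
        g = tb.group_identical_samples(cm)
        assert g.rows == ["a+b"]

    def test_one_observed_difference_blocks_merge(self):
        cm = matrix_from_sets({"a": {"x", "y"}, "b": {"x"}})
        g = tb.group_identical_samples(cm)
        assert sorted(g.rows) == ["a", "b"]

    def test_missing_tolerant_merge_keeps_consensus(self):
        data = pd.DataFrame([[1.0, np.nan, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
                             [1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]],
                            index=["a", "b"],
                            columns=[f"c{i}" for i in range(10)])
        cm = tb.CharacterMatrix(
            data, {c: tb.Character(c, "SNV") for c in data.columns},
            {"a": frozenset(), "b": frozenset()})
        g = tb.group_identical_samples(cm)
        assert g.rows == ["a+b"]
        assert g.data.loc["a+b", "c1"] == 1.0

    def test_thin_overlap_blocks_merge(self):
        # only 1 of b's 10 observed entries is shared: insufficient evidence
        row_a = [1.0] + [np.nan] * 9
        row_b = [1.0] + [0.0] * 9
        data = pd.DataFrame([row_a, row_b], index=["a", "b"],
                            columns=[f"c{i}" for i in range(10)])
        cm = tb.CharacterMatrix(
            data, {c: tb.Character(c, "SNV") for c in data.columns},
            {"a": frozenset(), "b": frozenset()})
        g = tb.group_identical_samples(cm)
        assert sorted(g.rows) == ["a", "b"]


class TestInferTree:
    def test_nested_chain(self):
        cm = matrix_from_sets({"S1": {"a"}, "S2": {"a", "b"},
                               "S3": {"a", "b", "c"}})
        evo = tb.infer_tree(cm)
        assert evo.parent("S1") == "NORMAL"
        assert evo.parent("S2") == "S1"
        assert evo.parent("S3") == "S2"
        assert evo.gains("S1") == ("a",)
        assert evo.gains("S2") == ("b",)
        assert evo.gains("S3") == ("c",)
        assert evo.violations == ()

    def test_branch_point_latent(self):
        cm = matrix_from_sets({"S1": {"a", "b"}, "S2": {"a", "c"}})
        evo = tb.infer_tree(cm)
        latents = evo.nodes("latent")
        assert len(latents) == 1
        lat = latents[0]
        assert evo.parent(lat) == "NORMAL"
        assert evo.gains(lat) == ("a",)
        assert set(evo.children(lat)) == {"S1", "S2"}
        assert evo.gains("S1") == ("b",)
        assert evo.gains("S2") == ("c",)

    def test_single_yst_gets_latent_ec(self):
        cm = matrix_from_sets({"YST1": {"a"}}, labels={"YST1": "YST"})
        evo = tb.infer_tree(cm)
        assert evo.parent("YST1").startswith("ECx")
        assert evo.parent(evo.parent("YST1")) == "NORMAL"

    def test_gcnisx_vs_ecx_typing(self):
        cm = matrix_from_sets(
            {"G1": {"a", "b"}, "G2": {"a", "c"}},
            labels={"G1": "GCNIS", "G2": "GCNIS"})
        evo = tb.infer_tree(cm)
        assert evo.nodes("latent") == ["GCNISx1"]

    def test_character_in_all_groups_on_root_edge(self):
        cm = matrix_from_sets({"S1": {"a", "b"}, "S2": {"a"}})
        evo = tb.infer_tree(cm)
        assert evo.gains("S2") == ("a",)   # S2 is the shared ancestor node
        assert evo.parent("S2") == "NORMAL"

    def test_zero_row_attaches_to_root(self):
        cm = matrix_from_sets({"N1": set(), "S1": {"a"}})
        evo = tb.infer_tree(cm)
        assert evo.parent("N1") == "NORMAL"
        assert evo.gains("N1") == ()

    def test_empty_matrix_rejected(self):
        cm = matrix_from_sets({"S1": {"a"}})
        cm.data = cm.data.iloc[:0]
        with pytest.raises(ValueError):
            tb.infer_tree(cm)

    def test_deterministic(self):
        sets = {"S1": {"a", "b"}, "S2": {"a", "c"}, "S3": {"a", "c", "d"}}
        e1 = tb.infer_tree(matrix_from_sets(sets))
        e2 = tb.infer_tree(matrix_from_sets(sets))
        assert e1 == e2
        assert tb.to_newick(e1) == tb.to_newick(e2)

    def test_conflict_counted_as_violation(self):
        # x and y cross: (1,1), (1,0), (0,1) all present
        cm = matrix_from_sets({"S1": {"x", "y"}, "S2": {"x"}, "S3": {"y"}})
        evo = tb.infer_tree(cm)
        assert len(evo.violations) == 1
        # the violated character is still placed (on multiple edges)
        table = tb.annotate_edges(evo, cm)
        v = evo.violations[0]
        assert (table["character"] == v).sum() >= 2
        assert table.loc[table["character"] == v, "violated"].all()


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(30))
    def test_conflict_free_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        sets = random_no_loss_instance(rng, n_nodes=int(rng.integers(3, 7)),
                                       n_chars=int(rng.integers(2, 12)))
        cm = matrix_from_sets(sets)
        grouped = tb.group_identical_samples(cm)
        evo = tb.infer_tree(grouped)
        assert evo.violations == ()
        merged_sets = {gid: set(sets[gid.split("+")[0]])
                       for gid in grouped.rows}
        assert evo.observed_clusters() == expected_clusters(merged_sets)

    @pytest.mark.parametrize("seed", range(30))
    def test_min_violations_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_groups = int(rng.integers(3, 7))
        n_chars = int(rng.integers(2, 9))
        data = pd.DataFrame(
            rng.integers(0, 2, size=(n_groups, n_chars)).astype(float),
            index=[f"g{i}" for i in range(n_groups)],
            columns=[f"c{j}" for j in range(n_chars)])
        mask = rng.random(data.shape) < 0.1
        data = data.mask(mask)
        data = data.loc[~data.isna().all(axis=1)]
        if data.empty:
            pytest.skip("degenerate draw")
        cm = tb.CharacterMatrix(
            data, {c: tb.Character(c, "SNV") for c in data.columns},
            {g: frozenset({"EC"}) for g in data.index})
        want = brute_force_min_violations(data)
        got = tb.minimum_violation_set(cm)
        assert len(got) == want
        evo = tb.infer_tree(cm)
        assert len(evo.violations) == want


class TestNewick:
    def test_single_leaf_shape(self):
        evo = tb.infer_tree(matrix_from_sets({"LEAF": {"a"}}))
        text = tb.to_newick(evo)
        assert text.startswith("(LEAF")
        assert text.rstrip(";").endswith("NORMAL[&kind=root&gains=]")

    def test_chain_nesting_depth(self):
        cm = matrix_from_sets({"S1": {"a"}, "S2": {"a", "b"},
                               "S3": {"a", "b", "c"}})
        text = tb.to_newick(tb.infer_tree(cm))
        assert text.count("(") == 3

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        sets = random_no_loss_instance(rng, n_nodes=int(rng.integers(3, 8)),
                                       n_chars=int(rng.integers(1, 10)))
        evo = tb.infer_tree(tb.group_identical_samples(matrix_from_sets(sets)))
        assert tb.parse_newick(tb.to_newick(evo)) == evo
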