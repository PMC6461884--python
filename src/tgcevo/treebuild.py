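"""Evolutionary-tree reconstruction from binary heritable characters.

Characters are SNV/SV presence and LOH events keyed by (arm, retained
haplotype); two different retained haplotypes on one arm are two distinct,
independent characters.  The model is gain-once/no-loss: every character
is acquired on exactly one edge and inherited by the whole subtree.  On a
conflict-free matrix this yields the unique perfect phylogeny rooted at
the all-zero normal genotype.  Where two sample groups have partially
non-overlapping character sets, a latent (unsampled) precursor carrying
exactly the shared set is inserted at their branch point; a latent
EC-typed precursor is additionally inserted above any differentiated
(TE/YST/META) group without an EC-typed ancestor.  Matrices incompatible
with the no-loss model are repaired by declaring a minimum number of
characters "violated" (exact search on small instances, greedy above) and
reporting them.

This is a self-contained implementation of the reconstruction procedure,
not a wrapper around any external clone-tree tool.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

GCNIS, EC, TE, YST, META, NORMAL = "GCNIS", "EC", "TE", "YST", "META", "NORMAL"
DIFFERENTIATED = frozenset({TE, YST, META})

EXACT_SEARCH_LIMIT = 12   # max conflicted characters for exhaustive repair


@dataclass
class Character:
    name: str
    kind: str                       # SNV | SV | LOH
    arm: Optional[str] = None
    retained_haplotype: Optional[str] = None
    subclonal_in: tuple = ()        # samples where detection was subclonal


@dataclass
class CharacterMatrix:
    """Samples/groups x binary characters with missing entries (NaN)."""

    data: pd.DataFrame              # values in {0.0, 1.0, NaN}
    characters: dict                # name -> Character
    labels: dict                    # row id -> frozenset of histology labels

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("character matrix entries must be 0, 1 or missing")
        all_missing = np.isnan(vals).all(axis=1) if vals.size else []
        for rid, bad in zip(self.data.index, all_missing):
            if bad:
                raise ValueError(f"row {rid!r} is entirely missing")

    @property
    def rows(self) -> list:
        return list(self.data.index)

    def carrier_set(self, char: str) -> frozenset:
        col = self.data[char]
        return frozenset(col.index[col == 1.0])

    def character_set(self, row) -> frozenset:
        r = self.data.loc[row]
        return frozenset(r.index[r == 1.0])


def build_character_matrix(marker_calls: pd.DataFrame,
                           allelic_calls: pd.DataFrame,
                           labels: Optional[dict] = None,
                           include_subclonal: bool = True,
                           mask_absent_on_loh: bool = True) -> CharacterMatrix:
    """Assemble the matrix from upstream marker and allelic call tables.

    Marker columns: PRESENT (and, unless ``include_subclonal`` is off,
    SUBCLONAL) -> 1, ABSENT -> 0, MISSING -> missing.  LOH columns are
    keyed ``LOH:<arm>:<haplotype>``; a sample is 1 where it shows that LOH
    event, 0 for any other observed state on the arm, missing where the
    arm call is missing.

    With ``mask_absent_on_loh`` (default), a marker called ABSENT in a
    sample whose arm shows LOH is recorded as missing instead of 0: the
    allele carrying an ancestral variant may itself have been lost, so
    absence there is not evidence against inheritance.
    """
    m_samples = set(marker_calls["sample"]) if len(marker_calls) else set()
    a_samples = set(allelic_calls["sample"]) if len(allelic_calls) else set()
    if m_samples and a_samples and m_samples != a_samples:
        raise ValueError("marker and allelic call tables cover different samples: "
                         f"{sorted(m_samples ^ a_samples)}")
    samples = sorted(m_samples | a_samples)
    chars: dict[str, Character] = {}
    cols: dict[str, dict] = {}

    loh_arms: set[tuple] = set()
    if mask_absent_on_loh and len(allelic_calls):
        loh_arms = {(r.sample, r.arm) for r in allelic_calls.itertuples(index=False)
                    if r.state == "LOH"}

    for r in marker_calls.itertuples(index=False):
        name = f"{r.kind}:{r.marker}"
        if name not in chars:
            chars[name] = Character(name, r.kind, arm=r.arm)
            cols[name] = {}
        if r.state == "MISSING":
            val = np.nan
        elif r.state == "ABSENT" and (r.sample, r.arm) in loh_arms:
            val = np.nan
        elif r.state == "PRESENT":
            val = 1.0
        elif r.state == "SUBCLONAL":
            val = 1.0 if include_subclonal else 0.0
            if include_subclonal:
                chars[name].subclonal_in += (r.sample,)
        else:
            val = 0.0
        cols[name][r.sample] = val

    loh = allelic_calls[(allelic_calls["state"] == "LOH")
                        & (allelic_calls["retained_haplotype"] != "undetermined")]
    for r in loh.itertuples(index=False):
        name = f"LOH:{r.arm}:{r.retained_haplotype}"
        if name not in chars:
            chars[name] = Character(name, "LOH", arm=r.arm,
                                    retained_haplotype=r.retained_haplotype)
            cols[name] = {}
    for name, ch in list(chars.items()):
        if ch.kind != "LOH":
            continue
        sub = allelic_calls[allelic_calls["arm"] == ch.arm]
        for r in sub.itertuples(index=False):
            if r.state == "MISSING":
                cols[name][r.sample] = np.nan
            elif (r.state == "LOH"
                  and r.retained_haplotype == ch.retained_haplotype):
                cols[name][r.sample] = 1.0
            else:
                cols[name][r.sample] = 0.0

    data = pd.DataFrame(index=samples, columns=sorted(cols), dtype=float)
    for name, vals in cols.items():
        for s, v in vals.items():
            data.loc[s, name] = v
    labels = labels or {}
    row_labels = {s: frozenset({labels[s]} if s in labels else ())
                  for s in samples}
    return CharacterMatrix(data, chars, row_labels)


def group_identical_samples(matrix: CharacterMatrix,
                            completeness: float = 0.9,
                            min_row_coverage: float = 0.5) -> CharacterMatrix:
    """Merge rows that agree on every mutually observed entry.

    Rows merge only when, of the less-complete row's observed entries, at
    least ``completeness`` are observed in both, and both rows observe at
    least ``min_row_coverage`` of all columns (so sparse rows are not
    merged on thin evidence).  The merged entry is the consensus over
    members (missing only where all members are missing); the group id
    concatenates the sample ids.
    """
    df = matrix.data
    ncol = max(df.shape[1], 1)
    rows = list(df.index)
    parent = {r: r for r in rows}

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    vals = {r: df.loc[r].to_numpy(dtype=float) for r in rows}
    for r1, r2 in itertools.combinations(rows, 2):
        v1, v2 = vals[r1], vals[r2]
        obs1, obs2 = ~np.isnan(v1), ~np.isnan(v2)
        both = obs1 & obs2
        if min(obs1.sum(), obs2.sum()) < min_row_coverage * ncol:
            continue
        if both.sum() < completeness * min(obs1.sum(), obs2.sum()):
            continue
        if np.array_equal(v1[both], v2[both]):
            parent[find(r2)] = find(r1)

    groups: dict[str, list] = {}
    for r in rows:
        groups.setdefault(find(r), []).append(r)

    out_rows, out_idx, out_labels = [], [], {}
    for members in groups.values():
        members = sorted(members)
        gid = "+".join(str(m) for m in members)
        stack = np.vstack([vals[m] for m in members])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            consensus = np.nanmax(stack, axis=0)  # members agree where observed
        out_rows.append(consensus)
        out_idx.append(gid)
        out_labels[gid] = frozenset().union(*(matrix.labels.get(m, frozenset())
                                              for m in members))
    data = pd.DataFrame(out_rows, index=out_idx, columns=df.columns,
                        dtype=float).sort_index()
    return CharacterMatrix(data, matrix.characters, out_labels)


# -- tree -------------------------------------------------------------------


ROOT_ID = "NORMAL"


@dataclass
class EvoTree:
    """Rooted tree over observed groups and latent precursors.

    Wraps a networkx DiGraph.  Node attributes: ``kind`` (root | observed |
    latent), ``labels`` (histology labels), ``charset``.  Edge attribute
    ``gains`` is the tuple of characters first present in the child.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    root: str = ROOT_ID
    violations: tuple = ()

    def children(self, node: str) -> list:
        return sorted(self.graph.successors(node))

    def parent(self, node: str) -> Optional[str]:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def nodes(self, kind: Optional[str] = None) -> list:
        if kind is None:
            return sorted(self.graph.nodes)
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("kind") == kind)

    def gains(self, child: str) -> tuple:
        parent = self.parent(child)
        return self.graph.edges[parent, child].get("gains", ())

    def path_union(self, node: str) -> frozenset:
        out: set = set()
        cur = node
        while cur != self.root:
            out.update(self.gains(cur))
            cur = self.parent(cur)
        return frozenset(out)

    def observed_clusters(self) -> set:
        """Non-trivial sets of observed groups below each node."""
        obs = set(self.nodes("observed"))
        clusters = set()
        for n in self.graph.nodes:
            below = frozenset(d for d in nx.descendants(self.graph, n) | {n}
                              if d in obs)
            if 0 < len(below) < len(obs):
                clusters.add(below)
        return clusters

    def ancestors_of(self, node: str) -> list:
        out, cur = [], self.parent(node)
        while cur is not None:
            out.append(cur)
            cur = self.parent(cur)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, EvoTree):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        for u, v in self.graph.edges:
            if tuple(self.graph.edges[u, v].get("gains", ())) != \
                    tuple(other.graph.edges[u, v].get("gains", ())):
                return False
        return self.root == other.root


# -- conflict repair --------------------------------------------------------


def crossing_pairs(matrix: CharacterMatrix) -> list:
    """Character pairs incompatible with a single-gain/no-loss model.

    Two characters cross when (restricted to observed entries) some group
    carries both, another only the first and a third only the second.
    """
    df = matrix.data
    chars = list(df.columns)
    pairs = []
    for c, d in itertools.combinations(chars, 2):
        x = df[c].to_numpy(dtype=float)
        y = df[d].to_numpy(dtype=float)
        obs = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[obs], y[obs]
        if ((x * y).any() and (x * (1 - y)).any() and ((1 - x) * y).any()):
            pairs.append((c, d))
    return pairs


def minimum_violation_set(matrix: CharacterMatrix,
                          exact_limit: int = EXACT_SEARCH_LIMIT) -> tuple:
    """Smallest character set whose removal leaves the matrix conflict-free.

    This is a minimum vertex cover of the crossing graph: exhaustive
    search over the conflicted characters when there are at most
    ``exact_limit`` of them, otherwise a max-degree greedy heuristic.
    Ties break lexicographically.
    """
    pairs = crossing_pairs(matrix)
    if not pairs:
        return ()
    involved = sorted({c for p in pairs for c in p})
    if len(involved) <= exact_limit:
        for k in range(1, len(involved) + 1):
            for combo in itertools.combinations(involved, k):
                removed = set(combo)
                if all(c in removed or d in removed for c, d in pairs):
                    return tuple(combo)
    # greedy vertex cover
    g = nx.Graph(pairs)
    removed = []
    while g.number_of_edges():
        node = max(g.nodes, key=lambda n: (g.degree[n], n))
        removed.append(node)
        g.remove_node(node)
    return tuple(sorted(removed))


# -- construction -----------------------------------------------------------


def _intersection_closure(sets) -> set:
    cands = {frozenset()} | set(sets)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(sorted(cands, key=sorted), 2):
            inter = a & b
            if inter not in cands:
                cands.add(inter)
                changed = True
    return cands


def _impute_missing(matrix: CharacterMatrix, group_sets: dict,
                    vset: set) -> dict:
    """Missing-tolerant deep attachment of groups.

    A group's genotype is extended by every candidate ancestral genotype
    (intersection of group character sets) containing no character the
    group observably lacks: missing entries never separate a group from a
    clade it is otherwise compatible with.  With complete data this is a
    no-op.
    """
    vals = {g: matrix.data.loc[g].to_numpy(dtype=float) for g in matrix.rows}
    cols = list(matrix.data.columns)
    zero = {g: {c for c, v in zip(cols, vals[g]) if v == 0.0} - vset
            for g in matrix.rows}
    if not any(np.isnan(v).any() for v in vals.values()):
        return group_sets
    cands = _intersection_closure(group_sets.values())
    out = {}
    for g, s in group_sets.items():
        extra: set = set()
        for cand in cands:
            if not (cand & zero[g]):
                extra |= cand
        out[g] = frozenset(s | extra)
    return out


def _latent_type(tree: nx.DiGraph, node: str, labels: dict) -> str:
    """GCNISx when every child branch reaches a GCNIS-labelled group."""
    def branch_labels(child):
        out = set()
        for d in nx.descendants(tree, child) | {child}:
            out |= set(labels.get(d, frozenset()))
        return out
    kids = list(tree.successors(node))
    if kids and all(GCNIS in branch_labels(k) for k in kids):
        return "GCNISx"
    return "ECx"


def infer_tree(matrix: CharacterMatrix,
               exact_limit: int = EXACT_SEARCH_LIMIT) -> EvoTree:
    """Reconstruct the evolutionary tree from a (grouped) character matrix.

    See the module docstring for the model.  Deterministic: all ties are
    broken lexicographically, and fewer latent nodes are always preferred
    (latent nodes arise only at genuine branch points).
    """
    if not len(matrix.data):
        raise ValueError("empty character matrix")

    violated = minimum_violation_set(matrix, exact_limit)
    vset = set(violated)

    group_sets = {g: matrix.character_set(g) - vset for g in matrix.rows}
    group_sets = _impute_missing(matrix, group_sets, vset)

    # candidate genotypes: group sets closed under intersection, plus root
    cands = _intersection_closure(group_sets.values())

    # parent = unique maximal proper subset (tie-broken deterministically)
    ordered = sorted(cands, key=lambda s: (len(s), tuple(sorted(s))))
    parent_of: dict[frozenset, frozenset] = {}
    for s in ordered:
        if not s:
            continue
        subs = [t for t in cands if t < s]
        best = max(subs, key=lambda t: (len(t), tuple(sorted(t))))
        parent_of[s] = best

    # drop latent pass-through genotypes (single child, not observed)
    observed_sets = set(group_sets.values())
    child_count: dict[frozenset, int] = {s: 0 for s in cands}
    for s, p in parent_of.items():
        child_count[p] += 1
    removable = [s for s in cands
                 if s and s not in observed_sets and child_count[s] <= 1]
    for s in removable:
        p = parent_of[s]
        for t in list(parent_of):
            if parent_of[t] == s:
                parent_of[t] = p
        cands.discard(s)

    # build the graph
    tree = nx.DiGraph()
    set_to_node: dict[frozenset, str] = {frozenset(): ROOT_ID}
    tree.add_node(ROOT_ID, kind="root", labels=frozenset({NORMAL}),
                  charset=frozenset())

    by_set: dict[frozenset, list] = {}
    for g, s in group_sets.items():
        by_set.setdefault(s, []).append(g)

    latent_sets = []
    for s in sorted(cands - {frozenset()},
                    key=lambda t: (len(t), tuple(sorted(t)))):
        if s in by_set:
            g0 = sorted(by_set[s])[0]
            set_to_node[s] = g0
            tree.add_node(g0, kind="observed", labels=matrix.labels.get(g0,
                          frozenset()), charset=s)
        else:
            latent_sets.append(s)
            set_to_node[s] = f"__latent_{len(latent_sets)}"
            tree.add_node(set_to_node[s], kind="latent", labels=frozenset(),
                          charset=s)

    for s in sorted(cands - {frozenset()},
                    key=lambda t: (len(t), tuple(sorted(t)))):
        p = parent_of[s]
        gains = tuple(sorted(s - p))
        tree.add_edge(set_to_node[p], set_to_node[s], gains=gains)

    # extra groups sharing a genotype hang off the representative; groups
    # with an empty genotype (e.g. normal controls) hang off the root
    for s, members in by_set.items():
        start = 0 if s == frozenset() else 1
        for g in sorted(members)[start:]:
            tree.add_node(g, kind="observed",
                          labels=matrix.labels.get(g, frozenset()), charset=s)
            tree.add_edge(set_to_node[s], g, gains=())

    # violated characters re-enter as (multiply) gained leaf-level events
    for c in violated:
        for g in sorted(matrix.carrier_set(c)):
            if g in tree:
                p = next(iter(tree.predecessors(g)))
                gains = tree.edges[p, g].get("gains", ())
                tree.edges[p, g]["gains"] = tuple(sorted(set(gains) | {c}))

    # name and type latent nodes (preorder numbering per type)
    label_map = {n: tree.nodes[n].get("labels", frozenset()) for n in tree}
    counters = {"GCNISx": 0, "ECx": 0}
    rename = {}
    for n in nx.dfs_preorder_nodes(tree, ROOT_ID):
        if tree.nodes[n].get("kind") == "latent":
            t = _latent_type(tree, n, label_map)
            counters[t] += 1
            rename[n] = f"{t}{counters[t]}"
    tree = nx.relabel_nodes(tree, rename)

    evo = EvoTree(tree, ROOT_ID, tuple(violated))
    _enforce_ec_ancestor(evo)
    _check_paths(evo, matrix, vset)
    return evo


def _enforce_ec_ancestor(evo: EvoTree) -> None:
    """Insert a latent ECx above differentiated groups lacking one."""
    def is_ec_typed(node: str) -> bool:
        d = evo.graph.nodes[node]
        if d.get("kind") == "latent" or node.startswith("ECx"):
            return node.startswith("ECx")
        return EC in d.get("labels", frozenset())

    n_ecx = sum(1 for n in evo.graph if n.startswith("ECx"))
    for node in list(evo.nodes("observed")):
        labels = evo.graph.nodes[node].get("labels", frozenset())
        if not (labels & DIFFERENTIATED):
            continue
        if is_ec_typed(node):
            continue
        if any(is_ec_typed(a) for a in evo.ancestors_of(node)):
            continue
        n_ecx += 1
        new = f"ECx{n_ecx}"
        parent = evo.parent(node)
        gains = evo.graph.edges[parent, node].get("gains", ())
        evo.graph.remove_edge(parent, node)
        evo.graph.add_node(new, kind="latent", labels=frozenset(),
                           charset=evo.graph.nodes[node].get("charset",
                                                             frozenset()))
        evo.graph.add_edge(parent, new, gains=gains)
        evo.graph.add_edge(new, node, gains=())


def _check_paths(evo: EvoTree, matrix: CharacterMatrix, vset: set) -> None:
    """Root-path gains must reproduce each group's observed 1-entries;
    any surplus must sit on entries that were missing (imputed), never on
    an observed 0."""
    for node in evo.nodes("observed"):
        want = matrix.character_set(node) - vset
        got = evo.path_union(node) - vset
        row = matrix.data.loc[node]
        zeros = set(row.index[row == 0.0]) - vset
        if not want <= got or (got - want) & zeros:
            raise AssertionError(
                f"internal error: path gains for {node} do not reproduce its "
                f"character set ({sorted(want ^ got)})")


def annotate_edges(evo: EvoTree, matrix: CharacterMatrix) -> pd.DataFrame:
    """Edge-gain table; also re-verifies the path-union invariant."""
    _check_paths(evo, matrix, set(evo.violations))
    rows = []
    for u, v in sorted(evo.graph.edges):
        for c in evo.graph.edges[u, v].get("gains", ()):
            ch = matrix.characters.get(c)
            rows.append((u, v, c, ch.kind if ch else "",
                         c in evo.violations))
    return pd.DataFrame(rows, columns=["parent", "child", "character",
                                       "kind", "violated"])


# -- newick -----------------------------------------------------------------


def to_newick(evo: EvoTree) -> str:
    """Newick with internal node labels and gain/kind annotations.

    Gains are carried in a bracketed comment (``[&kind=...&gains=a|b]``)
    after each node label; the string round-trips through
    ``parse_newick``.
    """
    def annot(node: str) -> str:
        kind = evo.graph.nodes[node].get("kind", "observed")
        parent = evo.parent(node)
        gains = ""
        if parent is not None:
            gains = "|".join(evo.graph.edges[parent, node].get("gains", ()))
        return f"[&kind={kind}&gains={gains}]"

    def rec(node: str) -> str:
        kids = evo.children(node)
        inner = "(" + ",".join(rec(k) for k in kids) + ")" if kids else ""
        return f"{inner}{node}{annot(node)}"

    return rec(evo.root) + ";"


def parse_newick(text: str) -> EvoTree:
    """Parse the dialect written by :func:`to_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    text = text[:-1]
    pos = 0

    def parse_node():
        nonlocal pos
        children = []
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in "(),;":
            pos += 1
        token = text[start:pos]
        name, annot = token, ""
        if "[" in token:
            name, annot = token.split("[", 1)
            annot = annot.rstrip("]")
        kind, gains = "observed", ()
        for part in annot.lstrip("&").split("&"):
            if part.startswith("kind="):
                kind = part[5:]
            elif part.startswith("gains="):
                raw = part[6:]
                gains = tuple(raw.split("|")) if raw else ()
        return {"name": name, "kind": kind, "gains": gains,
                "children": children}

    root = parse_node()
    if pos != len(text):
        raise ValueError(f"trailing characters in newick at offset {pos}")

    g = nx.DiGraph()

    def build(node, parent):
        g.add_node(node["name"], kind=node["kind"], labels=frozenset(),
                   charset=frozenset())
        if parent is not None:
            g.add_edge(parent, node["name"], gains=node["gains"])
        for ch in node["children"]:
            build(ch, node["name"])

    build(root, None)
    # recover charsets from path unions
    evo = EvoTree(g, root["name"])
    for n in g.nodes:
        g.nodes[n]["charset"] = evo.path_union(n)
    return evo
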