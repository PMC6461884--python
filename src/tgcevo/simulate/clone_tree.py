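"""Clone trees and arm-level genome evolution.

The developmental model is WGD-first: a normal diploid root founds a
genome-doubled in-situ (GCNIS) lineage; one of its descendants gains extra
12p copies and becomes the invasive stem-cell precursor (EC); teratoma,
yolk-sac and metastatic clones descend from EC-labelled ancestors only.
GCNIS-labelled clones never gain 12p.  Subsequent copy-number evolution is
arm-level, one haplotype copy at a time, with losses predominating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from tgcevo.arms import ARM_12P
from tgcevo.config import SimConfig

NORMAL, GCNIS, EC, TE, YST, META, LATENT = (
    "NORMAL", "GCNIS", "EC", "TE", "YST", "META", "LATENT")

#: labels that require an EC-typed ancestor
DIFFERENTIATED = frozenset({TE, YST, META})


@dataclass
class Clone:
    id: str
    parent_id: Optional[str]
    label: str
    # arm -> [nA, nB] copies of parental haplotypes
    cn_profile: dict = field(default_factory=dict)
    wgd: bool = False                   # genome has been doubled in this clone
    markers: dict = field(default_factory=dict)  # marker id -> multiplicity

    def total_cn(self, arm: str) -> int:
        nA, nB = self.cn_profile[arm]
        return nA + nB


@dataclass
class GenomeEvent:
    """One entry of the copy-number event log."""
    child_id: str                       # edge identified by its child clone
    kind: str                           # WGD | LOSS | GAIN | GAIN_12P | SKIPPED
    arm: Optional[str] = None
    haplotype: Optional[int] = None     # 0 = A, 1 = B


class CloneTree:
    """Rooted tree of clones; the root is the diploid NORMAL clone."""

    def __init__(self) -> None:
        self.clones: dict[str, Clone] = {}
        self.root_id: Optional[str] = None
        self.events: list[GenomeEvent] = []
        self.wgd_edge: Optional[str] = None   # child id of the WGD edge

    def add(self, clone: Clone) -> None:
        if clone.id in self.clones:
            raise ValueError(f"duplicate clone id {clone.id}")
        if clone.parent_id is None:
            if self.root_id is not None:
                raise ValueError("tree already has a root")
            self.root_id = clone.id
        elif clone.parent_id not in self.clones:
            raise ValueError(f"unknown parent {clone.parent_id}")
        self.clones[clone.id] = clone

    def __getitem__(self, cid: str) -> Clone:
        return self.clones[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.clones

    def children(self, cid: str) -> list[str]:
        return [c.id for c in self.clones.values() if c.parent_id == cid]

    def preorder(self) -> Iterator[str]:
        stack = [self.root_id]
        while stack:
            cid = stack.pop()
            yield cid
            stack.extend(sorted(self.children(cid), reverse=True))

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs in preorder of the child."""
        return [(self.clones[c].parent_id, c) for c in self.preorder()
                if self.clones[c].parent_id is not None]

    def ancestors(self, cid: str) -> list[str]:
        """Ancestor ids from parent up to the root."""
        out = []
        cur = self.clones[cid].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.clones[cur].parent_id
        return out

    def subtree(self, cid: str) -> set[str]:
        out, stack = set(), [cid]
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self.children(c))
        return out

    def labels(self) -> dict[str, str]:
        return {cid: c.label for cid, c in self.clones.items()}

    def to_newick(self) -> str:
        def rec(cid: str) -> str:
            kids = sorted(self.children(cid))
            if not kids:
                return cid
            return "(" + ",".join(rec(k) for k in kids) + ")" + cid
        return rec(self.root_id) + ";"

    def check_invariants(self) -> None:
        root = self.clones[self.root_id]
        if root.label != NORMAL or root.markers:
            raise AssertionError("root must be an unmutated NORMAL clone")
        for arm, (a, b) in root.cn_profile.items():
            if (a, b) != (1, 1):
                raise AssertionError(f"root must be (1,1) on {arm}")
        for clone in self.clones.values():
            for arm, (a, b) in clone.cn_profile.items():
                if a < 0 or b < 0:
                    raise AssertionError(f"negative copy number on {arm} in {clone.id}")
            for mid, mult in clone.markers.items():
                pass  # per-arm bound checked by the caller with marker defs
            if clone.label == GCNIS:
                base = (2, 2) if clone.wgd else (1, 1)
                if clone.total_cn(ARM_12P) > sum(base):
                    raise AssertionError(f"GCNIS clone {clone.id} carries a 12p gain")
            if clone.label in DIFFERENTIATED:
                if not any(self.clones[a].label == EC for a in self.ancestors(clone.id)):
                    raise AssertionError(f"{clone.label} clone {clone.id} lacks an EC ancestor")


# ---------------------------------------------------------------------------


def _build_skeleton(config: SimConfig, rng: np.random.Generator) -> CloneTree:
    """Topology and labels only; every clone diploid (1,1), no events."""
    arms = list(config.arm_table)
    diploid = lambda: {a: [1, 1] for a in arms}

    tree = CloneTree()
    tree.add(Clone("N", None, NORMAL, diploid()))
    tree.add(Clone("C1", "N", GCNIS, diploid()))       # genome-doubled founder
    tree.add(Clone("C2", "C1", EC, diploid()))         # invasive precursor, 12p gain
    next_idx = 3
    if config.n_clones >= 4:
        tree.add(Clone("C3", "C1", GCNIS, diploid()))  # dormant in-situ branch
        next_idx = 4
    labels = [TE, YST, EC, META]
    probs = np.array([0.3, 0.3, 0.25, 0.15])
    while next_idx <= config.n_clones:
        ec_nodes = [cid for cid, c in tree.clones.items() if c.label == EC]
        parent = ec_nodes[int(rng.integers(len(ec_nodes)))]
        label = labels[int(rng.choice(len(labels), p=probs))]
        tree.add(Clone(f"C{next_idx}", parent, label, diploid()))
        next_idx += 1
    return tree


def apply_genome_events(tree: CloneTree, config: SimConfig,
                        rng: np.random.Generator,
                        max_retries: int = 10) -> CloneTree:
    """Apply WGD and arm-level copy-number events along the tree edges.

    The WGD doubles both haplotypes on the edge founding the doubled
    lineage (edge into ``C1``).  Every edge then receives a Poisson number
    of +/-1-copy arm events; an event is a loss with probability
    ``loss_gain_ratio``.  12p is excluded from random events: the invasive
    founder edge (into ``C2``) gains ``n_12p_gain`` copies explicitly and
    in-situ clones keep the post-WGD baseline.  Events that would drop an
    arm below two total copies or exceed ``max_copies`` per haplotype are resampled and
    eventually skipped (logged).  Mutates and returns *tree*; the event log
    is on ``tree.events``.
    """
    arms = [a for a in config.arm_table if a != ARM_12P]

    for parent_id, child_id in tree.edges():
        clone = tree[child_id]
        parent = tree[parent_id]
        # inherit parent genome
        clone.cn_profile = {a: list(cn) for a, cn in parent.cn_profile.items()}
        clone.wgd = parent.wgd

        if child_id == "C1":  # WGD on the edge founding the doubled lineage
            for a in clone.cn_profile:
                clone.cn_profile[a] = [2 * clone.cn_profile[a][0],
                                       2 * clone.cn_profile[a][1]]
            clone.wgd = True
            tree.wgd_edge = child_id
            tree.events.append(GenomeEvent(child_id, "WGD"))

        if child_id == "C2":  # invasive founder gains 12p
            hap = int(rng.integers(2))
            clone.cn_profile[ARM_12P][hap] += config.n_12p_gain
            tree.events.append(GenomeEvent(child_id, "GAIN_12P", ARM_12P, hap))

        n_events = int(rng.poisson(config.cna_per_edge))
        for _ in range(n_events):
            done = False
            for _attempt in range(max_retries):
                is_loss = rng.random() < config.loss_gain_ratio
                if is_loss and rng.random() < config.loh_bias:
                    # atomic LOH: eliminate the whole minority haplotype of
                    # one arm on this edge (>= 2 copies must remain)
                    elig = [a for a in arms
                            if min(clone.cn_profile[a]) >= 1
                            and sum(clone.cn_profile[a])
                            - min(clone.cn_profile[a]) >= 2]
                    if elig:
                        arm = elig[int(rng.integers(len(elig)))]
                        cn = clone.cn_profile[arm]
                        hap = (int(rng.integers(2)) if cn[0] == cn[1]
                               else int(cn[1] < cn[0]))
                        for _k in range(cn[hap]):
                            tree.events.append(
                                GenomeEvent(child_id, "LOSS", arm, hap))
                        cn[hap] = 0
                        done = True
                        break
                arm = arms[int(rng.integers(len(arms)))]
                cn = clone.cn_profile[arm]
                if is_loss:
                    present = [h for h in (0, 1) if cn[h] > 0]
                    hap = present[int(rng.integers(len(present)))]
                    if sum(cn) - 1 < 2:
                        continue  # keep >= 2 total copies per arm; resample
                    cn[hap] -= 1
                    tree.events.append(GenomeEvent(child_id, "LOSS", arm, hap))
                else:
                    ok = [h for h in (0, 1) if 0 < cn[h] < config.max_copies]
                    if not ok:
                        continue
                    hap = ok[int(rng.integers(len(ok)))]
                    cn[hap] += 1
                    tree.events.append(GenomeEvent(child_id, "GAIN", arm, hap))
                done = True
                break
            if not done:
                tree.events.append(GenomeEvent(child_id, "SKIPPED"))
    tree.check_invariants()
    return tree


def simulate_clone_tree(config: SimConfig, seed: Optional[int] = None) -> CloneTree:
    """Simulate a labelled clone tree with genome events applied.

    Deterministic for a fixed seed (defaults to ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree = _build_skeleton(config, rng)
    return apply_genome_events(tree, config, rng)


def edge_event_counts(tree: CloneTree) -> dict[str, int]:
    """Number of copy-number events (excl. WGD/SKIPPED) per edge child id."""
    counts = {c: 0 for c in tree.clones if c != tree.root_id}
    for ev in tree.events:
        if ev.kind in ("LOSS", "GAIN", "GAIN_12P"):
            counts[ev.child_id] += 1
    return counts
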