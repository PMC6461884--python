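"""End-to-end recovery experiments on simulated data.

Shared between the test suite and the acceptance report: each function
simulates with a seeded generator, runs the analysis modules, and scores
the result against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tgcevo import variants
from tgcevo.config import SimConfig
from tgcevo.report import build_tree_from_calls, pipeline_calls, truth_cn_purity
from tgcevo.simulate.clone_tree import CloneTree
from tgcevo.simulate.io import SimResult, simulate_all


# -- WGD-timing recovery ----------------------------------------------------


def timing_trial(seed: int, depth: int = 10_000, snv_rate: float = 0.1,
                 frac_pre_wgd: float = 0.15) -> tuple[int, int]:
    """(correct, total) timing classifications on pure, deep samples.

    Samples are pure (purity 1) single-clone preparations at high depth;
    classification uses the truth copy number of the sampled clone's arm.
    Truth timing is the marker's placement timing; a marker whose mutated
    copies were later lost or gained is still scored against it.
    """
    config = SimConfig(n_clones=6, n_samples=6, snv_rate=snv_rate,
                       frac_pre_wgd=frac_pre_wgd, purity_range=(1.0, 1.0),
                       depth_median=depth, depth_sigma=0.0, cna_per_edge=1.0,
                       seed=seed).validate()
    result = simulate_all(config)
    truth = {m.id: m.timing for m in result.markers if m.kind == "SNV"}
    calls = variants.call_markers(result.counts,
                                  cn_purity=truth_cn_purity(result))
    correct = total = 0
    carrier = {c.sample_id: c.major_clone() for c in result.samples}
    for r in calls.itertuples(index=False):
        if r.kind != "SNV" or not r.timing:
            continue
        clone = result.tree[carrier[r.sample]]
        mult = clone.markers.get(r.marker, 0)
        if mult == 0:
            continue  # marker not carried by this sample's clone
        total += 1
        if r.timing == truth[r.marker]:
            correct += 1
    return correct, total


def timing_recovery(n_seeds: int = 20, seed0: int = 0, **kw) -> float:
    """Pooled fraction of correct PRE/POST-WGD calls over seeds."""
    correct = total = 0
    for s in range(seed0, seed0 + n_seeds):
        c, t = timing_trial(s, **kw)
        correct += c
        total += t
    return correct / total if total else float("nan")


def vaf_by_timing(seed: int = 0, depth: int = 10_000) -> pd.DataFrame:
    """Observed VAFs with truth timing and arm copy number, pure samples."""
    config = SimConfig(n_clones=6, n_samples=6, snv_rate=0.1,
                       frac_pre_wgd=0.15, purity_range=(1.0, 1.0),
                       depth_median=depth, depth_sigma=0.0, cna_per_edge=1.0,
                       seed=seed).validate()
    result = simulate_all(config)
    truth = {m.id: m for m in result.markers}
    carrier = {c.sample_id: c.major_clone() for c in result.samples}
    vafs = variants.marker_vaf_table(result.counts)
    rows = []
    for r in vafs.itertuples(index=False):
        if r.kind != "SNV" or pd.isna(r.vaf):
            continue
        clone = result.tree[carrier[r.sample]]
        m = truth[r.marker]
        rows.append((r.sample, r.marker, m.timing, clone.total_cn(m.arm),
                     clone.markers.get(r.marker, 0), float(r.vaf)))
    return pd.DataFrame(rows, columns=["sample", "marker", "timing",
                                       "total_cn", "multiplicity", "vaf"])


# -- tree recovery ----------------------------------------------------------


def tree_recovery_config(seed: int) -> SimConfig:
    """Standard tree-recovery scenario: 6 clones, the invasive founder C2
    left unsampled, 8 samples at depth 500 and purity >= 0.7."""
    return SimConfig(
        n_clones=6, n_samples=8, snv_rate=0.05, frac_pre_wgd=0.1,
        cna_per_edge=3.0, loh_bias=0.35, purity_range=(0.7, 1.0),
        depth_median=500, n_svs=2,
        sampled_clones=("C1", "C3", "C4", "C5", "C6"),
        seed=seed).validate()


def true_sample_clusters(tree: CloneTree, sample_clones: dict) -> set:
    """Non-trivial clusters of sample groups induced by the true clone tree.

    *sample_clones* maps sample id -> clone id; samples of the same clone
    form one group, named like the analysis groups (sorted ids joined
    with '+').
    """
    by_clone: dict[str, list] = {}
    for sid, cid in sample_clones.items():
        by_clone.setdefault(cid, []).append(sid)
    group_of = {cid: "+".join(sorted(sids)) for cid, sids in by_clone.items()}
    all_groups = frozenset(group_of.values())
    clusters = set()
    for cid in tree.preorder():
        below = frozenset(group_of[c] for c in tree.subtree(cid)
                          if c in group_of)
        if 0 < len(below) < len(all_groups):
            clusters.add(below)
    return clusters


@dataclass
class TreeTrial:
    seed: int
    n_markers: int
    n_loh_truth: int
    topology_match: bool
    latent_expected: bool
    latent_inserted: bool
    n_violations: int


def truth_loh_events(result: SimResult) -> set:
    """(arm, retained haplotype) LOH states present in any sampled clone."""
    out = set()
    sampled = {c.major_clone() for c in result.samples}
    for cid in sampled:
        clone = result.tree[cid]
        for arm, (a, b) in clone.cn_profile.items():
            if a == 0 and b > 0:
                out.add((arm, "B"))
            elif b == 0 and a > 0:
                out.add((arm, "A"))
    return out


def _unsampled_branch_ancestors(result: SimResult) -> set:
    """Unsampled clones that are branch points between sampled lineages
    with private descendant events on >= 2 sides."""
    tree = result.tree
    sampled = {c.major_clone() for c in result.samples}
    out = set()
    for cid in tree.preorder():
        if cid in sampled or cid == tree.root_id:
            continue
        kids = tree.children(cid)
        sides = sum(1 for k in kids if tree.subtree(k) & sampled)
        if sides >= 2:
            out.add(cid)
    return out


def tree_trial(seed: int) -> TreeTrial:
    config = tree_recovery_config(seed)
    result = simulate_all(config)
    allelic_df, marker_df = pipeline_calls(result)
    labels = {c.sample_id: c.histology for c in result.samples}
    grouped, evo = build_tree_from_calls(allelic_df, marker_df, labels)

    sample_clones = {c.sample_id: c.major_clone() for c in result.samples}
    truth_clusters = true_sample_clusters(result.tree, sample_clones)
    inferred_clusters = evo.observed_clusters()

    latent_expected = bool(_unsampled_branch_ancestors(result))
    latent_inserted = bool(evo.nodes("latent"))
    return TreeTrial(
        seed=seed,
        n_markers=len(result.markers),
        n_loh_truth=len(truth_loh_events(result)),
        topology_match=(truth_clusters == inferred_clusters),
        latent_expected=latent_expected,
        latent_inserted=latent_inserted,
        n_violations=len(evo.violations),
    )


def tree_recovery(n_seeds: int = 50, seed0: int = 0) -> list:
    return [tree_trial(s) for s in range(seed0, seed0 + n_seeds)]
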