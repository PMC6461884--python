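"""Truth-file output and the one-call simulation entry point."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tgcevo.arms import ordered_arms, split_arm
from tgcevo.config import SimConfig
from tgcevo.simulate.clone_tree import CloneTree, simulate_clone_tree
from tgcevo.simulate.mutations import place_mutations
from tgcevo.simulate.panel import AmpliconPanel, build_panel
from tgcevo.simulate.readcounts import generate_read_counts
from tgcevo.simulate.samples import compose_samples


@dataclass
class SimResult:
    config: SimConfig
    tree: CloneTree
    markers: list
    samples: list
    panel: AmpliconPanel
    counts: pd.DataFrame


def simulate_all(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run the full generator: tree, events, mutations, samples, counts.

    A single seeded generator drives every stage, so a fixed (config, seed)
    pair gives bit-identical truth and count tables.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tree = simulate_clone_tree(config, seed)
    # tree consumed part of an identically-seeded stream; continue with a
    # stage-specific child stream for the rest
    rng = np.random.default_rng([seed, 1])
    tree, markers = place_mutations(tree, config, rng)
    samples = compose_samples(tree, config, np.random.default_rng([seed, 2]))
    panel = build_panel(markers, config, np.random.default_rng([seed, 3]))
    counts = generate_read_counts(panel, samples, tree, config,
                                  np.random.default_rng([seed, 4]),
                                  markers=markers)
    return SimResult(config, tree, markers, samples, panel, counts)


# -- truth tables -----------------------------------------------------------


def clone_table(result: SimResult) -> pd.DataFrame:
    rows = []
    arms = ordered_arms(result.config.arm_table)
    for cid in result.tree.preorder():
        clone = result.tree[cid]
        cn = ";".join(f"{a}={clone.cn_profile[a][0]}|{clone.cn_profile[a][1]}"
                      for a in arms)
        rows.append((cid, clone.parent_id or "", clone.label,
                     int(clone.wgd), cn))
    return pd.DataFrame(rows, columns=["clone", "parent", "label", "wgd",
                                       "cn_profile"])


def marker_table(result: SimResult) -> pd.DataFrame:
    """VCF-like truth table for markers (one row per marker)."""
    rows = []
    for m in result.markers:
        chrom, _ = split_arm(m.arm)
        carriers = ";".join(
            f"{cid}:{result.tree[cid].markers[m.id]}"
            for cid in result.tree.preorder()
            if m.id in result.tree[cid].markers)
        info = (f"KIND={m.kind};ARM={m.arm};TIMING={m.timing};"
                f"ORIGIN={m.origin_edge};CARRIERS={carriers}")
        if m.context_class:
            info += f";CONTEXT={m.context_class}"
        rows.append((chrom, m.arm, m.position, m.id, "N", "V", info))
    return pd.DataFrame(rows, columns=["CHROM", "ARM", "POS", "ID", "REF",
                                       "ALT", "INFO"])


def composition_table(result: SimResult) -> pd.DataFrame:
    rows = []
    for comp in result.samples:
        mix = ";".join(f"{cid}:{frac:.6g}"
                       for cid, frac in sorted(comp.clone_fractions.items()))
        rows.append((comp.sample_id, comp.histology, mix,
                     round(comp.normal_fraction, 6)))
    return pd.DataFrame(rows, columns=["sample", "histology",
                                       "clone_fractions", "normal_fraction"])


def panel_table(result: SimResult) -> pd.DataFrame:
    rows = []
    for amp in result.panel:
        for s in amp.snps:
            rows.append((amp.id, amp.arm, amp.start, amp.end, s.id,
                         s.position, "SNP", ""))
        if amp.marker_id:
            rows.append((amp.id, amp.arm, amp.start, amp.end,
                         f"{amp.id}_v", amp.position, "MARKER", amp.marker_id))
    return pd.DataFrame(rows, columns=["amplicon", "arm", "start", "end",
                                       "locus", "position", "locus_type",
                                       "marker"])


def write_truth(result: SimResult, outdir: str) -> dict:
    """Write all truth/count tables; returns {name: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    _write("truth_clones.tsv", clone_table(result))
    _write("truth_markers.tsv", marker_table(result))
    _write("truth_samples.tsv", composition_table(result))
    _write("panel.tsv", panel_table(result))
    _write("counts.tsv", result.counts)
    nwk = os.path.join(outdir, "truth_tree.nwk")
    with open(nwk, "w") as fh:
        fh.write(result.tree.to_newick() + "\n")
    paths["truth_tree.nwk"] = nwk
    return paths
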