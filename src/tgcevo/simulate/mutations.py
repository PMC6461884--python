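"""Somatic marker placement (SNVs and SVs) on a clone tree.

SNVs arrive as a Poisson process over the genome with density ``snv_rate``
per Mb.  A configurable small fraction is placed before genome doubling
(on the WGD edge) and therefore carries multiplicity 2 — both copies of
the mutated haplotype carry the variant — while post-WGD SNVs sit on a
single copy of one haplotype.  Multiplicities are propagated through
downstream arm losses/gains copy-by-copy, so a later loss may remove the
mutated copy.  A wild-type copy is always retained at placement time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from tgcevo.config import SimConfig
from tgcevo.signatures import CONTEXTS_96, load_fixture_signatures
from tgcevo.simulate.clone_tree import CloneTree, edge_event_counts

PRE_WGD, POST_WGD = "PRE_WGD", "POST_WGD"


@dataclass
class MarkerDef:
    id: str
    kind: str                     # SNV | SV
    arm: str
    position: int                 # 1-based within arm
    origin_edge: str              # child clone id of the edge where gained
    timing: str                   # PRE_WGD | POST_WGD
    haplotype: Optional[int] = None       # 0=A, 1=B (SNV only)
    context_class: Optional[str] = None   # one of the 96 classes (SNV only)


def _draw_context(rng: np.random.Generator, probs: np.ndarray) -> str:
    return CONTEXTS_96[int(rng.choice(len(CONTEXTS_96), p=probs))]


def _context_probs(config: SimConfig) -> np.ndarray:
    sigs, _ = load_fixture_signatures()
    mix = np.asarray(config.signature_mix, dtype=float)
    if mix.shape[0] != sigs.shape[1]:
        raise ValueError(
            f"signature_mix has {mix.shape[0]} weights for {sigs.shape[1]} signatures")
    mix = mix / mix.sum()
    p = sigs @ mix
    return p / p.sum()


def _propagate(tree: CloneTree, marker_id: str, arm: str, hap: int,
               origin: str, mult0: int, rng: np.random.Generator) -> None:
    """Write per-clone multiplicities for one SNV, following copy losses/gains.

    Losses remove an unmutated copy of the haplotype while one exists, so a
    variant disappears from a lineage only when its haplotype is eliminated
    entirely (the LOH case).  A gain duplicates a mutated copy with
    probability m/n.
    """
    # events per edge in log order, restricted to (arm, hap)
    per_edge: dict[str, list[str]] = {}
    for ev in tree.events:
        if ev.arm == arm and ev.haplotype == hap and ev.kind in ("LOSS", "GAIN", "GAIN_12P"):
            per_edge.setdefault(ev.child_id, []).append(ev.kind)

    def hap_copies(cid: str) -> int:
        return tree[cid].cn_profile[arm][hap]

    def rec(cid: str, mult: int) -> None:
        if mult > 0:
            tree[cid].markers[marker_id] = mult
        for child in tree.children(cid):
            m = mult
            n = hap_copies(cid)
            for kind in per_edge.get(child, []):
                if kind == "LOSS":
                    if n <= m:
                        m -= 1
                    n -= 1
                else:
                    if n > 0 and rng.random() < m / n:
                        m += 1
                    n += 1
            rec(child, m)

    rec(origin, mult0)


def place_mutations(tree: CloneTree, config: SimConfig,
                    rng: np.random.Generator) -> tuple[CloneTree, list[MarkerDef]]:
    """Place SNV and SV markers on the edges of *tree*.

    Returns the tree (clone ``markers`` dicts filled in) and the marker
    definitions.  Expected SNV count is ``snv_rate * genome_Mb``, split
    ``frac_pre_wgd`` : ``1 - frac_pre_wgd`` between the pre-doubling part of
    the WGD edge and all edges in proportion to 1 + their CNA event count.
    """
    arms = list(config.arm_table)
    lengths = np.array([config.arm_table[a] for a in arms], dtype=float)
    arm_probs = lengths / lengths.sum()
    genome_mb = lengths.sum()
    ctx_probs = _context_probs(config)

    ev_counts = edge_event_counts(tree)
    edge_ids = sorted(ev_counts)
    weights = np.array([1.0 + ev_counts[e] for e in edge_ids])
    weights = weights / weights.sum()

    lam = config.snv_rate * genome_mb
    n_pre = int(rng.poisson(config.frac_pre_wgd * lam)) if tree.wgd_edge else 0
    n_post_total = int(rng.poisson((1.0 - config.frac_pre_wgd) * lam))
    post_edges = list(rng.choice(len(edge_ids), size=n_post_total, p=weights))

    markers: list[MarkerDef] = []
    counter = 0

    def place_snv(edge: str, timing: str) -> None:
        nonlocal counter
        clone = tree[edge]
        mult0 = 2 if timing == PRE_WGD else 1
        for _ in range(50):
            arm = arms[int(rng.choice(len(arms), p=arm_probs))]
            nA, nB = clone.cn_profile[arm]
            total = nA + nB
            if total < mult0 + 1:   # always retain a wild-type copy
                continue
            haps = [h for h in (0, 1) if clone.cn_profile[arm][h] >= mult0]
            if not haps:
                continue
            hap = haps[int(rng.integers(len(haps)))]
            counter += 1
            mid = f"M{counter:04d}"
            pos = int(rng.integers(1, int(config.arm_table[arm] * 1e6)) + 1)
            markers.append(MarkerDef(mid, "SNV", arm, pos, edge, timing,
                                     haplotype=hap,
                                     context_class=_draw_context(rng, ctx_probs)))
            _propagate(tree, mid, arm, hap, edge, mult0, rng)
            return
        # genome saturated on every arm tried; drop the mutation silently

    for _ in range(n_pre):
        place_snv(tree.wgd_edge, PRE_WGD)
    for idx in post_edges:
        place_snv(edge_ids[int(idx)], POST_WGD)

    # SVs: binary presence markers inherited by the whole subtree
    for k in range(config.n_svs):
        edge = edge_ids[int(rng.choice(len(edge_ids), p=weights))]
        arm = arms[int(rng.choice(len(arms), p=arm_probs))]
        pos = int(rng.integers(1, int(config.arm_table[arm] * 1e6)) + 1)
        timing = PRE_WGD if edge == tree.wgd_edge and rng.random() < config.frac_pre_wgd \
            else POST_WGD
        mid = f"SV{k + 1:02d}"
        markers.append(MarkerDef(mid, "SV", arm, pos, edge, timing))
        for cid in tree.subtree(edge):
            tree[cid].markers[mid] = 1

    # multiplicity can never exceed the arm copy number
    defs = {m.id: m for m in markers}
    for clone in tree.clones.values():
        for mid, mult in clone.markers.items():
            if defs[mid].kind == "SNV":
                assert mult <= clone.total_cn(defs[mid].arm)
    return tree, markers
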