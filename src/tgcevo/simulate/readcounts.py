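"""Read-count generation for the amplicon panel.

Per sample and locus the expected allele fraction follows from the clone
mixture and allele-specific copy numbers (closed forms shared with the
profiling/calling modules); sequencing depth is log-normal around the
configured median (floored), and counts are binomial, or beta-binomial
when an overdispersion rho > 0 is set.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from tgcevo.config import SimConfig
from tgcevo.simulate.clone_tree import CloneTree
from tgcevo.simulate.panel import AmpliconPanel
from tgcevo.simulate.samples import SampleComposition

COUNT_COLUMNS = ["sample", "replicate", "locus", "amplicon", "arm", "position",
                 "locus_type", "marker", "countA", "countB"]


def expected_locus_fraction(tree: CloneTree, comp: SampleComposition,
                            arm: str, marker=None) -> float:
    """Expected B-allele (SNP) or variant-read (marker) fraction.

    SNP loci: sum of haplotype-B copies over sum of total copies, weighting
    clones by their mixture fraction (normal cells contribute (1,1)).
    SNV markers: mutated copies over total copies, normal contributing 2
    wild-type copies.  SV markers: half the carrying-clone fraction.
    """
    f_n = comp.normal_fraction
    if marker is not None and marker.kind == "SV":
        carried = sum(f for cid, f in comp.clone_fractions.items()
                      if marker.id in tree[cid].markers)
        return 0.5 * carried
    tot = 2.0 * f_n
    num = 1.0 * f_n if marker is None else 0.0
    for cid, f in comp.clone_fractions.items():
        nA, nB = tree[cid].cn_profile[arm]
        tot += f * (nA + nB)
        if marker is None:
            num += f * nB
        else:
            num += f * tree[cid].markers.get(marker.id, 0)
    if tot <= 0:
        raise ValueError(f"zero total copy number on {arm}")
    return num / tot


def _draw_counts(rng: np.random.Generator, depth: int, p: float,
                 rho: float) -> int:
    p = min(max(p, 0.0), 1.0)
    if rho <= 0 or p in (0.0, 1.0):
        return int(rng.binomial(depth, p))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return int(rng.binomial(depth, rng.beta(a, b)))


def generate_read_counts(panel: AmpliconPanel, samples: list,
                         tree: CloneTree, config: SimConfig,
                         rng: np.random.Generator,
                         markers: Optional[list] = None) -> pd.DataFrame:
    """Simulate the (sample x locus) allele read-count table.

    For SNP loci ``countA``/``countB`` are haplotype-A/B reads; for marker
    loci they are reference/variant reads.  Deterministic for a fixed rng
    state.  Loci dropped out (prob. ``dropout_rate``) get zero depth.
    """
    marker_defs = {m.id: m for m in (markers or [])}
    rows = []
    for comp in samples:
        for rep in range(1, config.replicates + 1):
            for amp in panel:
                loci = ([(s.id, "SNP", None, s.position) for s in amp.snps]
                        if amp.marker_id is None
                        else [(f"{amp.id}_v", None, amp.marker_id, amp.position)])
                for locus_id, ltype, marker_id, pos in loci:
                    marker = marker_defs.get(marker_id) if marker_id else None
                    if marker_id and marker is None:
                        raise ValueError(f"panel references unknown marker {marker_id}")
                    if ltype is None:
                        ltype = marker.kind
                    p = expected_locus_fraction(tree, comp, amp.arm, marker)
                    if rng.random() < config.dropout_rate:
                        depth = 0
                    else:
                        depth = max(config.min_depth,
                                    int(round(rng.lognormal(np.log(config.depth_median),
                                                            config.depth_sigma))))
                    cb = _draw_counts(rng, depth, p, config.overdispersion)
                    rows.append((comp.sample_id, f"r{rep}", locus_id, amp.id,
                                 amp.arm, pos, ltype, marker_id or "",
                                 depth - cb, cb))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
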