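"""Sample composition: clone mixtures with normal-cell contamination."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from tgcevo.config import SimConfig
from tgcevo.simulate.clone_tree import CloneTree, DIFFERENTIATED, EC, GCNIS


@dataclass
class SampleComposition:
    sample_id: str
    histology: str
    clone_fractions: dict = field(default_factory=dict)  # clone id -> fraction
    normal_fraction: float = 0.0

    @property
    def purity(self) -> float:
        return 1.0 - self.normal_fraction

    def major_clone(self) -> str:
        return max(self.clone_fractions, key=lambda c: (self.clone_fractions[c], c))

    def check(self) -> None:
        fracs = list(self.clone_fractions.values()) + [self.normal_fraction]
        if any(f < 0 for f in fracs):
            raise ValueError(f"negative fraction in sample {self.sample_id}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions of sample {self.sample_id} do not sum to 1")


def compose_samples(tree: CloneTree, config: SimConfig,
                    rng: np.random.Generator) -> list[SampleComposition]:
    """Build ``n_samples`` sample mixtures from the clone tree.

    Clones are taken from ``config.sampled_clones`` if given (cycled to
    ``n_samples``; replicate samples of the same clone exercise grouping
    downstream), else from ``config.sample_histologies`` (one sample per
    requested label; error if a label is absent from the tree), else by
    cycling over all non-normal clones.  Each sample mixes one clone with
    normal cells at a purity drawn from ``purity_range``; GCNIS samples
    may additionally carry a small admixture of a progressed (EC-lineage)
    clone, modelling polyclonal in-situ disease.
    """
    non_root = [cid for cid in tree.preorder() if cid != tree.root_id]
    labels = tree.labels()

    if config.sampled_clones is not None:
        for cid in config.sampled_clones:
            if cid not in tree:
                raise ValueError(f"sampled clone {cid!r} not in tree")
        picks = [config.sampled_clones[i % len(config.sampled_clones)]
                 for i in range(config.n_samples)]
    elif config.sample_histologies is not None:
        picks = []
        for lab in config.sample_histologies:
            cands = [cid for cid in non_root if labels[cid] == lab]
            if not cands:
                raise ValueError(f"no clone with histology label {lab!r} in tree")
            picks.append(cands[int(rng.integers(len(cands)))])
    else:
        picks = [non_root[i % len(non_root)] for i in range(config.n_samples)]

    progressed = [cid for cid in non_root
                  if labels[cid] == EC or labels[cid] in DIFFERENTIATED]

    samples = []
    for i, cid in enumerate(picks):
        lo, hi = config.purity_range
        purity = float(rng.uniform(lo, hi))
        fractions = {cid: purity}
        if (labels[cid] == GCNIS and config.gcnis_admixture > 0 and progressed):
            admix = min(config.gcnis_admixture, purity)
            other = progressed[int(rng.integers(len(progressed)))]
            fractions[cid] = purity - admix
            fractions[other] = fractions.get(other, 0.0) + admix
        comp = SampleComposition(
            sample_id=f"S{i + 1:02d}",
            histology=labels[cid],
            clone_fractions=fractions,
            normal_fraction=1.0 - purity,
        )
        comp.check()
        samples.append(comp)
    return samples
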