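"""Amplicon panel construction.

The panel mimics a targeted design: every arm carries SNP amplicons with
phased germline heterozygous SNPs (haplotype A vs B alleles), and every
simulated tumour marker gets its own amplicon covering the variant locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tgcevo.arms import ordered_arms
from tgcevo.config import SimConfig


@dataclass
class SnpLocus:
    id: str
    position: int      # 1-based within arm


@dataclass
class Amplicon:
    id: str
    arm: str
    start: int
    end: int
    snps: list = field(default_factory=list)      # list[SnpLocus]
    marker_id: Optional[str] = None

    @property
    def position(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class AmpliconPanel:
    amplicons: list

    def __iter__(self):
        return iter(self.amplicons)

    def snp_loci(self) -> list[tuple]:
        """(locus id, amplicon) pairs for all SNP loci."""
        return [(s.id, a) for a in self.amplicons for s in a.snps]

    def by_id(self) -> dict:
        return {a.id: a for a in self.amplicons}


def build_panel(markers: list, config: SimConfig,
                rng: np.random.Generator) -> AmpliconPanel:
    """Design the amplicon panel for a simulated tumour.

    ``amplicons_per_arm`` SNP amplicons are spread evenly along every arm,
    each carrying ``snps_per_amplicon`` phased heterozygous SNPs; one extra
    amplicon is added per tumour marker at its position.
    """
    amplicons: list[Amplicon] = []
    for arm in ordered_arms(config.arm_table):
        length = int(config.arm_table[arm] * 1e6)
        n = config.amplicons_per_arm
        for j in range(n):
            centre = int(length * (j + 0.5) / n)
            amp_id = f"A_{arm}_{j + 1:02d}"
            snps = [SnpLocus(f"{amp_id}_s{k + 1}", max(1, centre - 100 + 50 * k))
                    for k in range(config.snps_per_amplicon)]
            amplicons.append(Amplicon(amp_id, arm, max(1, centre - 150),
                                      centre + 150, snps))
    for m in markers:
        amplicons.append(Amplicon(f"A_{m.id}", m.arm, max(1, m.position - 150),
                                  m.position + 150, [], marker_id=m.id))
    return AmpliconPanel(amplicons)
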