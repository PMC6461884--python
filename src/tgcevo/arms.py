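"""Static chromosome-arm table (arm-level genome model).

The analysis operates at chromosome-arm resolution: 41 arms covering
chr1-22 and chrX (acrocentric chromosomes 13, 14, 15, 21 and 22 carry no
p-arm amplicons).  Lengths are approximate cytogenetic arm lengths in Mb;
only relative sizes matter (mutation placement weights, amplicon spacing).
"""

from __future__ import annotations

# arm id -> length (Mb); insertion order is chromosomal order
ARM_LENGTHS_MB: dict[str, float] = {
    "1p": 125.0, "1q": 124.0,
    "2p": 93.0, "2q": 149.0,
    "3p": 91.0, "3q": 107.0,
    "4p": 50.0, "4q": 141.0,
    "5p": 48.0, "5q": 133.0,
    "6p": 61.0, "6q": 110.0,
    "7p": 60.0, "7q": 99.0,
    "8p": 45.0, "8q": 101.0,
    "9p": 49.0, "9q": 92.0,
    "10p": 40.0, "10q": 95.0,
    "11p": 53.0, "11q": 82.0,
    "12p": 36.0, "12q": 98.0,
    "13q": 98.0,
    "14q": 91.0,
    "15q": 85.0,
    "16p": 36.0, "16q": 54.0,
    "17p": 24.0, "17q": 57.0,
    "18p": 17.0, "18q": 61.0,
    "19p": 26.0, "19q": 33.0,
    "20p": 28.0, "20q": 35.0,
    "21q": 34.0,
    "22q": 37.0,
    "Xp": 61.0, "Xq": 94.0,
}

ARMS: tuple[str, ...] = tuple(ARM_LENGTHS_MB)

#: arm whose gain marks the invasive precursor
ARM_12P = "12p"

GENOME_MB: float = sum(ARM_LENGTHS_MB.values())

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER["X"] = 23


def split_arm(arm: str) -> tuple[str, str]:
    """Split an arm id like ``"12p"`` into ``("12", "p")``."""
    chrom, pq = arm[:-1], arm[-1]
    if pq not in ("p", "q") or chrom not in _CHROM_ORDER:
        raise ValueError(f"not a valid arm id: {arm!r}")
    return chrom, pq


def arm_sort_key(arm: str) -> tuple[int, int]:
    """Sort key placing arms in chromosomal order, p before q."""
    chrom, pq = split_arm(arm)
    return _CHROM_ORDER[chrom], 0 if pq == "p" else 1


def ordered_arms(arms) -> list[str]:
    return sorted(arms, key=arm_sort_key)
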