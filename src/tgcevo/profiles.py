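"""Lesser-allele-frequency (LAF) profiles and LOH/imbalance calling.

The LAF of a germline heterozygous SNP is min(countA, countB)/depth, so it
lives in [0, 0.5]: 0.5 means balanced parental haplotypes, values below
the LOH threshold mean one haplotype is (nearly) absent.  SNP LAFs are
averaged per amplicon, replicate runs of a sample are averaged entrywise,
and amplicon/arm LAF values are categorised as LOH / IMBALANCE / BALANCED.
For LOH calls the retained parental haplotype is identified from the
majority allele, so LOH events on the same arm in different samples can be
classified as consistent (same haplotype retained) or independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from tgcevo.arms import arm_sort_key

LOH, IMBALANCE, BALANCED, MISSING = "LOH", "IMBALANCE", "BALANCED", "MISSING"
CONSISTENT, INDEPENDENT, NOT_COMPARABLE = ("CONSISTENT", "INDEPENDENT",
                                           "NOT_COMPARABLE")
UNDETERMINED = "undetermined"

DEFAULT_MIN_DEPTH = 20
DEFAULT_LOH_THRESHOLD = 0.10
DEFAULT_BALANCED_THRESHOLD = 0.35


def compute_laf(count_a: int, count_b: int,
                min_depth: int = DEFAULT_MIN_DEPTH) -> Optional[float]:
    """LAF = min/total; ``None`` (missing) below *min_depth* total reads."""
    if count_a < 0 or count_b < 0:
        raise ValueError(f"negative read counts: ({count_a}, {count_b})")
    depth = count_a + count_b
    if depth < min_depth:
        return None
    return min(count_a, count_b) / depth


def amplicon_average(lafs: Iterable[Optional[float]]) -> Optional[float]:
    """Unweighted mean of the non-missing SNP LAFs of one amplicon."""
    vals = [x for x in lafs if x is not None and not math.isnan(x)]
    if not vals:
        return None
    return float(np.mean(vals))


def call_allelic_state(laf: Optional[float],
                       loh_threshold: float = DEFAULT_LOH_THRESHOLD,
                       balanced_threshold: float = DEFAULT_BALANCED_THRESHOLD,
                       ) -> str:
    """Categorise a LAF: strictly below the LOH threshold -> LOH."""
    if laf is None or (isinstance(laf, float) and math.isnan(laf)):
        return MISSING
    if not (0.0 <= laf <= 0.5 + 1e-12):
        raise ValueError(f"LAF must lie in [0, 0.5], got {laf}")
    if laf < loh_threshold:
        return LOH
    if laf < balanced_threshold:
        return IMBALANCE
    return BALANCED


def determine_retained_haplotype(count_a: int, count_b: int, state: str) -> str:
    """For LOH calls, the haplotype with the larger read count; ties and
    non-LOH states are undetermined."""
    if state != LOH or count_a == count_b:
        return UNDETERMINED
    return "A" if count_a > count_b else "B"


@dataclass
class AllelicCall:
    """LOH/imbalance state of one amplicon or arm in one sample."""
    sample_id: str
    target: str                    # amplicon or arm id
    arm: str
    laf: Optional[float]
    state: str
    retained_haplotype: str = UNDETERMINED

    def __post_init__(self) -> None:
        if self.retained_haplotype != UNDETERMINED and self.state != LOH:
            raise ValueError("retained haplotype only defined for LOH calls")


def compare_loh_events(call_x: AllelicCall, call_y: AllelicCall) -> str:
    """Compare two LOH events on the same arm via the retained haplotype."""
    if call_x.arm != call_y.arm:
        raise ValueError(
            f"calls are on different arms: {call_x.arm} vs {call_y.arm}")
    if call_x.state != LOH or call_y.state != LOH:
        return NOT_COMPARABLE
    if UNDETERMINED in (call_x.retained_haplotype, call_y.retained_haplotype):
        return NOT_COMPARABLE
    if call_x.retained_haplotype == call_y.retained_haplotype:
        return CONSISTENT
    return INDEPENDENT


def expected_laf(states: Iterable[tuple]) -> float:
    """Closed-form LAF for a mixture of copy-number states.

    *states* is an iterable of ``((nA, nB), fraction)``; fractions must sum
    to one.  Returns min(sum f*nA, sum f*nB) / sum f*(nA+nB).
    """
    states = list(states)
    fsum = sum(f for _, f in states)
    if abs(fsum - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fsum}")
    a = sum(f * cn[0] for cn, f in states)
    b = sum(f * cn[1] for cn, f in states)
    if a + b <= 0:
        raise ValueError("zero total copy number in mixture")
    return min(a, b) / (a + b)


# -- table-level pipeline ---------------------------------------------------


def snp_laf_table(counts: pd.DataFrame,
                  min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-SNP LAF from a counts table (SNP rows only)."""
    snp = counts[counts["locus_type"] == "SNP"].copy()
    depth = snp["countA"] + snp["countB"]
    laf = np.minimum(snp["countA"], snp["countB"]) / depth.where(depth > 0)
    laf[depth < min_depth] = np.nan
    snp["laf"] = laf
    snp["depth"] = depth
    return snp


def laf_profile(counts: pd.DataFrame, sample_id: str,
                min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Amplicon-averaged, replicate-averaged LAF profile of one sample.

    Replicates are averaged entrywise over non-missing values after the
    per-amplicon SNP average.  Rows are ordered by (chromosome, arm,
    position).
    """
    snp = snp_laf_table(counts[counts["sample"] == sample_id], min_depth)
    if snp.empty:
        raise ValueError(f"no SNP counts for sample {sample_id!r}")
    per_rep = (snp.groupby(["replicate", "amplicon", "arm"], sort=False)
               .agg(laf=("laf", "mean"), depth=("depth", "sum"),
                    position=("position", "min"))
               .reset_index())
    prof = (per_rep.groupby(["amplicon", "arm"], sort=False)
            .agg(laf=("laf", "mean"), depth=("depth", "sum"),
                 position=("position", "min"))
            .reset_index())
    prof.insert(0, "sample", sample_id)
    key = prof["arm"].map(arm_sort_key)
    prof["_c"] = [k[0] for k in key]
    prof["_a"] = [k[1] for k in key]
    prof = (prof.sort_values(["_c", "_a", "position", "amplicon"])
            .drop(columns=["_c", "_a"]).reset_index(drop=True))
    return prof


def average_replicates(profiles: list) -> pd.DataFrame:
    """Entrywise mean of LAF profiles of the same sample over a shared panel.

    Input profiles must cover identical amplicon sets; missing entries are
    excluded from the mean (a value present in any replicate survives).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    base = profiles[0]
    key = list(base["amplicon"])
    for p in profiles[1:]:
        if list(p["amplicon"]) != key:
            raise ValueError("replicate profiles cover different panels")
    out = base.copy()
    stack = np.vstack([p["laf"].to_numpy(dtype=float) for p in profiles])
    with np.errstate(invalid="ignore"):
        out["laf"] = np.nanmean(stack, axis=0)
    out["depth"] = np.sum([p["depth"].to_numpy() for p in profiles], axis=0)
    return out


def arm_level_calls(counts: pd.DataFrame, sample_id: str,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    loh_threshold: float = DEFAULT_LOH_THRESHOLD,
                    balanced_threshold: float = DEFAULT_BALANCED_THRESHOLD,
                    ) -> list:
    """Arm-level allelic calls for one sample.

    The arm LAF is the mean over its amplicon-averaged LAFs; the retained
    haplotype of an LOH call comes from summed phased counts over the arm.
    """
    prof = laf_profile(counts, sample_id, min_depth)
    snp = snp_laf_table(counts[counts["sample"] == sample_id], 1)
    calls = []
    for arm, grp in prof.groupby("arm", sort=False):
        laf = amplicon_average(grp["laf"])
        state = call_allelic_state(laf, loh_threshold, balanced_threshold)
        retained = UNDETERMINED
        if state == LOH:
            sub = snp[snp["arm"] == arm]
            retained = determine_retained_haplotype(
                int(sub["countA"].sum()), int(sub["countB"].sum()), state)
        calls.append(AllelicCall(sample_id, arm, arm, laf, state, retained))
    calls.sort(key=lambda c: arm_sort_key(c.arm))
    return calls


def calls_to_frame(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.target, c.arm,
          np.nan if c.laf is None else c.laf, c.state, c.retained_haplotype)
         for c in calls],
        columns=["sample", "target", "arm", "laf", "state",
                 "retained_haplotype"])
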