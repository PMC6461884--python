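"""Marker presence calls and mutation timing relative to genome duplication.

The variant allele fraction (VAF) of a mutation at multiplicity ``m`` on
an arm of total copy number ``cn`` in a tumour-cell fraction ``f`` is

    vaf = f * m / (f * cn + 2 * (1 - f))

Inverting this for ``m`` and rounding gives the mutation multiplicity;
a rounded multiplicity >= 2 in a genome-doubled clone indicates the
mutation preceded the duplication, multiplicity 1 that it followed it.
Rounding at .5 boundaries is downward, treating post-duplication as the
default regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

PRESENT, SUBCLONAL, ABSENT = "PRESENT", "SUBCLONAL", "ABSENT"
MISSING = "MISSING"
PRE_WGD, POST_WGD, INDETERMINATE = "PRE_WGD", "POST_WGD", "INDETERMINATE"

DEFAULT_MIN_DEPTH = 20
DETECT_THRESHOLD = 0.03     # strictly above -> detected
CLONAL_THRESHOLD = 0.05     # below -> subclonal detection


def compute_vaf(ref_count: int, var_count: int,
                min_depth: int = DEFAULT_MIN_DEPTH) -> Optional[float]:
    """Variant reads / total reads; ``None`` below *min_depth*."""
    if ref_count < 0 or var_count < 0:
        raise ValueError(f"negative read counts: ({ref_count}, {var_count})")
    depth = ref_count + var_count
    if depth < min_depth:
        return None
    return var_count / depth


def call_marker_presence(vaf: Optional[float],
                         detect_threshold: float = DETECT_THRESHOLD,
                         clonal_threshold: float = CLONAL_THRESHOLD) -> str:
    """ABSENT / SUBCLONAL / PRESENT from a VAF (strict >3% detection).

    SUBCLONAL covers detections below the clonal threshold (minor-clone
    evidence); both SUBCLONAL and PRESENT count as "detected" downstream.
    """
    if vaf is None or (isinstance(vaf, float) and math.isnan(vaf)):
        return MISSING
    if vaf <= detect_threshold:
        return ABSENT
    if vaf < clonal_threshold:
        return SUBCLONAL
    return PRESENT


def expected_vaf(multiplicity: float, total_cn: float, tumour_fraction: float) -> float:
    if not (0 <= multiplicity <= total_cn):
        raise ValueError(f"multiplicity {multiplicity} outside [0, {total_cn}]")
    if not (0 <= tumour_fraction <= 1):
        raise ValueError(f"tumour fraction {tumour_fraction} outside [0, 1]")
    denom = tumour_fraction * total_cn + 2.0 * (1.0 - tumour_fraction)
    if denom <= 0:
        raise ValueError("zero effective copy number")
    return tumour_fraction * multiplicity / denom


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def estimate_multiplicity(vaf: float, total_cn: float,
                          tumour_fraction: float) -> tuple[float, int]:
    """Invert ``expected_vaf``; returns (real-valued, rounded) multiplicity.

    Rounding is half-down and the result clipped to [0, total_cn].
    """
    if tumour_fraction <= 0:
        raise ValueError("tumour fraction must be > 0 to estimate multiplicity")
    if total_cn < 1:
        raise ValueError(f"total copy number must be >= 1, got {total_cn}")
    m = vaf * (tumour_fraction * total_cn + 2.0 * (1.0 - tumour_fraction)) \
        / tumour_fraction
    rounded = min(max(_round_half_down(m), 0), int(total_cn))
    return m, rounded


def classify_wgd_timing(multiplicity_rounded: int, total_cn: float,
                        wgd: bool) -> str:
    """PRE_WGD for multiplicity >= 2 in a doubled genome; POST_WGD for 1."""
    if multiplicity_rounded <= 0 or total_cn < 2:
        return INDETERMINATE
    if multiplicity_rounded >= 2:
        return PRE_WGD if wgd else INDETERMINATE
    return POST_WGD


@dataclass
class MarkerCall:
    sample_id: str
    marker_id: str
    vaf: Optional[float]
    state: str
    multiplicity: Optional[float] = None
    multiplicity_rounded: Optional[int] = None
    timing: Optional[str] = None


# -- table-level pipeline ---------------------------------------------------


def marker_vaf_table(counts: pd.DataFrame,
                     min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Replicate-averaged VAF per (sample, marker) from a counts table."""
    mk = counts[counts["locus_type"].isin(["SNV", "SV"])].copy()
    depth = mk["countA"] + mk["countB"]
    vaf = mk["countB"] / depth.where(depth > 0)
    vaf[depth < min_depth] = np.nan
    mk["vaf"] = vaf
    out = (mk.groupby(["sample", "marker", "arm", "locus_type"], sort=False)
           .agg(vaf=("vaf", "mean"))
           .reset_index()
           .rename(columns={"locus_type": "kind"}))
    return out


def call_markers(counts: pd.DataFrame,
                 cn_purity: Optional[pd.DataFrame] = None,
                 wgd: bool = True,
                 min_depth: int = DEFAULT_MIN_DEPTH,
                 detect_threshold: float = DETECT_THRESHOLD,
                 clonal_threshold: float = CLONAL_THRESHOLD) -> pd.DataFrame:
    """Presence calls (and, where copy numbers are known, timing) per marker.

    *cn_purity*, if given, maps (sample, arm) to total_cn and purity
    (columns ``sample, arm, total_cn, purity``); SNV markers then also get
    multiplicity and WGD-timing estimates.  SV markers are presence-only.
    """
    vafs = marker_vaf_table(counts, min_depth)
    lut = {}
    if cn_purity is not None:
        for r in cn_purity.itertuples(index=False):
            lut[(r.sample, r.arm)] = (float(r.total_cn), float(r.purity))
    rows = []
    for r in vafs.itertuples(index=False):
        vaf = None if pd.isna(r.vaf) else float(r.vaf)
        state = call_marker_presence(vaf, detect_threshold, clonal_threshold)
        m = m_round = None
        timing = None
        if (r.kind == "SNV" and vaf is not None
                and (r.sample, r.arm) in lut):
            cn, purity = lut[(r.sample, r.arm)]
            if purity > 0 and cn >= 1:
                m, m_round = estimate_multiplicity(vaf, cn, purity)
                timing = classify_wgd_timing(m_round, cn, wgd)
        rows.append((r.sample, r.marker, r.arm, r.kind,
                     np.nan if vaf is None else vaf, state,
                     np.nan if m is None else m,
                     -1 if m_round is None else m_round,
                     timing or ""))
    return pd.DataFrame(rows, columns=["sample", "marker", "arm", "kind",
                                       "vaf", "state", "multiplicity",
                                       "multiplicity_rounded", "timing"])
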