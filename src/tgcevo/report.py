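"""Pipeline orchestration, false-colour rendering and mutation-table summary."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

import tgcevo
from tgcevo import profiles, signatures, treebuild, variants
from tgcevo.config import SimConfig
from tgcevo.simulate.io import SimResult, simulate_all, write_truth

log = logging.getLogger("tgcevo")

MUTATION_TYPES = ("Missense", "Stopgain", "Frs del", "Frs sub",
                  "Nonfrs del", "Nonfrs sub", "Acceptor", "Donor")
#: mutation types producing a truncated protein (frameshift or stop-gain)
TRUNCATING_TYPES = frozenset({"Stopgain", "Frs del", "Frs sub"})

ND = "n.d."


@dataclass
class PresenceCount:
    """(mutated, assessed) pair for one sample class; None when blank/n.d."""
    mutated: Optional[int]
    assessed: Optional[int]
    not_determined: bool = False

    @classmethod
    def parse(cls, text: str, line_no: int) -> "PresenceCount":
        text = text.strip()
        if not text:
            return cls(None, None)
        if text == ND:
            return cls(None, None, not_determined=True)
        m = re.fullmatch(r"(\d+)/(\d+)", text)
        if not m:
            raise ValueError(f"line {line_no}: malformed presence count {text!r}")
        mut, assessed = int(m.group(1)), int(m.group(2))
        if mut > assessed:
            raise ValueError(
                f"line {line_no}: mutated {mut} exceeds assessed {assessed}")
        return cls(mut, assessed)

    def render(self) -> str:
        if self.not_determined:
            return ND
        if self.mutated is None:
            return ""
        return f"{self.mutated}/{self.assessed}"


@dataclass
class MutationTableRow:
    tumour: str
    gene: str
    accession: str
    mutation_type: str
    nt_change: str
    aa_change: str
    gcnis: PresenceCount
    histology: PresenceCount
    meta: PresenceCount


def load_mutation_table(path=None) -> list:
    """Parse the packaged per-gene mutation table (or a compatible TSV).

    Blank presence cells and "n.d." entries are preserved as distinct
    non-values.  Raises ``ValueError`` with the line number on malformed
    rows.
    """
    if path is None:
        ref = resources.files("tgcevo.data").joinpath("table1.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.rstrip("\n").split("\n")
    header = lines[0].split("\t")
    expected = ["tumour", "gene", "accession", "mutation_type", "nt_change",
                "aa_change", "gcnis", "histology", "meta"]
    if header != expected:
        raise ValueError(f"line 1: unexpected header {header}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"line {i}: expected at least 6 columns")
        fields += [""] * (9 - len(fields))
        if fields[3] not in MUTATION_TYPES:
            raise ValueError(f"line {i}: unknown mutation type {fields[3]!r}")
        rows.append(MutationTableRow(
            fields[0], fields[1], fields[2], fields[3], fields[4], fields[5],
            PresenceCount.parse(fields[6], i),
            PresenceCount.parse(fields[7], i),
            PresenceCount.parse(fields[8], i)))
    return rows


def write_mutation_table(rows: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("tumour\tgene\taccession\tmutation_type\tnt_change\t"
                 "aa_change\tgcnis\thistology\tmeta\n")
        for r in rows:
            cells = [r.tumour, r.gene, r.accession, r.mutation_type,
                     r.nt_change, r.aa_change, r.gcnis.render(),
                     r.histology.render(), r.meta.render()]
            while len(cells) > 6 and cells[-1] == "":
                cells.pop()
            fh.write("\t".join(cells) + "\n")


def summarize_mutation_table(rows: list) -> dict:
    """Summary counts of the protein-change mutation table.

    Returns truncating-variant count (stop-gains plus frameshifts), the
    per-tumour row counts with their min/max, and per-tumour counts of
    mutations seen in at least one precursor (GCNIS) sample.
    """
    per_tumour: dict[str, int] = {}
    gcnis_present: dict[str, int] = {}
    truncating = 0
    for r in rows:
        per_tumour[r.tumour] = per_tumour.get(r.tumour, 0) + 1
        gcnis_present.setdefault(r.tumour, 0)
        if r.mutation_type in TRUNCATING_TYPES:
            truncating += 1
        if r.gcnis.mutated is not None and r.gcnis.mutated >= 1:
            gcnis_present[r.tumour] += 1
    counts = list(per_tumour.values())
    return {
        "n_rows": len(rows),
        "truncating": truncating,
        "per_tumour": per_tumour,
        "min_per_tumour": min(counts) if counts else 0,
        "max_per_tumour": max(counts) if counts else 0,
        "gcnis_present": gcnis_present,
    }


# -- pipeline ---------------------------------------------------------------


def truth_cn_purity(result: SimResult) -> pd.DataFrame:
    """(sample, arm) -> total copy number and purity from simulation truth.

    The copy number is the major clone's; purity is the summed tumour-cell
    fraction.  This is the simulation-mode stand-in for the user-supplied
    table required on real data.
    """
    rows = []
    for comp in result.samples:
        major = comp.major_clone()
        for arm in result.config.arm_table:
            rows.append((comp.sample_id, arm,
                         result.tree[major].total_cn(arm), comp.purity))
    return pd.DataFrame(rows, columns=["sample", "arm", "total_cn", "purity"])


def sample_loh_thresholds(result: SimResult, margin: float = 0.04) -> dict:
    """Purity-adjusted LOH thresholds per sample.

    A pure-LOH arm in a sample of purity f has LAF (1-f)/2 under a
    retained diploid fraction, so the threshold is raised accordingly
    (never below the default 0.1).
    """
    return {comp.sample_id: max(profiles.DEFAULT_LOH_THRESHOLD,
                                (1.0 - comp.purity) / 2.0 + margin)
            for comp in result.samples}


def pipeline_calls(result: SimResult, min_depth: int = 20,
                   purity_adjusted: bool = True):
    """Allelic and marker call tables for all samples of a simulation."""
    thresholds = sample_loh_thresholds(result) if purity_adjusted else {}
    allelic = []
    for comp in result.samples:
        thr = thresholds.get(comp.sample_id, profiles.DEFAULT_LOH_THRESHOLD)
        allelic.extend(profiles.arm_level_calls(
            result.counts, comp.sample_id, min_depth, loh_threshold=thr))
    allelic_df = profiles.calls_to_frame(allelic)
    marker_df = variants.call_markers(result.counts,
                                      cn_purity=truth_cn_purity(result),
                                      min_depth=min_depth)
    return allelic_df, marker_df


def build_tree_from_calls(allelic_df: pd.DataFrame, marker_df: pd.DataFrame,
                          labels: dict):
    matrix = treebuild.build_character_matrix(marker_df, allelic_df, labels)
    grouped = treebuild.group_identical_samples(matrix)
    evo = treebuild.infer_tree(grouped)
    return grouped, evo


def run_pipeline(config: SimConfig, seed: int, outdir: str) -> dict:
    """Simulate and analyse end to end, writing all artifacts to *outdir*.

    Stages: simulate -> profile -> call -> signatures -> tree -> report.
    A manifest (config, seed, version, output checksums) makes reruns
    verifiable; identical (config, seed) reproduce identical files.
    """
    os.makedirs(outdir, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        result = simulate_all(config, seed)
        paths = write_truth(result, outdir)
        log.info("simulated %d clones, %d markers, %d samples, %d count rows",
                 len(result.tree.clones), len(result.markers),
                 len(result.samples), len(result.counts))

        stage("profile")
        prof = pd.concat([profiles.laf_profile(result.counts, c.sample_id)
                          for c in result.samples], ignore_index=True)
        prof_path = os.path.join(outdir, "profiles.tsv")
        prof.to_csv(prof_path, sep="\t", index=False)
        paths["profiles.tsv"] = prof_path

        stage("call")
        allelic_df, marker_df = pipeline_calls(result)
        for name, df in (("allelic_calls.tsv", allelic_df),
                         ("marker_calls.tsv", marker_df)):
            p = os.path.join(outdir, name)
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
        n_det = int((marker_df["state"].isin(["PRESENT", "SUBCLONAL"])).sum())
        log.info("called %d marker detections, %d LOH arm calls", n_det,
                 int((allelic_df["state"] == "LOH").sum()))

        stage("signatures")
        detected = set(marker_df.loc[
            marker_df["state"].isin(["PRESENT", "SUBCLONAL"]), "marker"])
        contexts = [m.context_class for m in result.markers
                    if m.kind == "SNV" and m.id in detected]
        sig_path = os.path.join(outdir, "exposures.tsv")
        if contexts:
            catalog = signatures.build_context_catalog(contexts)
            sigset = signatures.fixture_signature_set()
            exp = signatures.refit_exposures(catalog, sigset)
            sig_rows = [(n, float(v)) for n, v in zip(exp.names, exp.values)]
            sig_df = pd.DataFrame(sig_rows, columns=["signature", "exposure"])
            sig_df["significant"] = sig_df["exposure"] > 0.05
            sig_df["cosine"] = exp.cosine
        else:
            sig_df = pd.DataFrame(columns=["signature", "exposure",
                                           "significant", "cosine"])
        sig_df.to_csv(sig_path, sep="\t", index=False)
        paths["exposures.tsv"] = sig_path

        stage("tree")
        labels = {c.sample_id: c.histology for c in result.samples}
        grouped, evo = build_tree_from_calls(allelic_df, marker_df, labels)
        tree_path = os.path.join(outdir, "tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(treebuild.to_newick(evo) + "\n")
        paths["tree.nwk"] = tree_path
        gains_path = os.path.join(outdir, "edge_gains.tsv")
        treebuild.annotate_edges(evo, grouped).to_csv(gains_path, sep="\t",
                                                      index=False)
        paths["edge_gains.tsv"] = gains_path
        viol_path = os.path.join(outdir, "violations.txt")
        with open(viol_path, "w") as fh:
            for v in evo.violations:
                fh.write(v + "\n")
        paths["violations.txt"] = viol_path

        stage("report")
        matrix_tsv = os.path.join(outdir, "matrix.tsv")
        render_false_colour_matrix(prof, marker_df, matrix_tsv,
                                   image_path=os.path.join(outdir, "matrix.png"))
        paths["matrix.tsv"] = matrix_tsv
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "version": tgcevo.__version__,
        "checksums": {name: _sha256(path) for name, path in sorted(paths.items())},
    }
    man_path = os.path.join(outdir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = man_path
    return paths


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


# -- rendering --------------------------------------------------------------


def laf_to_rgb(laf: float) -> tuple:
    """Blue (0.5, balanced) -> red (<0.1, LOH) colour ramp; white for missing."""
    if laf is None or (isinstance(laf, float) and np.isnan(laf)):
        return (1.0, 1.0, 1.0)
    t = min(max(laf / 0.5, 0.0), 1.0)
    return (1.0 - t, 0.0, t)


def render_false_colour_matrix(prof: pd.DataFrame, marker_df: pd.DataFrame,
                               tsv_path: str,
                               image_path: Optional[str] = None) -> pd.DataFrame:
    """Samples x amplicons LAF matrix (chromosome-ordered columns).

    Writes the numeric TSV twin (the tested artifact) and optionally a
    PNG: LAF on a blue-to-red ramp, missing cells white, and a greyscale
    marker-presence panel alongside (detected cells dark).
    """
    laf_mat = prof.pivot(index="sample", columns="amplicon", values="laf")
    order = prof.drop_duplicates("amplicon").copy()
    keys = order["arm"].map(profiles.arm_sort_key)
    order["_c"] = [k[0] for k in keys]
    order["_a"] = [k[1] for k in keys]
    order = order.sort_values(["_c", "_a", "position", "amplicon"])
    laf_mat = laf_mat[list(order["amplicon"])]
    laf_mat.to_csv(tsv_path, sep="\t", na_rep="NA")

    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        det = (marker_df.pivot(index="sample", columns="marker", values="state")
               if len(marker_df) else pd.DataFrame(index=laf_mat.index))
        fig, axes = plt.subplots(
            1, 2, figsize=(12, 0.4 * len(laf_mat) + 2),
            gridspec_kw={"width_ratios": [3, 1]})
        rgb = np.array([[laf_to_rgb(v) for v in row]
                        for row in laf_mat.to_numpy()])
        axes[0].imshow(rgb, aspect="auto", interpolation="nearest")
        axes[0].set_yticks(range(len(laf_mat.index)),
                           labels=list(laf_mat.index), fontsize=6)
        axes[0].set_xticks([])
        axes[0].set_title("amplicon-averaged LAF (blue 0.5 -> red <0.1)")
        if det.shape[1]:
            shade = det.reindex(laf_mat.index).map(
                lambda s: {"PRESENT": 0.0, "SUBCLONAL": 0.35,
                           "ABSENT": 0.85}.get(s, 1.0)).to_numpy(dtype=float)
            axes[1].imshow(shade, aspect="auto", cmap="gray", vmin=0, vmax=1,
                           interpolation="nearest")
        axes[1].set_yticks([])
        axes[1].set_xticks([])
        axes[1].set_title("markers (>3% dark)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return laf_mat
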