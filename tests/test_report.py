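import json

import numpy as np
import pandas as pd
import pytest

from tgcevo import report as rp
from tgcevo.config import SimConfig


class TestMutationTableFixture:
    def test_row_count(self):
        rows = rp.load_mutation_table()
        assert len(rows) == 47

    def test_truncating_count(self):
        s = rp.summarize_mutation_table(rp.load_mutation_table())
        assert s["truncating"] == 4

    def test_per_tumour_counts(self):
        s = rp.summarize_mutation_table(rp.load_mutation_table())
        assert s["per_tumour"] == {"T1382": 16, "T3209": 10,
                                   "T6107": 3, "T618": 18}
        assert s["min_per_tumour"] == 3
        assert s["max_per_tumour"] == 18

    def test_gcnis_presence_counts(self):
        s = rp.summarize_mutation_table(rp.load_mutation_table())
        assert s["gcnis_present"]["T618"] == 7
        assert s["gcnis_present"]["T6107"] == 0

    def test_round_trip_lossless(self, tmp_path):
        rows = rp.load_mutation_table()
        out = tmp_path / "table.tsv"
        rp.write_mutation_table(rows, out)
        from importlib import resources
        original = resources.files("tgcevo.data").joinpath("table1.tsv") \
            .read_text()
        assert out.read_text() == original

    def test_empty_table_all_zero(self):
        s = rp.summarize_mutation_table([])
        assert s["truncating"] == 0
        assert s["min_per_tumour"] == 0
        assert s["max_per_tumour"] == 0

    def test_malformed_count_names_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "tumour\tgene\taccession\tmutation_type\tnt_change\taa_change\t"
            "gcnis\thistology\tmeta\n"
            "T1\tG\tNM_1\tMissense\tc.1A>C\tp.X1Y\t5/3\t\t\n")
        with pytest.raises(ValueError, match="line 2"):
            rp.load_mutation_table(bad)

    def test_unknown_type_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "tumour\tgene\taccession\tmutation_type\tnt_change\taa_change\t"
            "gcnis\thistology\tmeta\n"
            "T1\tG\tNM_1\tWeird\tc.1A>C\tp.X1Y\t1/3\t\t\n")
        with pytest.raises(ValueError, match="Weird"):
            rp.load_mutation_table(bad)

    def test_nd_and_blank_distinct(self):
        rows = rp.load_mutation_table()
        by_gene = {(r.tumour, r.gene, r.aa_change): r for r in rows}
        syt7 = by_gene[("T1382", "SYT7", "p.G219S")]
        assert syt7.meta.not_determined
        assert syt7.gcnis.mutated is None and not syt7.gcnis.not_determined


class TestPipeline:
    def test_artifacts_and_manifest(self, tmp_path, small_config):
        paths = rp.run_pipeline(small_config, seed=11,
                                outdir=str(tmp_path / "run"))
        for name in ("counts.tsv", "profiles.tsv", "allelic_calls.tsv",
                     "marker_calls.tsv", "exposures.tsv", "tree.nwk",
                     "edge_gains.tsv", "manifest.json", "matrix.tsv"):
            assert name in paths
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 11
        assert manifest["config"]["n_clones"] == small_config.n_clones
        assert set(manifest["checksums"])

    def test_rerun_bit_identical(self, tmp_path, small_config):
        rp.run_pipeline(small_config, seed=5, outdir=str(tmp_path / "a"))
        rp.run_pipeline(small_config, seed=5, outdir=str(tmp_path / "b"))
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma["checksums"] == mb["checksums"]

    def test_single_sample_single_leaf(self, tmp_path):
        cfg = SimConfig(n_clones=3, n_samples=1, snv_rate=0.005,
                        amplicons_per_arm=1, seed=2).validate()
        paths = rp.run_pipeline(cfg, seed=2, outdir=str(tmp_path / "one"))
        newick = (tmp_path / "one" / "tree.nwk").read_text()
        from tgcevo import treebuild
        evo = treebuild.parse_newick(newick)
        assert len(evo.nodes("observed")) == 1


class TestRendering:
    def test_matrix_tsv_values(self, tmp_path):
        prof = pd.DataFrame({
            "sample": ["s1", "s1", "s2", "s2"],
            "amplicon": ["a1", "a2", "a1", "a2"],
            "arm": ["1p", "2q", "1p", "2q"],
            "position": [10, 20, 10, 20],
            "laf": [0.5, 0.48, 0.02, np.nan],
            "depth": [100] * 4,
        })
        out = tmp_path / "m.tsv"
        mat = rp.render_false_colour_matrix(prof, pd.DataFrame(), str(out))
        assert mat.loc["s1", "a1"] == 0.5
        assert np.isnan(mat.loc["s2", "a2"])
        text = out.read_text()
        assert "NA" in text

    def test_colour_ramp(self):
        assert rp.laf_to_rgb(0.5) == (0.0, 0.0, 1.0)       # balanced: blue
        r, g, b = rp.laf_to_rgb(0.02)                       # LOH: red
        assert r > 0.9 and b < 0.1
        assert rp.laf_to_rgb(float("nan")) == (1.0, 1.0, 1.0)  # missing: white

    def test_png_written(self, tmp_path, small_result):
        from tgcevo import profiles, variants
        prof = pd.concat([profiles.laf_profile(small_result.counts, c.sample_id)
                          for c in small_result.samples], ignore_index=True)
        calls = variants.call_markers(small_result.counts)
        png = tmp_path / "m.png"
        rp.render_false_colour_matrix(prof, calls, str(tmp_path / "m.tsv"),
                                      image_path=str(png))
        assert png.stat().st_size > 0
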