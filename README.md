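# tgcevo

Clonal-evolution analysis of multi-region targeted amplicon sequencing for
germ cell tumours, together with a synthetic tumour generator that follows
a whole-genome-duplication-first developmental model.

The package covers the full analysis chain:

* **`tgcevo.simulate`** — generates clone trees (normal diploid root, a
  genome-doubled in-situ founder lineage, an invasive 12p-gaining EC
  precursor and differentiated/metastatic descendants), arm-level
  allele-specific copy-number evolution with losses predominating, SNV/SV
  markers placed before or after the duplication, sample mixtures with
  normal-cell contamination, and (beta-)binomial read counts for a phased
  SNP + marker amplicon panel. Full truth files are written for every run.
* **`tgcevo.profiles`** — lesser-allele-frequency (LAF) profiles of
  heterozygous SNPs, amplicon and replicate averaging, LOH / imbalance /
  balanced calling (LOH strictly below LAF 0.1) and comparison of LOH
  events between samples via the retained parental haplotype.
* **`tgcevo.variants`** — VAF computation, marker presence calls (detected
  strictly above 3% of reads; a 3–5% subclonal band), mutation-multiplicity
  estimation and PRE/POST whole-genome-duplication timing classification.
* **`tgcevo.signatures`** — 96-class trinucleotide catalogs and
  deterministic non-negative least-squares refitting against a fixed
  signature matrix (a synthetic 4-signature fixture ships for tests; the
  public reference text dialect is accepted as drop-in), reporting
  contributions above 5%.
* **`tgcevo.treebuild`** — evolutionary-tree reconstruction from binary
  SNV/SV-presence and LOH characters under a gain-once/no-loss model:
  identical samples are grouped, latent precursors (`GCNISx`/`ECx`) are
  inserted at branch points between partially non-overlapping profiles, a
  latent EC ancestor is enforced for differentiated histologies, and
  incompatibilities are repaired by a minimum set of "violated" characters
  (exact search up to 12 conflicted characters, greedy above). Trees
  round-trip through an annotated Newick dialect.
* **`tgcevo.report`** — pipeline orchestration with a reproducibility
  manifest, false-colour LAF/marker matrix rendering (TSV twin + PNG), and
  summaries of the packaged per-gene mutation table fixture.

## Command line

```sh
tgcevo --config config.yaml --seed 7 --outdir out report   # full pipeline
tgcevo --outdir out simulate                               # truth + counts
tgcevo --outdir out profile --counts out/counts.tsv
tgcevo --outdir out call --counts out/counts.tsv --cn-purity cn.tsv
tgcevo --outdir out signatures --snvs snvs.tsv
tgcevo --outdir out tree --matrix matrix.tsv
tgcevo table1-summary
```

`--config` takes a YAML file mirroring the `SimConfig` fields; reruns with
the same config and seed are bit-identical (checksums recorded in
`manifest.json`). All tabular formats are TSV; trees are Newick.

## Notes

* The tree builder implements the reconstruction procedure described for
  this analysis directly (set-containment construction with latent Steiner
  nodes); it is **not** a reimplementation of, or wrapper around, any
  external clone-tree inference tool.
* Real patient-level results from raw WGS/targeted data are out of scope;
  end-to-end behaviour is validated on the bundled simulator (see
  `tests/test_acceptance.py`).
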