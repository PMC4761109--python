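# unicity

Isoform-, variant- and processing-aware peptide unicity mapping and
mass-spectrometry evidence integration for curated proteomes.

## The problem

Curated protein knowledgebases integrate published high-throughput
proteomics results to confirm that a protein exists and to annotate its
post-translational modifications (PTMs). Two things make this hard:

1. **Scores are heterogeneous and error-tolerant.** Published peptide
   identifications can carry ~1% false positives; accumulating many
   datasets accumulates errors. Stringent score cut-offs are needed before
   anything is annotated.
2. **Peptides rarely identify one protein.** Search engines report a
   parsimonious protein list, which does not give an unambiguous
   peptide→protein assignment. Deciding unicity properly requires comparing
   each observed peptide against *all* theoretical peptides of the
   proteome — including splice isoforms, proteolytically processed
   products (signal peptides, chains, propeptides) and single amino-acid
   variants.

This package implements that workflow as a standalone, testable toolkit:

* a **unicity table** — an index of every theoretical tryptic peptide of
  an annotated proteome, over every proteoform (canonical, isoforms,
  processed products, variant-substituted forms), keyed with I/L
  equivalence (isoleucine/leucine are isobaric in MS) and classified as
  `unique_protein` / `unique_gene` / `shared` / `absent`;
* a **PSM filter** applying the standard stringent thresholds: a peptide
  identification is accepted when Mascot ≥ 40 **or** posterior error
  probability (PEP) < 1%; a PTM site is considered localized when its
  Ascore ≥ 19;
* **biological-relevance rules** (a phosphosite must not lie inside a
  transmembrane segment), a pluggable rule registry;
* **site-evidence merging** into canonical coordinates with the evidence
  code `ECO:0000244` (combined experimental + computational evidence),
  and **protein-existence promotion** when ≥ K distinct unique peptides
  support an entry;
* a **synthetic-fixture generator** that plants true sites, sub-threshold
  decoys and deliberately ambiguous peptides with a manifest of the
  expected end-to-end outcome, so the whole pipeline is verifiable
  without downloading anything.

## Worked example

```bash
# 1. make a fixture: 25 entries, 10 true phosphosites, 5 decoys, 3 ambiguous
unicity fixtures make --seed 7 --entries 25 --true-sites 10 --decoys 5 \
    --ambiguous 3 --out demo/

# 2. run the pipeline
cat > demo/config.yaml <<'EOF'
fasta: proteome.fasta
features: features.tsv
datasets:
  - psms: psms.tsv
    metadata: metadata.json
out_dir: run1
EOF
unicity pipeline run --config demo/config.yaml
# -> 10 peptides passed the filtering steps, supporting 10 PTM sites in 10 entries

unicity report show --run-dir demo/run1
```

prints

```
input PSMs:                 18
accepted identifications:   13
validated unique peptides:  10
localized sites:            13
annotated sites:            10
entries covered:            10
rejections:
  identification: 5
```

Reading: of 18 input PSMs, the 5 decoys fail both score thresholds; the
3 ambiguous PSMs pass identification but map to more than one gene, so
they are rejected at unicity resolution and annotate nothing; the 10 true
PSMs are unique, localized, biologically plausible, and become 10
`ECO:0000244` site annotations (`demo/run1/annotations.tsv`), one per
planted site. Every rejection is in `demo/run1/audit.jsonl` with its
stage and reason.

The library surface mirrors the CLI: `build_unicity_table`, `lookup` /
`classify`, `apply_identification_filter`, `apply_site_filter`,
`resolve_peptide`, `check_biological_relevance`, `merge_site_evidence`,
`promote_protein_existence`, `run` / `run_from_config`.

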