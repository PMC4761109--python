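# File formats

All coordinates are 1-based inclusive. All tables are plain
tab-separated text with a header row; `#` lines are comments.

## Proteome FASTA

UniProt-style headers. Canonical records:

```
>sp|P00001|EXMP1_TEST GN=EXMP1 PE=2
MKAARCCDDK
```

`GN=` is the gene symbol (optional), `PE=` the protein-existence level
(1 protein, 2 transcript, 3 homology, 4 predicted, 5 uncertain).
Isoform records use the bare `ACC-n` id and attach to entry `ACC`:

```
>P00001-2
MKAARDDK
```

Sequences are upper-cased on read; a trailing `*` is stripped. Allowed
residues: the 20 standard amino acids plus `U` (selenocysteine).

## Feature table

```
# coordinates are 1-based inclusive
accession	target_form	kind	begin	end	payload
P00001	canonical	TRANSMEM	2	4	-
P00001	canonical	VARIANT	3	3	A>V
P00001	canonical	CHAIN	3	10	-
P00001	P00001-2	ALIGN	0	0	1,1,5
```

`target_form` is `canonical` or an isoform id. Kinds: `VARIANT` (payload
`X>Y`, begin == end, X must match the sequence), `CHAIN`, `PEPTIDE`,
`SIGNAL`, `PROPEP`, `TRANSMEM`, `MOD_RES` (payload = PTM name). `ALIGN`
rows carry isoform alignment blocks as
`canonical_start,iso_start,length`; begin/end are ignored for them.

## PSM table

```
dataset_id	spectrum_id	peptide	mods	mascot	pep
DS1	S0001	SAMPK	3:Phosphoserine:25.0	55.0	0.001
DS1	S0002	SAMPK		39.0	
```

`mods` is `pos:NAME:ascore` joined by `;`; an empty ascore means the
localization score is missing (never zero). Empty `mascot`/`pep` fields
stay missing.

## Dataset metadata

JSON (list of objects) or TSV with columns `dataset_id`,
`raw_data_location`, `instrument`, `search_software`, `enzyme`,
`reported_fdr`. The first three are required for a dataset to be
integrated; the last two are warning-grade.

## Pipeline config (YAML)

```yaml
fasta: proteome.fasta
features: features.tsv          # optional
datasets:
  - psms: psms.tsv
    metadata: metadata.json
out_dir: run1
digest: {enzyme: trypsin, max_missed: 2, min_len: 7, max_len: 45}
policy: {mascot_min: 40, pep_max: 0.01, ascore_min: 19, combination: any}
normalization: il_equivalent
apply_variants: true
existence_k: 2
allow_unverified: false
emit_isoform_sites: true
strict: false
write_unicity_table: false
```

Relative paths resolve against the config file's directory.

## Outputs

* `annotations.tsv` — columns `accession position ptm_name evidence_code
  n_datasets n_spectra peptides`; provenance (release tag, digest spec,
  policy, normalization) in `#` header lines.
* `annotations_isoform.tsv` — same columns for isoform-specific sites;
  `position` is `iso_id:position`.
* `audit.jsonl` — one JSON object per rejection/warning/promotion with
  its stage and reason.
* `summary.json` — run summary, extras (PSM-level counts, promotions)
  and provenance.
* `unicity.tsv` + `unicity.meta.json` (when requested) — sorted
  `peptide_key → accession:form:start-end:canonical:variant:base:offset`
  pairs plus table metadata.
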