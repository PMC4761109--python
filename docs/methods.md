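# Methods

## Data model

A proteome is gene-centric: one entry per gene, holding a single
**canonical sequence** that anchors every annotation coordinate, plus
splice isoforms, sequence features and a protein-existence level
(protein_level … uncertain, encoded PE=1..5 in FASTA headers). Isoforms
carry explicit **alignment blocks** `(canonical_start, iso_start, length)`
mapping identical stretches back to the canonical; blocks are monotone and
non-overlapping on both sides and are validated to span identical
substrings. A helper can derive blocks for pure-deletion isoforms, but a
computed alignment is never silently trusted — it is flagged as derived.
Coordinates are 1-based inclusive throughout.

Features: `VARIANT` (single amino-acid substitution; the stated original
residue must match the sequence, otherwise the row is rejected), `CHAIN` /
`PEPTIDE` / `SIGNAL` / `PROPEP` (proteolytic processing products),
`TRANSMEM`, `MOD_RES`. Selenocysteine `U` is a first-class residue and
never aliases to cysteine.

## Proteoform enumeration

Each entry expands deterministically into digestible sequence forms:
canonical; each isoform; each processing product (the subsequence its
feature spans, with its parent offset remembered); and, when variant
application is on (the default), each variant applied to the canonical and
to every processing product containing the substituted position. **At most
one variant per form**: combinatorial multi-variant proteoforms explode
exponentially, and single-variant expansion covers the intended use
(detecting variant peptides); the limitation is deliberate and documented.
Form counts therefore obey
`1 + #isoforms + #processing + Σ_variants (1 + #processing containing it)`,
which the tests verify by brute force.

## Digestion

Fully specific digestion with missed cleavages. `trypsin` cleaves
C-terminal to K/R except before proline; `trypsin_p` cleaves
unconditionally (several search engines use this rule — the table's
dialect must match the engine that produced the PSMs); `none` leaves the
form whole. Defaults: trypsin, ≤ 2 missed cleavages, peptide length 7–45
(shorter peptides are almost never unique and longer ones are rarely
observed). The length filter applies last. The digest spec is stamped into
every unicity table and report header so tables are never mixed across
specs. N-terminal-methionine-cleaved forms are not auto-generated — a
known limitation. For a form with `c` internal sites, peptides with
exactly `k ≤ c` missed cleavages number `c + 1 − k`; this count law and a
substring-enumeration oracle (plus pyteomics' regex cleaver) back the
implementation in tests.

## The unicity table

Every theoretical peptide of every form is keyed and indexed with all its
assignments `(accession, form, start, end, canonical coordinates,
variant flag)`. The default key normalization is **I/L equivalence**
(both residues map to the placeholder `J`) because standard MS cannot
distinguish them; `exact` mode exists for non-MS uses. Normalization is
idempotent (`J` is legal input in I/L mode only), and the mode is stamped
into the table and enforced at lookup.

Classification is evaluated at the entry (accession) level:
`unique_protein` when all assignments share one accession — matching the
gene-centric model, a peptide seen only in one entry's isoform still
identifies that entry; `unique_gene` when several accessions share one
non-empty gene symbol; `shared` otherwise; `absent` when the peptide is
not theoretical. Canonical coordinates of an assignment exist iff the
region maps contiguously inside alignment blocks; isoform-specific
assignments keep `NONE` and are reported distinctly. The lookup path is a
plain hash map; serialization is a sorted two-column TSV plus a JSON
sidecar, so two builds from the same inputs are byte-identical and golden
tables diff cleanly.

## Score filtering

Identification: accept iff Mascot ≥ 40 **or** PEP < 0.01. Localization: a
modification is localized iff Ascore ≥ 19. The "minimum" thresholds are
inclusive (≥); the PEP bound is strict (<). The or-chained published rule
is read as identification = Mascot-or-PEP with Ascore gating only site
localization, because Ascore scores localization, not identification; a
`combination: all` mode is available for the conjunctive reading and then
requires both Mascot and PEP present and passing. Missing scores never
default to zero — a PSM with no usable score is rejected with that exact
reason, and a site without an Ascore is retained as existence evidence but
never annotated. Spectra are never re-searched.

Dataset gating follows a minimum-information checklist: raw-data
location, instrument and search software are required (fail ⇒ the dataset
is skipped unless `allow_unverified`); enzyme and reported FDR are
warning-grade.

## Site annotation

Only `unique_protein` peptides contribute sites (the strictest reading of
unambiguous assignment); `unique_gene` and `shared` peptides are rejected
at resolution but remain visible in the audit log and count as shared
evidence. A peptide occurring at several positions within its single
entry is position-ambiguous and likewise rejected. Relevance rules are a
pluggable registry; the default rule rejects phosphorylation sites (PTM
names starting "Phospho") whose canonical position falls inside a
`TRANSMEM` interval, bounds inclusive — the rule is scoped to
phosphorylation only, since that is the established implausibility case;
other PTM classes can be added by registering rules. Sites on
isoform-specific regions are emitted with isoform coordinates in a
separate output file rather than dropped. Accepted sites merge on
(accession, position, PTM name); supporting spectra deduplicate on
(dataset, spectrum); every annotation carries `ECO:0000244`.

Protein-existence promotion: an entry below protein level is promoted
when ≥ K distinct validated unique peptide keys support it. K defaults
to 2 (the common two-peptide convention; no authoritative value exists),
is configurable, and every promotion or non-promotion is written to the
audit log.

Run summaries count **validated peptides as distinct normalized peptide
keys** among accepted, uniquely-resolved records (PSM-level counts are
also reported in `extras`), annotated sites from the merged evidence, and
covered entries as distinct accessions in it. Counts are conserved at
every stage boundary, asserted from the audit trail in tests.

## Synthetic fixtures

The generator emulates the structural features the pipeline must handle:
entries assembled from tryptic "units" (no internal K/R, not starting
with P, ending K/R, length 7–12, ≥ 1 Ser/Thr), so planted features on
unit boundaries are automatically cleavage-compatible; TM segments and
chains span whole units; variants are cleavage-neutral substitutions;
isoforms are unit-run deletions or novel-unit insertions with exact
alignment blocks; shared units planted across entries guarantee ambiguous
peptides. Default shape: 8–16 units per entry (≈ 60–190 residues) —
small proteins by design, sized so that test-suite and verification runs
complete quickly while exercising every code path.

PSM datasets plant: true phosphosites on uniquely-mapping units outside
TM segments (Mascot ~ U[45,90], PEP ~ U[0,0.005], Ascore ~ U[20,40]);
decoys failing both identification thresholds (Mascot ~ U[10,35], PEP ~
U[0.02,0.5]); ambiguous PSMs on shared units with passing scores; and
optionally true-scoring sites inside TM segments that the relevance rule
must reject. All scores keep ≥ 0.5 margin from every threshold so fixture
outcomes cannot hinge on inclusive-vs-strict semantics (those are tested
separately with exact boundary values). The manifest records the planted
truth and the expected summary, computed from the construction itself, so
every fixture is self-verifying.

What the fixtures do **not** emulate: real score distributions (no
overlap between true and false populations), mass errors, retention
times, spectra, shared peptides arising from homologous gene families,
multi-variant haplotypes, or realistic protein length and PTM-density
distributions. Passing the recovery tests therefore shows the plumbing
and decision logic are exact under separable conditions, not that the
thresholds themselves have any particular sensitivity/specificity on
real data — the thresholds are curation policy, taken as given.

## Numerical and degenerate-input choices

Thresholds are compared in double precision with no tolerance: scores are
data, not computed quantities. Deterministic orderings everywhere
(peptides by (start, end); forms canonical → isoforms → processed →
variants; table keys sorted at serialization; merged sites by accession
then position) make every output byte-reproducible; no output contains a
timestamp. Empty PSM tables yield an all-zero summary and exit 0. Invalid
rows (feature or PSM) are skipped and reported, with a `strict` switch
that turns them into errors. An empty proteome, an unknown accession or
isoform id, out-of-range coordinates and malformed headers are hard
errors before any stage runs.

## Known limitations

* Single-variant proteoforms only; variant×variant and variant×isoform
  combinations are not enumerated.
* Variants are applied in canonical coordinates only.
* Isoform-specific processing products of an isoform that cannot be
  mapped back to canonical are rejected as unmappable rather than
  emitted with nested coordinates.
* No peptide mass/charge modelling, no semi- or non-specific digestion,
  no FDR re-estimation — out of scope by design.
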