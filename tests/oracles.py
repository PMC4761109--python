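"""Independent brute-force oracles used by the test suite.

These deliberately take a different computational route from the package
(substring enumeration with boundary-validity checks instead of fragment
assembly) so that agreement is evidence of correctness, not of shared code.
"""

from __future__ import annotations

from unicity.digestion import DigestSpec
from unicity.proteome import FormOptions, Proteome, enumerate_sequence_forms
from unicity.table import normalize_peptide


def naive_form_peptides(seq: str, spec: DigestSpec) -> set[tuple[int, int]]:
    """All (start, end) 1-based regions of ``seq`` that are fully-specific
    peptides under ``spec``, found by scanning every substring."""
    n = len(seq)
    cut_after = set()
    if spec.enzyme != "none":
        for i in range(n - 1):
            if seq[i] in "KR":
                if spec.enzyme == "trypsin" and seq[i + 1] == "P":
                    continue
                cut_after.add(i)
    valid_start = {0} | {i + 1 for i in cut_after}
    valid_end = {n - 1} | cut_after
    prefix = [0] * (n + 1)
    for i in range(n):
        prefix[i + 1] = prefix[i] + (1 if i in cut_after else 0)
    out = set()
    for s in sorted(valid_start):
        for length in range(spec.min_len, spec.max_len + 1):
            e = s + length - 1
            if e >= n:
                break
            if e not in valid_end:
                continue
            if prefix[e] - prefix[s] > spec.max_missed:  # internal uncut sites
                continue
            out.add((s + 1, e + 1))
    return out


def naive_unicity_map(
    proteome: Proteome,
    spec: DigestSpec = DigestSpec(),
    opts: FormOptions = FormOptions(),
    normalization: str = "il_equivalent",
) -> dict[str, set[tuple[str, str, int, int]]]:
    """key -> set of (accession, form_id, start, end), by scanning every form."""
    mapping: dict[str, set[tuple[str, str, int, int]]] = {}
    for entry in proteome.entries:
        for form in enumerate_sequence_forms(entry, opts):
            for start, end in naive_form_peptides(form.seq, spec):
                key = normalize_peptide(form.seq[start - 1 : end], normalization)
                mapping.setdefault(key, set()).add(
                    (entry.accession, form.form_id, start, end)
                )
    return mapping


def naive_classify(
    mapping: dict[str, set], gene_symbols: dict[str, str], peptide_key: str
) -> str:
    assignments = mapping.get(peptide_key, set())
    if not assignments:
        return "absent"
    accessions = {acc for acc, _, _, _ in assignments}
    if len(accessions) == 1:
        return "unique_protein"
    genes = {gene_symbols.get(acc, "") for acc in accessions}
    if len(genes) == 1 and "" not in genes:
        return "unique_gene"
    return "shared"
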