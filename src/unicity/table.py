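"""The unicity table: every theoretical peptide of a proteome with every
possible assignment, used to decide whether an observed peptide identifies
one protein unambiguously.

Peptides are keyed after normalization. The default ``il_equivalent`` mode
replaces isoleucine and leucine by the placeholder ``J`` because the two
residues are isobaric and indistinguishable by standard MS; ``exact`` mode
is available for non-MS uses. A table is stamped with its normalization
mode and digest spec, and lookups check the mode so tables are never mixed
across conventions.

Uniqueness is evaluated at the entry (accession) level: entries are
gene-centric, so a peptide matching only the isoforms or processed
products of one entry still identifies that entry uniquely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .digestion import DigestSpec, digest_proteome
from .proteome import (
    AMINO_ALPHABET,
    AlphabetError,
    ConsistencyError,
    FormOptions,
    Proteome,
    canonical_region_of,
    enumerate_sequence_forms,
)

NORMALIZATION_MODES = ("il_equivalent", "exact")


def normalize_peptide(peptide: str, mode: str = "il_equivalent") -> str:
    """Normalized key of a peptide sequence; validates the alphabet.

    Normalization is idempotent: in ``il_equivalent`` mode the placeholder
    ``J`` is accepted on input (a key normalizes to itself); in ``exact``
    mode it is an alphabet error like any other non-residue character.
    """
    if mode not in NORMALIZATION_MODES:
        raise ConsistencyError(f"unknown normalization mode {mode!r}")
    peptide = peptide.upper()
    allowed = AMINO_ALPHABET | {"J"} if mode == "il_equivalent" else AMINO_ALPHABET
    for i, ch in enumerate(peptide, start=1):
        if ch not in allowed:
            raise AlphabetError(f"illegal residue {ch!r} at position {i}")
    if mode == "il_equivalent":
        return peptide.replace("I", "J").replace("L", "J")
    return peptide


class UnicityClass(Enum):
    unique_protein = "unique_protein"  # all assignments share one accession
    unique_gene = "unique_gene"        # several accessions, one gene symbol
    shared = "shared"                  # several genes
    absent = "absent"                  # not a theoretical peptide


@dataclass(frozen=True)
class Assignment:
    accession: str
    form_id: str
    start: int  # within the form, 1-based inclusive
    end: int
    canonical_start: Optional[int]  # None when the region is isoform-specific
    canonical_end: Optional[int]
    carries_variant: bool = False
    base: str = "canonical"  # coordinate system the form anchors to
    offset: int = 1          # base position of the form's first residue

    def base_region(self) -> tuple[int, int]:
        """The region in base-form ("canonical" or isoform) coordinates."""
        return self.offset + self.start - 1, self.offset + self.end - 1

    def sort_key(self):
        return (self.accession, self.form_id, self.start, self.end)


@dataclass
class UnicityTable:
    keys: dict[str, list[Assignment]] = field(default_factory=dict)
    normalization: str = "il_equivalent"
    digest_spec: DigestSpec = field(default_factory=DigestSpec)
    release_tag: str = ""
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def lookup(self, peptide: str) -> list[Assignment]:
        """All assignments of a peptide; empty list when absent."""
        return self.keys.get(normalize_peptide(peptide, self.normalization), [])

    def classify(self, peptide: str) -> UnicityClass:
        assignments = self.lookup(peptide)
        if not assignments:
            return UnicityClass.absent
        accessions = {a.accession for a in assignments}
        if len(accessions) == 1:
            return UnicityClass.unique_protein
        genes = {self.gene_symbols.get(acc, "") for acc in accessions}
        if len(genes) == 1 and "" not in genes:
            return UnicityClass.unique_gene
        return UnicityClass.shared

    def __len__(self) -> int:
        return len(self.keys)


def build_unicity_table(
    proteome: Proteome,
    spec: DigestSpec = DigestSpec(),
    opts: FormOptions = FormOptions(),
    normalization: str = "il_equivalent",
) -> UnicityTable:
    """Digest every enumerated sequence form of every entry into a keyed table.

    Assignments are deduplicated on (accession, form, start); construction is
    deterministic for fixed inputs.
    """
    if normalization not in NORMALIZATION_MODES:
        raise ConsistencyError(f"unknown normalization mode {normalization!r}")
    proteome.validate()
    table = UnicityTable(
        normalization=normalization,
        digest_spec=spec,
        release_tag=proteome.release_tag,
        gene_symbols={e.accession: e.gene_symbol for e in proteome.entries},
    )
    seen: set[tuple[str, str, str, int]] = set()
    for entry in proteome.entries:
        forms = enumerate_sequence_forms(entry, opts)
        for pep in digest_proteome(forms, spec):
            key = normalize_peptide(pep.sequence, normalization)
            dedup = (key, entry.accession, pep.form_ref.form_id, pep.start)
            if dedup in seen:
                continue
            seen.add(dedup)
            c_start, c_end = canonical_region_of(
                entry, pep.form_ref, pep.start, pep.end
            )
            table.keys.setdefault(key, []).append(
                Assignment(
                    accession=entry.accession,
                    form_id=pep.form_ref.form_id,
                    start=pep.start,
                    end=pep.end,
                    canonical_start=c_start,
                    canonical_end=c_end,
                    carries_variant=pep.carries_variant,
                    base=pep.form_ref.base,
                    offset=pep.form_ref.offset,
                )
            )
    for assignments in table.keys.values():
        assignments.sort(key=Assignment.sort_key)
    return table


# ---------------------------------------------------------------------------
# serialization — sorted two-column TSV plus a JSON metadata sidecar, so
# golden tables diff cleanly.

def write_unicity_table(table: UnicityTable, tsv_path, sidecar_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("peptide_key\tassignment\n")
        for key in sorted(table.keys):
            for a in table.keys[key]:
                c = (
                    f"{a.canonical_start}-{a.canonical_end}"
                    if a.canonical_start is not None
                    else "NONE"
                )
                var = "V" if a.carries_variant else "-"
                fh.write(
                    f"{key}\t{a.accession}:{a.form_id}:{a.start}-{a.end}:{c}:{var}:"
                    f"{a.base}:{a.offset}\n"
                )
    if sidecar_path is not None:
        meta = {
            "normalization": table.normalization,
            "digest_spec": {
                "enzyme": table.digest_spec.enzyme,
                "max_missed": table.digest_spec.max_missed,
                "min_len": table.digest_spec.min_len,
                "max_len": table.digest_spec.max_len,
            },
            "release_tag": table.release_tag,
            "n_keys": len(table.keys),
            "gene_symbols": dict(sorted(table.gene_symbols.items())),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_unicity_table(tsv_path, sidecar_path) -> UnicityTable:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    table = UnicityTable(
        normalization=meta["normalization"],
        digest_spec=DigestSpec(**meta["digest_spec"]),
        release_tag=meta["release_tag"],
        gene_symbols=meta.get("gene_symbols", {}),
    )
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("peptide_key"):
            raise ConsistencyError(f"{tsv_path}: not a unicity table")
        for line in fh:
            key, spec = line.rstrip("\n").split("\t")
            # form_id may itself contain ':', so peel fields off both ends
            head, region, canon, var, base, offset_s = spec.rsplit(":", 5)
            acc, form_id = head.split(":", 1)
            start_s, end_s = region.split("-")
            if canon == "NONE":
                c_start = c_end = None
            else:
                c_start, c_end = (int(x) for x in canon.split("-"))
            table.keys.setdefault(key, []).append(
                Assignment(
                    accession=acc,
                    form_id=form_id,
                    start=int(start_s),
                    end=int(end_s),
                    canonical_start=c_start,
                    canonical_end=c_end,
                    carries_variant=(var == "V"),
                    base=base,
                    offset=int(offset_s),
                )
            )
    return table
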