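"""Annotated-proteome data model and I/O.

A curated proteome is gene-centric: each entry carries one canonical
amino-acid sequence that anchors every annotation coordinate, plus any
number of splice isoforms (with explicit alignment blocks back to the
canonical), sequence features (variants, processed chains/peptides,
signal peptides, transmembrane regions, modified residues) and a
protein-existence level.

Formats
-------
* FASTA in the UniProt header dialect: canonical records as
  ``>sp|ACC|NAME GN=SYMBOL PE=<1..5>``, isoforms as ``>ACC-n``.
* A 6-column tab-separated feature table
  (``accession  target_form  kind  begin  end  payload``); isoform
  alignment blocks travel as rows of kind ``ALIGN`` whose payload is
  ``canonical_start,iso_start,length``.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Selenocysteine (U) is a first-class residue; it never aliases to C.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYU")

PROCESSING_KINDS = ("CHAIN", "PEPTIDE", "SIGNAL", "PROPEP")


# ---------------------------------------------------------------------------
# errors

class UnicityError(Exception):
    """Base class for all toolkit errors."""


class FastaParseError(UnicityError):
    pass


class OrphanIsoformError(FastaParseError):
    pass


class AlphabetError(UnicityError):
    pass


class ReferenceLookupError(UnicityError):
    """An accession / isoform id that does not exist in the proteome."""


class ConsistencyError(UnicityError):
    """A feature contradicts the sequence it annotates."""


class BoundsError(UnicityError):
    pass


class ConfigError(UnicityError):
    pass


# ---------------------------------------------------------------------------
# domain types

class Existence(Enum):
    """Protein-existence level, ordered best (protein_level) to worst."""

    protein_level = 1
    transcript_level = 2
    homology = 3
    predicted = 4
    uncertain = 5


class FeatureKind(Enum):
    VARIANT = "VARIANT"
    CHAIN = "CHAIN"
    PEPTIDE = "PEPTIDE"
    SIGNAL = "SIGNAL"
    PROPEP = "PROPEP"
    TRANSMEM = "TRANSMEM"
    MOD_RES = "MOD_RES"


@dataclass(frozen=True)
class Block:
    """One gap-free alignment block between canonical and isoform coordinates."""

    canonical_start: int
    iso_start: int
    length: int


@dataclass
class Feature:
    kind: FeatureKind
    target_form: str  # "canonical" or an isoform id
    begin: int
    end: int
    payload: Optional[str] = None  # VARIANT: "X>Y"; MOD_RES: PTM name

    def variant_residues(self) -> tuple[str, str]:
        if self.kind is not FeatureKind.VARIANT:
            raise ValueError("not a VARIANT feature")
        m = re.fullmatch(r"([A-Z])>([A-Z])", self.payload or "")
        if not m:
            raise ConsistencyError(f"bad VARIANT payload {self.payload!r}")
        return m.group(1), m.group(2)


@dataclass
class Isoform:
    iso_id: str
    seq: str
    alignment: list[Block] = field(default_factory=list)
    alignment_derived: bool = False  # True when blocks were computed, not supplied


@dataclass
class ProteinEntry:
    accession: str
    canonical_seq: str
    entry_name: str = ""
    gene_symbol: str = ""
    isoforms: list[Isoform] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    existence: Existence = Existence.predicted

    def isoform(self, iso_id: str) -> Isoform:
        for iso in self.isoforms:
            if iso.iso_id == iso_id:
                return iso
        raise ReferenceLookupError(f"unknown isoform {iso_id!r} on {self.accession}")

    def form_sequence(self, form: str) -> str:
        """Sequence of a base form: 'canonical' or an isoform id."""
        if form == "canonical":
            return self.canonical_seq
        return self.isoform(form).seq

    def validate(self) -> None:
        _check_sequence(self.canonical_seq, self.accession)
        for iso in self.isoforms:
            _check_sequence(iso.seq, iso.iso_id)
            _check_alignment(iso, self.canonical_seq)
        for feat in self.features:
            seq = self.form_sequence(feat.target_form)
            if not (1 <= feat.begin <= feat.end <= len(seq)):
                raise BoundsError(
                    f"{self.accession}: {feat.kind.value} {feat.begin}-{feat.end} "
                    f"outside 1..{len(seq)} of {feat.target_form}"
                )
            if feat.kind is FeatureKind.VARIANT:
                if feat.begin != feat.end:
                    raise ConsistencyError(
                        f"{self.accession}: VARIANT must be single-residue"
                    )
                orig, _alt = feat.variant_residues()
                if seq[feat.begin - 1] != orig:
                    raise ConsistencyError(
                        f"{self.accession}: VARIANT at {feat.begin} claims {orig} "
                        f"but sequence has {seq[feat.begin - 1]}"
                    )


@dataclass
class Proteome:
    entries: list[ProteinEntry] = field(default_factory=list)
    release_tag: str = ""

    def __post_init__(self) -> None:
        self._by_accession = {e.accession: e for e in self.entries}
        if len(self._by_accession) != len(self.entries):
            raise ConsistencyError("duplicate accessions in proteome")

    def get(self, accession: str) -> ProteinEntry:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise ReferenceLookupError(f"unknown accession {accession!r}") from None

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        if not self.entries:
            raise ConsistencyError("proteome has no entries")
        for entry in self.entries:
            entry.validate()


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise AlphabetError(f"{label}: empty sequence")
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ALPHABET:
            raise AlphabetError(f"{label}: illegal residue {ch!r} at position {i}")


def _check_alignment(iso: Isoform, canonical: str) -> None:
    prev_c = prev_i = 0
    for blk in iso.alignment:
        if blk.length < 1:
            raise ConsistencyError(f"{iso.iso_id}: empty alignment block")
        if blk.canonical_start <= prev_c or blk.iso_start <= prev_i:
            raise ConsistencyError(f"{iso.iso_id}: alignment blocks overlap/unsorted")
        c_sub = canonical[blk.canonical_start - 1 : blk.canonical_start - 1 + blk.length]
        i_sub = iso.seq[blk.iso_start - 1 : blk.iso_start - 1 + blk.length]
        if len(c_sub) != blk.length or len(i_sub) != blk.length:
            raise BoundsError(f"{iso.iso_id}: alignment block outside sequence")
        if c_sub != i_sub:
            raise ConsistencyError(
                f"{iso.iso_id}: aligned substrings differ in block "
                f"({blk.canonical_start},{blk.iso_start},{blk.length})"
            )
        prev_c = blk.canonical_start + blk.length - 1
        prev_i = blk.iso_start + blk.length - 1


# ---------------------------------------------------------------------------
# FASTA I/O

_CANONICAL_RE = re.compile(r"^(sp|tr)\|([A-Z][A-Z0-9]*)\|(\S+)(?:\s+(.*))?$")
_ISOFORM_RE = re.compile(r"^([A-Z][A-Z0-9]*-\d+)(?:\s+(.*))?$")


def _header_line_number(path, header: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.rstrip("\n") == ">" + header:
                return lineno
    return -1


def _parse_tail(tail: str) -> tuple[str, Existence]:
    gene = ""
    existence = Existence.predicted
    for tok in (tail or "").split():
        if tok.startswith("GN="):
            gene = tok[3:]
        elif tok.startswith("PE="):
            try:
                existence = Existence(int(tok[3:]))
            except ValueError:
                pass
    return gene, existence


def read_proteome_fasta(path, release_tag: str = "") -> Proteome:
    """Read a proteome FASTA (UniProt header dialect) into a :class:`Proteome`.

    Canonical records (``sp|ACC|NAME``) become entries; ``ACC-n`` records
    attach to entry ``ACC`` as isoforms with empty alignment. Sequences are
    upper-cased and ``*`` terminators stripped. Features are left empty:
    attach them with :func:`read_feature_table`.
    """
    entries: list[ProteinEntry] = []
    by_acc: dict[str, ProteinEntry] = {}
    pending_isoforms: list[tuple[str, str]] = []

    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        seq = str(record.seq).upper().rstrip("*")
        m = _CANONICAL_RE.match(header)
        if m:
            _db, acc, name, tail = m.groups()
            gene, existence = _parse_tail(tail or "")
            entry = ProteinEntry(
                accession=acc,
                canonical_seq=seq,
                entry_name=name,
                gene_symbol=gene,
                existence=existence,
            )
            _check_sequence(seq, acc)
            if acc in by_acc:
                raise ConsistencyError(f"duplicate accession {acc}")
            by_acc[acc] = entry
            entries.append(entry)
            continue
        m = _ISOFORM_RE.match(header)
        if m:
            iso_id = m.group(1)
            _check_sequence(seq, iso_id)
            pending_isoforms.append((iso_id, seq))
            continue
        lineno = _header_line_number(path, header)
        raise FastaParseError(f"{path}:{lineno}: malformed header {header!r}")

    for iso_id, seq in pending_isoforms:
        parent = iso_id.rsplit("-", 1)[0]
        if parent not in by_acc:
            raise OrphanIsoformError(
                f"isoform {iso_id} has no parent entry {parent} in {path}"
            )
        by_acc[parent].isoforms.append(Isoform(iso_id=iso_id, seq=seq))
    for entry in entries:
        entry.isoforms.sort(key=lambda iso: iso.iso_id)
    return Proteome(entries=entries, release_tag=release_tag)


def write_proteome_fasta(proteome: Proteome, path) -> None:
    records = []
    for entry in proteome.entries:
        name = entry.entry_name or entry.accession
        tail = []
        if entry.gene_symbol:
            tail.append(f"GN={entry.gene_symbol}")
        tail.append(f"PE={entry.existence.value}")
        records.append(
            SeqRecord(
                Seq(entry.canonical_seq),
                id=f"sp|{entry.accession}|{name}",
                description=" ".join(tail),
            )
        )
        for iso in entry.isoforms:
            records.append(SeqRecord(Seq(iso.seq), id=iso.iso_id, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# feature-table I/O

FEATURE_TABLE_HEADER = "accession\ttarget_form\tkind\tbegin\tend\tpayload"


@dataclass
class RowIssue:
    lineno: int
    message: str


def read_feature_table(
    path, proteome: Proteome, strict: bool = False
) -> tuple[Proteome, list[RowIssue]]:
    """Attach features and isoform alignments from a 6-column TSV.

    Invalid rows are skipped and reported (raised when ``strict``). Returns
    the proteome (mutated in place) and the list of skipped-row reports.
    """
    issues: list[RowIssue] = []

    def problem(lineno: int, message: str) -> None:
        if strict:
            raise ConsistencyError(f"{path}:{lineno}: {message}")
        issues.append(RowIssue(lineno, message))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 or line.startswith("accession\t"):
                continue  # header row
            parts = line.split("\t")
            if len(parts) != 6:
                problem(lineno, f"expected 6 columns, got {len(parts)}")
                continue
            acc, target, kind_s, begin_s, end_s, payload = parts
            if acc not in proteome:
                problem(lineno, f"unknown accession {acc!r}")
                continue
            entry = proteome.get(acc)
            try:
                begin, end = int(begin_s), int(end_s)
            except ValueError:
                problem(lineno, f"non-integer coordinates {begin_s!r}/{end_s!r}")
                continue
            if kind_s == "ALIGN":
                try:
                    iso = entry.isoform(target)
                except ReferenceLookupError as exc:
                    problem(lineno, str(exc))
                    continue
                try:
                    c_start, i_start, length = (int(x) for x in payload.split(","))
                except ValueError:
                    problem(lineno, f"bad ALIGN payload {payload!r}")
                    continue
                iso.alignment.append(Block(c_start, i_start, length))
                iso.alignment.sort(key=lambda b: b.canonical_start)
                continue
            try:
                kind = FeatureKind(kind_s)
            except ValueError:
                problem(lineno, f"unknown feature kind {kind_s!r}")
                continue
            feat = Feature(
                kind=kind,
                target_form=target,
                begin=begin,
                end=end,
                payload=None if payload in ("", "-") else payload,
            )
            try:
                _validate_feature(entry, feat)
            except UnicityError as exc:
                problem(lineno, str(exc))
                continue
            entry.features.append(feat)
    return proteome, issues


def _validate_feature(entry: ProteinEntry, feat: Feature) -> None:
    seq = entry.form_sequence(feat.target_form)
    if not (1 <= feat.begin <= feat.end <= len(seq)):
        raise BoundsError(
            f"{feat.kind.value} {feat.begin}-{feat.end} outside 1..{len(seq)}"
        )
    if feat.kind is FeatureKind.VARIANT:
        if feat.begin != feat.end:
            raise ConsistencyError("VARIANT must cover exactly one residue")
        orig, _ = feat.variant_residues()
        if seq[feat.begin - 1] != orig:
            raise ConsistencyError(
                f"VARIANT claims {orig} at {feat.begin} but sequence has "
                f"{seq[feat.begin - 1]}"
            )


def write_feature_table(proteome: Proteome, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write(FEATURE_TABLE_HEADER + "\n")
        for entry in proteome.entries:
            for iso in entry.isoforms:
                for blk in iso.alignment:
                    fh.write(
                        f"{entry.accession}\t{iso.iso_id}\tALIGN\t0\t0\t"
                        f"{blk.canonical_start},{blk.iso_start},{blk.length}\n"
                    )
            for feat in entry.features:
                payload = feat.payload if feat.payload is not None else "-"
                fh.write(
                    f"{entry.accession}\t{feat.target_form}\t{feat.kind.value}\t"
                    f"{feat.begin}\t{feat.end}\t{payload}\n"
                )


# ---------------------------------------------------------------------------
# coordinate mapping

def map_isoform_position_to_canonical(
    entry: ProteinEntry, iso_id: str, pos: int
) -> Optional[int]:
    """Map a 1-based isoform position to the canonical coordinate.

    Returns ``None`` when the position falls in an isoform-specific region
    (between alignment blocks).
    """
    iso = entry.isoform(iso_id)
    if not (1 <= pos <= len(iso.seq)):
        raise BoundsError(f"{iso_id}: position {pos} outside 1..{len(iso.seq)}")
    for blk in iso.alignment:
        if blk.iso_start <= pos < blk.iso_start + blk.length:
            return blk.canonical_start + (pos - blk.iso_start)
    return None


def map_canonical_position_to_isoform(
    entry: ProteinEntry, iso_id: str, pos: int
) -> Optional[int]:
    """Inverse of :func:`map_isoform_position_to_canonical`."""
    iso = entry.isoform(iso_id)
    if not (1 <= pos <= len(entry.canonical_seq)):
        raise BoundsError(f"{entry.accession}: position {pos} out of range")
    for blk in iso.alignment:
        if blk.canonical_start <= pos < blk.canonical_start + blk.length:
            return blk.iso_start + (pos - blk.canonical_start)
    return None


def derive_deletion_alignment(canonical: str, iso_seq: str) -> list[Block]:
    """Derive alignment blocks for a pure-deletion isoform.

    Only works when the isoform is the canonical with one contiguous
    internal stretch removed; raises :class:`ConsistencyError` otherwise.
    The caller must flag the result as derived, never silently trusted.
    """
    n, m = len(canonical), len(iso_seq)
    if m >= n:
        raise ConsistencyError("isoform is not shorter than canonical")
    prefix = 0
    while prefix < m and canonical[prefix] == iso_seq[prefix]:
        prefix += 1
    suffix = 0
    while suffix < m - prefix and canonical[n - 1 - suffix] == iso_seq[m - 1 - suffix]:
        suffix += 1
    if prefix + suffix != m:
        raise ConsistencyError("not a single-deletion isoform")
    blocks = []
    if prefix:
        blocks.append(Block(1, 1, prefix))
    if suffix:
        blocks.append(Block(n - suffix + 1, m - suffix + 1, suffix))
    return blocks


# ---------------------------------------------------------------------------
# sequence-form enumeration

@dataclass(frozen=True)
class FormOptions:
    apply_variants: bool = True
    include_isoforms: bool = True
    include_processed: bool = True


@dataclass(frozen=True)
class SequenceForm:
    """One concrete digestible string derived from an entry, with provenance.

    ``base`` is the coordinate system the form's positions anchor to
    ("canonical" or an isoform id); ``offset`` is the base position of the
    form's first residue. Variant substitutions keep base coordinates.
    """

    accession: str
    form_id: str
    seq: str
    base: str
    offset: int
    carries_variant: bool = False
    variant_pos: Optional[int] = None  # position within the form

    def base_region(self, start: int, end: int) -> tuple[int, int]:
        """Map a region within the form to base-form coordinates."""
        return self.offset + start - 1, self.offset + end - 1


def enumerate_sequence_forms(
    entry: ProteinEntry, opts: FormOptions = FormOptions()
) -> list[SequenceForm]:
    """Enumerate the digestible proteoform sequences of an entry.

    Emission order is deterministic: canonical, isoforms by id, processed
    products by (kind, begin), then variant-substituted forms by variant
    position (each variant applied to the canonical and to every processed
    product that contains the substituted residue — at most one variant
    per emitted form).
    """
    canonical = SequenceForm(
        accession=entry.accession,
        form_id="canonical",
        seq=entry.canonical_seq,
        base="canonical",
        offset=1,
    )
    forms = [canonical]

    if opts.include_isoforms:
        for iso in sorted(entry.isoforms, key=lambda i: i.iso_id):
            forms.append(
                SequenceForm(
                    accession=entry.accession,
                    form_id=iso.iso_id,
                    seq=iso.seq,
                    base=iso.iso_id,
                    offset=1,
                )
            )

    processed: list[tuple[Feature, SequenceForm]] = []
    if opts.include_processed:
        proc_feats = [
            f for f in entry.features if f.kind.value in PROCESSING_KINDS
        ]
        proc_feats.sort(key=lambda f: (f.kind.value, f.begin, f.end))
        for feat in proc_feats:
            base_seq = entry.form_sequence(feat.target_form)
            form = SequenceForm(
                accession=entry.accession,
                form_id=f"{feat.kind.value}:{feat.begin}-{feat.end}",
                seq=base_seq[feat.begin - 1 : feat.end],
                base=feat.target_form,
                offset=feat.begin,
            )
            processed.append((feat, form))
            forms.append(form)

    if opts.apply_variants:
        variants = [f for f in entry.features if f.kind is FeatureKind.VARIANT]
        variants.sort(key=lambda f: f.begin)
        for var in variants:
            if var.target_form != "canonical":
                continue  # variants are curated in canonical coordinates
            orig, alt = var.variant_residues()
            tag = f"VAR:{var.begin}:{orig}>{alt}"
            mutated = (
                entry.canonical_seq[: var.begin - 1]
                + alt
                + entry.canonical_seq[var.begin :]
            )
            forms.append(
                SequenceForm(
                    accession=entry.accession,
                    form_id=f"canonical|{tag}",
                    seq=mutated,
                    base="canonical",
                    offset=1,
                    carries_variant=True,
                    variant_pos=var.begin,
                )
            )
            for feat, proc_form in processed:
                if feat.target_form != "canonical":
                    continue
                if not (feat.begin <= var.begin <= feat.end):
                    continue
                local = var.begin - feat.begin + 1
                forms.append(
                    SequenceForm(
                        accession=entry.accession,
                        form_id=f"{proc_form.form_id}|{tag}",
                        seq=proc_form.seq[: local - 1] + alt + proc_form.seq[local:],
                        base="canonical",
                        offset=feat.begin,
                        carries_variant=True,
                        variant_pos=local,
                    )
                )
    return forms


def canonical_region_of(
    entry: ProteinEntry, form: SequenceForm, start: int, end: int
) -> tuple[Optional[int], Optional[int]]:
    """Canonical coordinates of a form region, or (None, None).

    Canonical coordinates exist iff the whole region maps inside isoform
    alignment blocks (identically for canonical-based forms, which map by
    offset arithmetic).
    """
    b_start, b_end = form.base_region(start, end)
    if form.base == "canonical":
        return b_start, b_end
    mapped = [
        map_isoform_position_to_canonical(entry, form.base, p)
        for p in range(b_start, b_end + 1)
    ]
    if any(p is None for p in mapped):
        return None, None
    for a, b in zip(mapped, mapped[1:]):
        if b != a + 1:  # region straddles an isoform-specific junction
            return None, None
    return mapped[0], mapped[-1]
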