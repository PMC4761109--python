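"""PTM-site annotation: unicity resolution, biological-relevance rules,
evidence merging, protein-existence promotion, output writers.

Only peptides whose unicity class is unique_protein contribute to site
annotation (the strictest reading of unambiguous assignment); peptides
unique within a gene but shared across entries are reported separately,
not annotated. Accepted sites are merged into canonical-coordinate
annotations carrying the evidence code ECO:0000244 (combined experimental
and computational evidence). Sites on isoform-specific regions keep their
isoform coordinates and are written to a separate output section rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Optional

from .proteome import Existence, FeatureKind, ProteinEntry, Proteome
from .psm import SiteCandidate
from .table import Assignment, UnicityClass, UnicityTable

ECO_COMBINED_EVIDENCE = "ECO:0000244"

# PTM names counted as phosphorylation for the relevance rules
PHOSPHO_PREFIX = "Phospho"


class RelevanceVerdict(Enum):
    accepted = "accepted"
    rejected_transmembrane = "rejected_transmembrane"
    rejected_unmappable = "rejected_unmappable"
    rejected_ambiguous = "rejected_ambiguous"


class Resolution(Enum):
    unique = "unique"
    rejected_ambiguous = "rejected_ambiguous"
    rejected_absent = "rejected_absent"


def resolve_peptide(
    peptide: str, table: UnicityTable
) -> tuple[Resolution, list[Assignment]]:
    """Decide whether a peptide identifies exactly one entry.

    unique_protein peptides proceed with their assignments; unique_gene and
    shared peptides are ambiguous for site annotation (they still count as
    shared evidence in reports); peptides not in the table are absent.
    """
    cls = table.classify(peptide)
    if cls is UnicityClass.absent:
        return Resolution.rejected_absent, []
    if cls is UnicityClass.unique_protein:
        return Resolution.unique, table.lookup(peptide)
    return Resolution.rejected_ambiguous, table.lookup(peptide)


# ---------------------------------------------------------------------------
# biological-relevance rules (pluggable registry)

# A rule sees (entry, ptm_name, canonical_position) for canonically mapped
# sites and returns a verdict or None (no opinion).
RelevanceRule = Callable[[ProteinEntry, str, int], Optional[RelevanceVerdict]]


def transmembrane_phospho_rule(
    entry: ProteinEntry, ptm_name: str, canonical_position: int
) -> Optional[RelevanceVerdict]:
    """A phosphorylation site inside a transmembrane segment is implausible:
    the kinase machinery has no access to residues buried in the bilayer."""
    if not ptm_name.startswith(PHOSPHO_PREFIX):
        return None
    for feat in entry.features:
        if feat.kind is FeatureKind.TRANSMEM and feat.target_form == "canonical":
            if feat.begin <= canonical_position <= feat.end:  # inclusive bounds
                return RelevanceVerdict.rejected_transmembrane
    return None


DEFAULT_RELEVANCE_RULES: tuple[RelevanceRule, ...] = (transmembrane_phospho_rule,)


def check_biological_relevance(
    entry: ProteinEntry,
    ptm_name: str,
    canonical_position: Optional[int],
    *,
    has_isoform_fallback: bool = False,
    emit_isoform_sites: bool = True,
    rules: Iterable[RelevanceRule] = DEFAULT_RELEVANCE_RULES,
) -> RelevanceVerdict:
    """Apply the relevance rule registry to one localized, uniquely-resolved site."""
    if canonical_position is None:
        if has_isoform_fallback and emit_isoform_sites:
            return RelevanceVerdict.accepted
        return RelevanceVerdict.rejected_unmappable
    for rule in rules:
        verdict = rule(entry, ptm_name, canonical_position)
        if verdict is not None:
            return verdict
    return RelevanceVerdict.accepted


# ---------------------------------------------------------------------------
# site resolution

@dataclass(frozen=True)
class ResolvedSite:
    """One accepted localized site occurrence, pre-merge."""

    accession: str
    canonical_position: Optional[int]
    iso_id: Optional[str]
    iso_position: Optional[int]
    ptm_name: str
    dataset_id: str
    spectrum_id: str
    peptide: str


@dataclass(frozen=True)
class SiteRejection:
    dataset_id: str
    spectrum_id: str
    peptide: str
    ptm_name: str
    position: int  # within the peptide
    verdict: RelevanceVerdict


def site_positions_of(
    candidate: SiteCandidate, assignments: Iterable[Assignment]
) -> set[tuple]:
    """Distinct site coordinates implied by a candidate's assignments.

    Each element is ("canonical", pos) or ("iso", iso_id, pos) or
    ("unmapped",). Multiple distinct coordinates mean the peptide occurs
    at several places in the entry, so the site itself is ambiguous.
    """
    positions: set[tuple] = set()
    for a in assignments:
        if a.canonical_start is not None:
            positions.add(("canonical", a.canonical_start + candidate.mod.position - 1))
        elif a.base != "canonical":
            b_start, _ = a.base_region()
            positions.add(("iso", a.base, b_start + candidate.mod.position - 1))
        else:
            positions.add(("unmapped",))
    return positions


def place_site(
    candidate: SiteCandidate,
    assignments: list[Assignment],
    proteome: Proteome,
    *,
    emit_isoform_sites: bool = True,
    rules: Iterable[RelevanceRule] = DEFAULT_RELEVANCE_RULES,
) -> tuple[Optional[ResolvedSite], Optional[SiteRejection]]:
    """Map one localized SiteCandidate through its (unique-entry) assignments
    and run the relevance checks. Returns (site, None) or (None, rejection).
    """
    accession = assignments[0].accession
    entry = proteome.get(accession)
    positions = site_positions_of(candidate, assignments)

    def rejection(verdict: RelevanceVerdict) -> SiteRejection:
        return SiteRejection(
            dataset_id=candidate.record.dataset_id,
            spectrum_id=candidate.record.spectrum_id,
            peptide=candidate.record.peptide,
            ptm_name=candidate.mod.name,
            position=candidate.mod.position,
            verdict=verdict,
        )

    if len(positions) != 1:
        return None, rejection(RelevanceVerdict.rejected_ambiguous)
    (where,) = positions
    canonical_position: Optional[int] = None
    iso_id = iso_position = None
    if where[0] == "canonical":
        canonical_position = where[1]
    elif where[0] == "iso":
        iso_id, iso_position = where[1], where[2]
    verdict = check_biological_relevance(
        entry,
        candidate.mod.name,
        canonical_position,
        has_isoform_fallback=iso_id is not None,
        emit_isoform_sites=emit_isoform_sites,
        rules=rules,
    )
    if verdict is not RelevanceVerdict.accepted:
        return None, rejection(verdict)
    return (
        ResolvedSite(
            accession=accession,
            canonical_position=canonical_position,
            iso_id=iso_id,
            iso_position=iso_position,
            ptm_name=candidate.mod.name,
            dataset_id=candidate.record.dataset_id,
            spectrum_id=candidate.record.spectrum_id,
            peptide=candidate.record.peptide,
        ),
        None,
    )


# ---------------------------------------------------------------------------
# merging

@dataclass
class SiteEvidence:
    accession: str
    canonical_position: Optional[int]
    iso_id: Optional[str]
    iso_position: Optional[int]
    ptm_name: str
    supporting: list[tuple[str, str, str]]  # (dataset_id, spectrum_id, peptide)
    evidence_code: str = ECO_COMBINED_EVIDENCE

    @property
    def n_datasets(self) -> int:
        return len({d for d, _, _ in self.supporting})

    @property
    def position_label(self) -> str:
        if self.canonical_position is not None:
            return str(self.canonical_position)
        return f"{self.iso_id}:{self.iso_position}"


def merge_site_evidence(sites: Iterable[ResolvedSite]) -> list[SiteEvidence]:
    """Group accepted site occurrences by (accession, position, PTM name);
    supporting spectra are deduplicated by (dataset_id, spectrum_id) and the
    output is sorted by accession then position."""
    grouped: dict[tuple, SiteEvidence] = {}
    for s in sites:
        key = (s.accession, s.canonical_position, s.iso_id, s.iso_position, s.ptm_name)
        ev = grouped.get(key)
        if ev is None:
            ev = SiteEvidence(
                accession=s.accession,
                canonical_position=s.canonical_position,
                iso_id=s.iso_id,
                iso_position=s.iso_position,
                ptm_name=s.ptm_name,
                supporting=[],
            )
            grouped[key] = ev
        if all(
            (d, sp) != (s.dataset_id, s.spectrum_id) for d, sp, _ in ev.supporting
        ):
            ev.supporting.append((s.dataset_id, s.spectrum_id, s.peptide))
    out = list(grouped.values())
    out.sort(
        key=lambda e: (
            e.accession,
            e.canonical_position is None,
            e.canonical_position or 0,
            e.iso_id or "",
            e.iso_position or 0,
            e.ptm_name,
        )
    )
    for ev in out:
        ev.supporting.sort()
    return out


# ---------------------------------------------------------------------------
# protein-existence promotion

def promote_protein_existence(
    entry: ProteinEntry, unique_peptide_keys: set[str], k: int = 2
) -> tuple[bool, str]:
    """Promote an entry to protein-level existence when at least ``k``
    distinct validated unique peptides support it. The change is logged,
    never silent: returns (promoted, audit note)."""
    n = len(unique_peptide_keys)
    if entry.existence is Existence.protein_level:
        return False, f"{entry.accession}: already protein_level ({n} peptides)"
    if n >= k:
        entry.existence = Existence.protein_level
        return True, (
            f"{entry.accession}: promoted to protein_level "
            f"({n} distinct unique peptides, threshold {k})"
        )
    return False, (
        f"{entry.accession}: insufficient peptides ({n} < {k}), existence unchanged"
    )


# ---------------------------------------------------------------------------
# output

ANNOTATION_COLUMNS = (
    "accession\tposition\tptm_name\tevidence_code\tn_datasets\tn_spectra\tpeptides"
)


def write_annotations(
    sites: Iterable[SiteEvidence], path, header_meta: Optional[dict] = None
) -> None:
    """Write the annotation TSV (deterministic ordering; provenance header)."""
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(ANNOTATION_COLUMNS + "\n")
        for ev in sites:
            peptides = ",".join(sorted({p for _, _, p in ev.supporting}))
            fh.write(
                f"{ev.accession}\t{ev.position_label}\t{ev.ptm_name}\t"
                f"{ev.evidence_code}\t{ev.n_datasets}\t{len(ev.supporting)}\t"
                f"{peptides}\n"
            )
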