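"""Synthetic proteomes and PSM datasets with planted ground truth.

Every stage of the pipeline is testable without downloading anything: the
generator emits a proteome FASTA + feature table, a PSM table + dataset
metadata, and a manifest recording exactly what was planted (true
phosphosites, sub-threshold decoy PSMs, deliberately ambiguous peptides)
together with the end-to-end summary the pipeline is expected to produce.

Sequences are built from "units": tryptic segments (no internal K/R, not
starting with P, ending in K or R, length 7-12) concatenated per entry, so
every unit is a 0-missed-cleavage tryptic peptide and features planted on
unit boundaries are automatically cleavage-compatible. Units are globally
unique under I/L-equivalent normalization unless deliberately shared
across entries.

Score distributions keep a margin of at least 0.5 from every filter
threshold (true PSMs: Mascot ~ U[45,90], PEP ~ U[0,0.005], Ascore ~
U[20,40]; decoys: Mascot ~ U[10,35], PEP ~ U[0.02,0.5]) so that the
inclusive-vs-strict semantics of the thresholds — which are unit-tested
with exact boundary values — can never flip a fixture outcome.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from .digestion import DigestSpec
from .pipeline import RunSummary
from .proteome import (
    Block,
    ConfigError,
    Existence,
    Feature,
    FeatureKind,
    FormOptions,
    Isoform,
    ProteinEntry,
    Proteome,
)
from .psm import DatasetMetadata, PsmRecord, Modification
from .table import UnicityClass, build_unicity_table, normalize_peptide

_FIRST = "ACDEFGHMNQSTVWYIL"      # unit start: no P (blocks upstream cleavage), no K/R
_INTERIOR = "ACDEFGHMNQSTVWYILP"  # no K/R inside a unit
_TERMINAL = "KR"
_VARIANT_ALTS = "ACDEFGHMNQVWY"   # never K/R/P: substitutions keep the cleavage map

PHOSPHO_NAME = {"S": "Phosphoserine", "T": "Phosphothreonine", "Y": "Phosphotyrosine"}


@dataclass(frozen=True)
class ProteomeParams:
    isoform_prob: float = 0.3
    variant_prob: float = 0.3
    tm_prob: float = 0.4
    chain_prob: float = 0.3
    shared_block_prob: float = 0.1
    min_units: int = 8
    max_units: int = 16
    min_unit_len: int = 7
    max_unit_len: int = 12

    def validate(self) -> None:
        for name in ("isoform_prob", "variant_prob", "tm_prob", "chain_prob",
                     "shared_block_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.min_units < 3 or self.max_units < self.min_units:
            raise ConfigError("need max_units >= min_units >= 3")
        if self.min_unit_len < 3 or self.max_unit_len < self.min_unit_len:
            raise ConfigError("bad unit length range")


@dataclass
class ProteomePlan:
    """Everything the PSM generator needs to know about what was planted."""

    unit_layout: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    # accession -> [(canonical_start, unit_seq), ...]
    tm_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    shared_units: list[str] = field(default_factory=list)  # units in >= 2 entries


def _make_unit(rng: random.Random, params: ProteomeParams) -> str:
    n = rng.randint(params.min_unit_len, params.max_unit_len)
    chars = [rng.choice(_FIRST)]
    chars += [rng.choice(_INTERIOR) for _ in range(n - 2)]
    chars.append(rng.choice(_TERMINAL))
    if not any(c in "ST" for c in chars[:-1]):  # guarantee a phospho-acceptor
        chars[rng.randrange(n - 1)] = rng.choice("ST")
    return "".join(chars)


def generate_proteome(
    n_entries: int,
    params: ProteomeParams = ProteomeParams(),
    seed: int = 0,
) -> tuple[Proteome, ProteomePlan]:
    """Generate a reproducible annotated proteome with planted structure.

    With ``shared_block_prob > 0`` identical tryptic units are planted across
    entries to guarantee shared peptides; with 0, units are globally unique
    under I/L-equivalent keys, so no peptide maps to more than one entry.
    """
    if n_entries < 1:
        raise ConfigError("n_entries must be >= 1")
    params.validate()
    rng = random.Random(seed)
    plan = ProteomePlan()
    seen_keys: set[str] = set()
    share_pool: list[str] = []
    unit_owner: dict[str, set[str]] = {}
    entries: list[ProteinEntry] = []

    for i in range(n_entries):
        acc = f"P{i:05d}"
        n_units = rng.randint(params.min_units, params.max_units)
        units: list[str] = []
        for _ in range(n_units):
            if share_pool and rng.random() < params.shared_block_prob:
                unit = rng.choice(share_pool)
                if unit in units:  # never duplicate a unit inside one entry
                    continue
            else:
                while True:
                    unit = _make_unit(rng, params)
                    key = normalize_peptide(unit)
                    if key not in seen_keys:
                        seen_keys.add(key)
                        break
            units.append(unit)
            unit_owner.setdefault(unit, set()).add(acc)
        if params.shared_block_prob > 0:
            share_pool.extend(units[: max(1, len(units) // 4)])

        n_units = len(units)  # shared-unit draws may skip a slot
        seq = "".join(units)
        starts = []
        pos = 1
        for unit in units:
            starts.append(pos)
            pos += len(unit)
        plan.unit_layout[acc] = list(zip(starts, units))

        entry = ProteinEntry(
            accession=acc,
            canonical_seq=seq,
            entry_name=f"{acc}_TEST",
            gene_symbol=f"GENE{i}",
            existence=rng.choice(
                [Existence.transcript_level, Existence.transcript_level,
                 Existence.predicted]
            ),
        )

        # transmembrane segment spanning 1-2 whole units
        plan.tm_intervals[acc] = []
        if rng.random() < params.tm_prob and n_units >= 5:
            u0 = rng.randrange(1, n_units - 2)
            span = rng.choice([1, 2])
            begin = starts[u0]
            end = starts[u0 + span - 1] + len(units[u0 + span - 1]) - 1
            entry.features.append(
                Feature(FeatureKind.TRANSMEM, "canonical", begin, end)
            )
            plan.tm_intervals[acc].append((begin, end))

        # processed chain on unit boundaries
        if rng.random() < params.chain_prob and n_units >= 6:
            u0 = rng.randrange(1, n_units - 3)
            u1 = rng.randrange(u0 + 1, n_units - 1)
            begin = starts[u0]
            end = starts[u1] + len(units[u1]) - 1
            entry.features.append(Feature(FeatureKind.CHAIN, "canonical", begin, end))

        # single amino-acid variant inside a unit (cleavage-neutral)
        if rng.random() < params.variant_prob:
            u0 = rng.randrange(n_units)
            unit = units[u0]
            local = rng.randrange(1, len(unit) - 1)  # skip first and terminal residue
            pos_c = starts[u0] + local
            orig = seq[pos_c - 1]
            alt = rng.choice([c for c in _VARIANT_ALTS if c != orig])
            entry.features.append(
                Feature(
                    FeatureKind.VARIANT, "canonical", pos_c, pos_c, f"{orig}>{alt}"
                )
            )

        # isoform: deletion of an internal unit-run, or insertion of a new unit
        if rng.random() < params.isoform_prob and n_units >= 5:
            iso_id = f"{acc}-2"
            if rng.random() < 0.5:  # deletion
                u0 = rng.randrange(1, n_units - 2)
                span = rng.choice([1, 2])
                del_start = starts[u0]
                del_len = sum(len(u) for u in units[u0 : u0 + span])
                iso_seq = seq[: del_start - 1] + seq[del_start - 1 + del_len :]
                blocks = [Block(1, 1, del_start - 1)]
                rest = len(seq) - (del_start - 1) - del_len
                if rest:
                    blocks.append(Block(del_start + del_len, del_start, rest))
            else:  # insertion of a brand-new unit between two units
                while True:
                    new_unit = _make_unit(rng, params)
                    key = normalize_peptide(new_unit)
                    if key not in seen_keys:
                        seen_keys.add(key)
                        break
                u0 = rng.randrange(1, n_units - 1)
                ins_at = starts[u0] - 1  # 0-based insertion point
                iso_seq = seq[:ins_at] + new_unit + seq[ins_at:]
                blocks = [Block(1, 1, ins_at)]
                rest = len(seq) - ins_at
                if rest:
                    blocks.append(
                        Block(ins_at + 1, ins_at + len(new_unit) + 1, rest)
                    )
            entry.isoforms.append(
                Isoform(iso_id=iso_id, seq=iso_seq, alignment=blocks)
            )

        entries.append(entry)

    plan.shared_units = sorted(u for u, owners in unit_owner.items() if len(owners) > 1)
    proteome = Proteome(entries=entries, release_tag=f"synthetic-seed{seed}")
    proteome.validate()
    return proteome, plan


# ---------------------------------------------------------------------------
# PSM dataset generation

@dataclass(frozen=True)
class PsmParams:
    n_true_sites: int = 50
    n_decoys: int = 50
    n_ambiguous: int = 20
    n_tm_inside: int = 0  # true-scoring phosphosites planted inside TM segments
    dataset_id: str = "DS1"


@dataclass
class FixtureManifest:
    seed: int
    dataset_id: str
    planted_sites: list[tuple[str, int, str]]       # (accession, canonical pos, PTM)
    tm_planted_sites: list[tuple[str, int, str]]    # expected rejected_transmembrane
    decoy_psms: list[str]                           # spectrum ids
    ambiguous_peptides: list[str]
    expected_summary: RunSummary

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "dataset_id": self.dataset_id,
            "planted_sites": [list(s) for s in self.planted_sites],
            "tm_planted_sites": [list(s) for s in self.tm_planted_sites],
            "decoy_psms": self.decoy_psms,
            "ambiguous_peptides": self.ambiguous_peptides,
            "expected_summary": self.expected_summary.to_dict(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "FixtureManifest":
        return cls(
            seed=data["seed"],
            dataset_id=data["dataset_id"],
            planted_sites=[tuple(s) for s in data["planted_sites"]],
            tm_planted_sites=[tuple(s) for s in data["tm_planted_sites"]],
            decoy_psms=data["decoy_psms"],
            ambiguous_peptides=data["ambiguous_peptides"],
            expected_summary=RunSummary.from_dict(data["expected_summary"]),
        )


def _in_tm(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(b <= pos <= e for b, e in intervals)


def generate_psm_dataset(
    proteome: Proteome,
    plan: ProteomePlan,
    params: PsmParams = PsmParams(),
    seed: int = 0,
    digest_spec: DigestSpec = DigestSpec(),
) -> tuple[list[PsmRecord], DatasetMetadata, FixtureManifest]:
    """Plant true phosphosite PSMs, sub-threshold decoys and ambiguous PSMs.

    True sites are placed on S/T residues of tryptic units that map uniquely
    (unique_protein, single occurrence) and lie outside every transmembrane
    interval; optional ``n_tm_inside`` sites use the same score profile but
    sit inside TM segments, so the relevance rule must reject them. Decoys
    fail identification on both scores. Ambiguous PSMs reuse units planted
    in several entries. The manifest records the planted truth and the
    summary the pipeline must reproduce.
    """
    rng = random.Random(seed)
    table = build_unicity_table(proteome, digest_spec, FormOptions())

    # enumerate candidate sites: (accession, canonical_pos, residue, unit)
    outside_tm: list[tuple[str, int, str, str]] = []
    inside_tm: list[tuple[str, int, str, str]] = []
    for entry in proteome.entries:
        tm = plan.tm_intervals.get(entry.accession, [])
        for start, unit in plan.unit_layout[entry.accession]:
            if table.classify(unit) is not UnicityClass.unique_protein:
                continue
            assignments = table.lookup(unit)
            canon_positions = {
                a.canonical_start for a in assignments if a.canonical_start is not None
            }
            # require a single unambiguous canonical placement of the unit
            if canon_positions != {start}:
                continue
            for local, residue in enumerate(unit[:-1], start=1):
                if residue not in "ST":
                    continue
                pos_c = start + local - 1
                target = inside_tm if _in_tm(pos_c, tm) else outside_tm
                target.append((entry.accession, pos_c, residue, unit))

    if len(outside_tm) < params.n_true_sites:
        raise ConfigError(
            f"only {len(outside_tm)} eligible non-TM sites for "
            f"{params.n_true_sites} requested true sites — enlarge the proteome"
        )
    if params.n_tm_inside and len(inside_tm) < params.n_tm_inside:
        raise ConfigError(
            f"only {len(inside_tm)} eligible in-TM sites for "
            f"{params.n_tm_inside} requested"
        )
    if params.n_ambiguous and not plan.shared_units:
        raise ConfigError(
            "n_ambiguous > 0 requires shared units (shared_block_prob > 0)"
        )

    true_sites = rng.sample(sorted(outside_tm), params.n_true_sites)
    tm_sites = rng.sample(sorted(inside_tm), params.n_tm_inside) if params.n_tm_inside else []

    records: list[PsmRecord] = []
    spectrum = 0

    def good_scores() -> tuple[float, float]:
        return rng.uniform(45.0, 90.0), rng.uniform(0.0, 0.005)

    def planted_record(prefix, acc, pos_c, residue, unit, start) -> PsmRecord:
        nonlocal spectrum
        spectrum += 1
        mascot, pep = good_scores()
        return PsmRecord(
            dataset_id=params.dataset_id,
            spectrum_id=f"{prefix}{spectrum:06d}",
            peptide=unit,
            mods=(
                Modification(
                    position=pos_c - start + 1,
                    name=PHOSPHO_NAME[residue],
                    ascore=round(rng.uniform(20.0, 40.0), 2),
                ),
            ),
            mascot=round(mascot, 2),
            pep=round(pep, 6),
        )

    start_of = {
        (acc, unit): start
        for acc, layout in plan.unit_layout.items()
        for start, unit in layout
    }
    for acc, pos_c, residue, unit in true_sites:
        records.append(
            planted_record("TRUE", acc, pos_c, residue, unit, start_of[(acc, unit)])
        )
    for acc, pos_c, residue, unit in tm_sites:
        records.append(
            planted_record("TMIN", acc, pos_c, residue, unit, start_of[(acc, unit)])
        )

    decoy_ids = []
    all_units = [u for layout in plan.unit_layout.values() for _, u in layout]
    for _ in range(params.n_decoys):
        spectrum += 1
        sid = f"DECOY{spectrum:06d}"
        decoy_ids.append(sid)
        unit = rng.choice(all_units)
        st_positions = [i + 1 for i, c in enumerate(unit[:-1]) if c in "ST"]
        local = rng.choice(st_positions)
        records.append(
            PsmRecord(
                dataset_id=params.dataset_id,
                spectrum_id=sid,
                peptide=unit,
                mods=(
                    Modification(
                        position=local,
                        name=PHOSPHO_NAME[unit[local - 1]],
                        ascore=round(rng.uniform(20.0, 40.0), 2),
                    ),
                ),
                mascot=round(rng.uniform(10.0, 35.0), 2),
                pep=round(rng.uniform(0.02, 0.5), 6),
            )
        )

    ambiguous_used: list[str] = []
    for k in range(params.n_ambiguous):
        spectrum += 1
        unit = plan.shared_units[k % len(plan.shared_units)]
        ambiguous_used.append(unit)
        st_positions = [i + 1 for i, c in enumerate(unit[:-1]) if c in "ST"]
        local = rng.choice(st_positions)
        mascot, pep = good_scores()
        records.append(
            PsmRecord(
                dataset_id=params.dataset_id,
                spectrum_id=f"AMBIG{spectrum:06d}",
                peptide=unit,
                mods=(
                    Modification(
                        position=local,
                        name=PHOSPHO_NAME[unit[local - 1]],
                        ascore=round(rng.uniform(20.0, 40.0), 2),
                    ),
                ),
                mascot=round(mascot, 2),
                pep=round(pep, 6),
            )
        )

    rng.shuffle(records)

    meta = DatasetMetadata(
        dataset_id=params.dataset_id,
        raw_data_location=f"file:///synthetic/{params.dataset_id}/raw",
        instrument="Synthetic Orbitrap",
        search_software="SyntheticSearch 1.0",
        enzyme="trypsin",
        reported_fdr=0.01,
    )

    planted = sorted(
        {(acc, pos, PHOSPHO_NAME[res]) for acc, pos, res, _ in true_sites}
    )
    tm_planted = sorted(
        {(acc, pos, PHOSPHO_NAME[res]) for acc, pos, res, _ in tm_sites}
    )
    unique_keys = {normalize_peptide(u, table.normalization)
                   for _, _, _, u in true_sites}
    unique_keys |= {normalize_peptide(u, table.normalization) for _, _, _, u in tm_sites}
    n_accept = len(true_sites) + len(tm_sites) + params.n_ambiguous
    expected = RunSummary(
        n_input_psms=len(records),
        n_accepted_identifications=n_accept,
        n_validated_unique_peptides=len(unique_keys),
        n_localized_sites=n_accept,  # every planted accepted PSM carries one
        n_annotated_sites=len(planted),
        n_entries_covered=len({acc for acc, _, _ in planted}),
        rejections={
            "identification": params.n_decoys,
            "not_localized": 0,
            "resolution_ambiguous": params.n_ambiguous,
            "resolution_absent": 0,
            "relevance_transmembrane": len(tm_planted),
            "relevance_unmappable": 0,
            "relevance_ambiguous": 0,
        },
    )
    manifest = FixtureManifest(
        seed=seed,
        dataset_id=params.dataset_id,
        planted_sites=planted,
        tm_planted_sites=tm_planted,
        decoy_psms=decoy_ids,
        ambiguous_peptides=sorted(set(ambiguous_used)),
        expected_summary=expected,
    )
    return records, meta, manifest


def write_manifest(manifest: FixtureManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> FixtureManifest:
    with open(path) as fh:
        return FixtureManifest.from_json(json.load(fh))
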