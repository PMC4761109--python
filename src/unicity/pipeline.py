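"""End-to-end orchestration: metadata gating, score filtering, unicity
resolution, relevance checks, evidence merging, reporting.

Stage order: metadata check -> identification filter -> site (localization)
filter -> unicity resolution -> biological-relevance check -> merge ->
write. Every rejection is written to a JSON-lines audit log with its stage
and reason, and counts are conserved at every stage boundary. Outputs are
deterministic: re-running an unchanged configuration reproduces them
byte-for-byte (no timestamps in any output).
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .annotation import (
    DEFAULT_RELEVANCE_RULES,
    RelevanceVerdict,
    Resolution,
    SiteEvidence,
    merge_site_evidence,
    place_site,
    promote_protein_existence,
    resolve_peptide,
    write_annotations,
)
from .digestion import DigestSpec
from .proteome import (
    ConfigError,
    FormOptions,
    Proteome,
    UnicityError,
    read_feature_table,
    read_proteome_fasta,
)
from .psm import (
    DatasetMetadata,
    FilterPolicy,
    PsmRecord,
    apply_identification_filter,
    apply_site_filter,
    read_dataset_metadata,
    read_psm_table,
    validate_dataset_metadata,
)
from .table import (
    UnicityTable,
    build_unicity_table,
    normalize_peptide,
    write_unicity_table,
)

EXIT_OK = 0
EXIT_INPUT_ERROR = 1
EXIT_INTERNAL_ERROR = 2


@dataclass
class RunSummary:
    """The run-level reporting triple and its supporting counts: validated
    peptides are counted as distinct normalized peptide keys, annotated
    sites and covered entries from the emitted evidence."""

    n_input_psms: int = 0
    n_accepted_identifications: int = 0
    n_validated_unique_peptides: int = 0
    n_localized_sites: int = 0
    n_annotated_sites: int = 0
    n_entries_covered: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_psms": self.n_input_psms,
            "n_accepted_identifications": self.n_accepted_identifications,
            "n_validated_unique_peptides": self.n_validated_unique_peptides,
            "n_localized_sites": self.n_localized_sites,
            "n_annotated_sites": self.n_annotated_sites,
            "n_entries_covered": self.n_entries_covered,
            "rejections": dict(sorted(self.rejections.items())),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunSummary":
        return cls(
            n_input_psms=data["n_input_psms"],
            n_accepted_identifications=data["n_accepted_identifications"],
            n_validated_unique_peptides=data["n_validated_unique_peptides"],
            n_localized_sites=data["n_localized_sites"],
            n_annotated_sites=data["n_annotated_sites"],
            n_entries_covered=data["n_entries_covered"],
            rejections=dict(data["rejections"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RunSummary):
            return NotImplemented
        return self.to_dict() == other.to_dict()


REJECTION_KEYS = (
    "identification",
    "not_localized",
    "resolution_ambiguous",
    "resolution_absent",
    "relevance_transmembrane",
    "relevance_unmappable",
    "relevance_ambiguous",
)


@dataclass
class PipelineResult:
    summary: RunSummary
    annotations: list[SiteEvidence]
    isoform_annotations: list[SiteEvidence]
    audit: list[dict]
    extras: dict
    table: UnicityTable
    proteome: Proteome


def run(
    proteome: Proteome,
    datasets: Iterable[tuple[list[PsmRecord], DatasetMetadata]],
    *,
    policy: FilterPolicy = FilterPolicy(),
    digest_spec: DigestSpec = DigestSpec(),
    form_opts: FormOptions = FormOptions(),
    normalization: str = "il_equivalent",
    existence_k: int = 2,
    allow_unverified: bool = False,
    emit_isoform_sites: bool = True,
    relevance_rules=DEFAULT_RELEVANCE_RULES,
    table: Optional[UnicityTable] = None,
) -> PipelineResult:
    """Run the integration pipeline programmatically on parsed inputs."""
    audit: list[dict] = []
    summary = RunSummary(rejections={k: 0 for k in REJECTION_KEYS})

    if table is None:
        table = build_unicity_table(proteome, digest_spec, form_opts, normalization)

    all_accepted: list[PsmRecord] = []
    for records, meta in datasets:
        report = validate_dataset_metadata(meta)
        if not report.verdict and not allow_unverified:
            audit.append(
                {
                    "stage": "metadata",
                    "dataset_id": meta.dataset_id,
                    "reason": f"failed checklist fields: {report.failures}",
                    "n_psms_skipped": len(records),
                }
            )
            continue
        for name, status in report.field_status.items():
            if status == "warning":
                audit.append(
                    {
                        "stage": "metadata",
                        "dataset_id": meta.dataset_id,
                        "reason": f"warning: missing {name}",
                    }
                )
        summary.n_input_psms += len(records)
        accepted, rejected = apply_identification_filter(records, policy)
        all_accepted.extend(accepted)
        summary.rejections["identification"] += len(rejected)
        for rej in rejected:
            audit.append(
                {
                    "stage": "identification",
                    "dataset_id": rej.record.dataset_id,
                    "spectrum_id": rej.record.spectrum_id,
                    "peptide": rej.record.peptide,
                    "reason": rej.reason,
                }
            )
    summary.n_accepted_identifications = len(all_accepted)

    # unicity resolution of accepted peptides (cached per normalized key)
    resolution_cache: dict[str, tuple[Resolution, list]] = {}

    def resolve(peptide: str):
        key = normalize_peptide(peptide, table.normalization)
        if key not in resolution_cache:
            resolution_cache[key] = resolve_peptide(peptide, table)
        return key, resolution_cache[key]

    unique_keys: set[str] = set()
    unique_psm_count = 0
    per_entry_keys: dict[str, set[str]] = {}
    for rec in all_accepted:
        key, (res, assignments) = resolve(rec.peptide)
        if res is Resolution.unique:
            unique_keys.add(key)
            unique_psm_count += 1
            per_entry_keys.setdefault(assignments[0].accession, set()).add(key)
    summary.n_validated_unique_peptides = len(unique_keys)

    # localization filter and site-level pipeline
    candidates = apply_site_filter(all_accepted, policy)
    resolved_sites = []
    for cand in candidates:
        if not cand.localized:
            summary.rejections["not_localized"] += 1
            audit.append(
                {
                    "stage": "localization",
                    "dataset_id": cand.record.dataset_id,
                    "spectrum_id": cand.record.spectrum_id,
                    "peptide": cand.record.peptide,
                    "ptm": cand.mod.name,
                    "position_in_peptide": cand.mod.position,
                    "reason": cand.reason,
                }
            )
            continue
        summary.n_localized_sites += 1
        _key, (res, assignments) = resolve(cand.record.peptide)
        if res is not Resolution.unique:
            reason_key = (
                "resolution_ambiguous"
                if res is Resolution.rejected_ambiguous
                else "resolution_absent"
            )
            summary.rejections[reason_key] += 1
            audit.append(
                {
                    "stage": "resolution",
                    "dataset_id": cand.record.dataset_id,
                    "spectrum_id": cand.record.spectrum_id,
                    "peptide": cand.record.peptide,
                    "ptm": cand.mod.name,
                    "position_in_peptide": cand.mod.position,
                    "reason": res.value,
                }
            )
            continue
        site, rejection = place_site(
            cand,
            assignments,
            proteome,
            emit_isoform_sites=emit_isoform_sites,
            rules=relevance_rules,
        )
        if rejection is not None:
            key = {
                RelevanceVerdict.rejected_transmembrane: "relevance_transmembrane",
                RelevanceVerdict.rejected_unmappable: "relevance_unmappable",
                RelevanceVerdict.rejected_ambiguous: "relevance_ambiguous",
            }[rejection.verdict]
            summary.rejections[key] += 1
            audit.append(
                {
                    "stage": "relevance",
                    "dataset_id": rejection.dataset_id,
                    "spectrum_id": rejection.spectrum_id,
                    "peptide": rejection.peptide,
                    "ptm": rejection.ptm_name,
                    "position_in_peptide": rejection.position,
                    "reason": rejection.verdict.value,
                }
            )
            continue
        resolved_sites.append(site)

    merged = merge_site_evidence(resolved_sites)
    annotations = [e for e in merged if e.canonical_position is not None]
    isoform_annotations = [e for e in merged if e.canonical_position is None]
    summary.n_annotated_sites = len(merged)
    summary.n_entries_covered = len({e.accession for e in merged})

    # protein-existence promotion
    promotions = []
    for accession in sorted(per_entry_keys):
        entry = proteome.get(accession)
        promoted, note = promote_protein_existence(
            entry, per_entry_keys[accession], k=existence_k
        )
        audit.append({"stage": "existence", "accession": accession, "reason": note})
        if promoted:
            promotions.append(accession)

    extras = {
        "n_psms_validated_unique": unique_psm_count,
        "n_annotated_sites_canonical": len(annotations),
        "n_annotated_sites_isoform": len(isoform_annotations),
        "n_entries_promoted": len(promotions),
        "promoted_accessions": promotions,
        "existence_k": existence_k,
    }
    return PipelineResult(
        summary=summary,
        annotations=annotations,
        isoform_annotations=isoform_annotations,
        audit=audit,
        extras=extras,
        table=table,
        proteome=proteome,
    )


# ---------------------------------------------------------------------------
# config-driven entry point

def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config


def _policy_from(config: dict) -> FilterPolicy:
    p = config.get("policy", {}) or {}
    return FilterPolicy(
        mascot_min=float(p.get("mascot_min", 40.0)),
        pep_max=float(p.get("pep_max", 0.01)),
        ascore_min=float(p.get("ascore_min", 19.0)),
        combination=p.get("combination", "any"),
    )


def _digest_from(config: dict) -> DigestSpec:
    d = config.get("digest", {}) or {}
    return DigestSpec(
        enzyme=d.get("enzyme", "trypsin"),
        max_missed=int(d.get("max_missed", 2)),
        min_len=int(d.get("min_len", 7)),
        max_len=int(d.get("max_len", 45)),
    )


def run_from_config(config: dict, base_dir=".") -> PipelineResult:
    """Execute a configured run and write all outputs under ``out_dir``."""
    base = Path(base_dir)

    def resolve_path(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    for key in ("fasta", "datasets", "out_dir"):
        if key not in config:
            raise ConfigError(f"config is missing required key {key!r}")
    fasta = resolve_path(config["fasta"])
    if not fasta.exists():
        raise ConfigError(f"proteome FASTA not found: {fasta}")
    strict = bool(config.get("strict", False))
    proteome = read_proteome_fasta(fasta, release_tag=config.get("release_tag", ""))
    feature_issues = []
    if config.get("features"):
        fpath = resolve_path(config["features"])
        if not fpath.exists():
            raise ConfigError(f"feature table not found: {fpath}")
        _, feature_issues = read_feature_table(fpath, proteome, strict=strict)
    proteome.validate()

    datasets = []
    psm_issues = []
    for ds in config["datasets"]:
        psm_path = resolve_path(ds["psms"])
        if not psm_path.exists():
            raise ConfigError(f"PSM table not found: {psm_path}")
        records, issues = read_psm_table(psm_path, strict=strict)
        psm_issues.extend(issues)
        if ds.get("metadata"):
            meta_path = resolve_path(ds["metadata"])
            if not meta_path.exists():
                raise ConfigError(f"metadata sheet not found: {meta_path}")
            metas = read_dataset_metadata(meta_path)
            ds_id = records[0].dataset_id if records else None
            meta = next(
                (m for m in metas if ds_id is None or m.dataset_id == ds_id),
                metas[0] if metas else None,
            )
            if meta is None:
                raise ConfigError(f"no dataset metadata in {meta_path}")
        else:
            meta = DatasetMetadata(dataset_id=ds.get("dataset_id", "unknown"))
        datasets.append((records, meta))

    policy = _policy_from(config)
    digest_spec = _digest_from(config)
    form_opts = FormOptions(apply_variants=bool(config.get("apply_variants", True)))
    normalization = config.get("normalization", "il_equivalent")

    result = run(
        proteome,
        datasets,
        policy=policy,
        digest_spec=digest_spec,
        form_opts=form_opts,
        normalization=normalization,
        existence_k=int(config.get("existence_k", 2)),
        allow_unverified=bool(config.get("allow_unverified", False)),
        emit_isoform_sites=bool(config.get("emit_isoform_sites", True)),
    )
    for issue in feature_issues:
        result.audit.append(
            {"stage": "feature_table", "line": issue.lineno, "reason": issue.message}
        )
    for issue in psm_issues:
        result.audit.append(
            {"stage": "psm_table", "line": issue.lineno, "reason": issue.message}
        )

    out_dir = resolve_path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    header_meta = {
        "release_tag": proteome.release_tag,
        "digest": digest_spec.describe(),
        "policy": (
            f"mascot_min={policy.mascot_min:g} pep_max={policy.pep_max:g} "
            f"ascore_min={policy.ascore_min:g} combination={policy.combination}"
        ),
        "normalization": normalization,
    }
    write_annotations(result.annotations, out_dir / "annotations.tsv", header_meta)
    write_annotations(
        result.isoform_annotations,
        out_dir / "annotations_isoform.tsv",
        {**header_meta, "coordinates": "isoform-local (iso_id:position)"},
    )
    with open(out_dir / "audit.jsonl", "w") as fh:
        for event in result.audit:
            fh.write(json.dumps(event, sort_keys=True) + "\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            {
                "summary": result.summary.to_dict(),
                "extras": result.extras,
                "provenance": header_meta,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    if config.get("write_unicity_table", False):
        write_unicity_table(
            result.table, out_dir / "unicity.tsv", out_dir / "unicity.meta.json"
        )
    return result


def run_pipeline(config_path, base_dir=None) -> int:
    """CLI-facing wrapper: 0 ok / 1 input error / 2 internal error."""
    try:
        config = load_config(config_path)
        base = base_dir if base_dir is not None else Path(config_path).parent
        result = run_from_config(config, base)
    except (ConfigError, UnicityError, FileNotFoundError, KeyError) as exc:
        print(f"input error: {exc}")
        return EXIT_INPUT_ERROR
    except Exception:
        traceback.print_exc()
        return EXIT_INTERNAL_ERROR
    s = result.summary
    print(
        f"{s.n_validated_unique_peptides} peptides passed the filtering steps, "
        f"supporting {s.n_annotated_sites} PTM sites in "
        f"{s.n_entries_covered} entries"
    )
    return EXIT_OK
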