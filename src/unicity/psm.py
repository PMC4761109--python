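"""PSM ingestion, dataset-metadata checks, and score-threshold filtering.

Spectra are never re-searched; filtering applies stringent cut-offs to the
scores reported with each peptide-spectrum match. A PSM is accepted for
identification when its Mascot score is >= 40 or its posterior error
probability (PEP) is < 1%. A modification site is considered localized
when its Ascore is >= 19; a non-localized site is excluded from site
annotation but its peptide still counts as existence evidence. The
"minimum" thresholds (Mascot, Ascore) are inclusive; the PEP bound is
strict. Missing scores never default to zero — missingness is its own
rejection reason so audit trails stay honest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .proteome import ConfigError, ConsistencyError, RowIssue

PSM_TABLE_COLUMNS = ["dataset_id", "spectrum_id", "peptide", "mods", "mascot", "pep"]


@dataclass(frozen=True)
class Modification:
    position: int  # 1-based within the peptide
    name: str      # controlled-vocabulary PTM name, e.g. "Phosphoserine"
    ascore: Optional[float] = None


@dataclass(frozen=True)
class PsmRecord:
    dataset_id: str
    spectrum_id: str
    peptide: str
    mods: tuple[Modification, ...] = ()
    mascot: Optional[float] = None
    pep: Optional[float] = None


@dataclass(frozen=True)
class FilterPolicy:
    """Identification / localization thresholds.

    ``combination="any"`` accepts a PSM when either score passes (the
    default); ``"all"`` demands both Mascot and PEP present and passing.
    """

    mascot_min: float = 40.0
    pep_max: float = 0.01
    ascore_min: float = 19.0
    combination: str = "any"

    def __post_init__(self) -> None:
        for name in ("mascot_min", "pep_max", "ascore_min"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0")
        if self.combination not in ("any", "all"):
            raise ConfigError("combination must be 'any' or 'all'")


@dataclass
class DatasetMetadata:
    dataset_id: str
    raw_data_location: str = ""
    instrument: str = ""
    search_software: str = ""
    enzyme: str = ""
    reported_fdr: Optional[float] = None


# ---------------------------------------------------------------------------
# ingestion

def _parse_mods(text: str, peptide_len: int) -> tuple[Modification, ...]:
    """Parse ``pos:NAME:ascore;…`` (ascore may be empty = missing)."""
    if not text or text == "-":
        return ()
    mods = []
    for chunk in text.split(";"):
        parts = chunk.split(":")
        if len(parts) == 2:
            pos_s, name = parts
            ascore_s = ""
        elif len(parts) == 3:
            pos_s, name, ascore_s = parts
        else:
            raise ConsistencyError(f"malformed modification {chunk!r}")
        try:
            pos = int(pos_s)
        except ValueError:
            raise ConsistencyError(f"non-integer mod position {pos_s!r}") from None
        if not (1 <= pos <= peptide_len):
            raise ConsistencyError(
                f"mod position {pos} outside 1..{peptide_len} of peptide"
            )
        if not name:
            raise ConsistencyError(f"empty PTM name in {chunk!r}")
        ascore = float(ascore_s) if ascore_s else None
        mods.append(Modification(position=pos, name=name, ascore=ascore))
    return tuple(mods)


def read_psm_table(
    path, strict: bool = False
) -> tuple[list[PsmRecord], list[RowIssue]]:
    """Read the canonical PSM TSV dialect.

    Header ``dataset_id spectrum_id peptide mods mascot pep``; modifications
    encoded ``pos:NAME:ascore;…``. Missing numeric fields stay missing.
    Malformed rows are skipped and reported (raised when ``strict``).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing_cols = [c for c in PSM_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ConsistencyError(f"{path}: missing columns {missing_cols}")
    records: list[PsmRecord] = []
    issues: list[RowIssue] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            peptide = row.peptide.strip().upper()
            if not peptide:
                raise ConsistencyError("empty peptide")
            mods = _parse_mods(row.mods.strip(), len(peptide))
            mascot = float(row.mascot) if row.mascot.strip() else None
            pep = float(row.pep) if row.pep.strip() else None
            if pep is not None and not (0.0 <= pep <= 1.0):
                raise ConsistencyError(f"PEP {pep} outside [0, 1]")
            records.append(
                PsmRecord(
                    dataset_id=row.dataset_id,
                    spectrum_id=row.spectrum_id,
                    peptide=peptide,
                    mods=mods,
                    mascot=mascot,
                    pep=pep,
                )
            )
        except (ConsistencyError, ValueError) as exc:
            if strict:
                raise ConsistencyError(f"{path}:{idx}: {exc}") from exc
            issues.append(RowIssue(idx, str(exc)))
    return records, issues


def write_psm_table(records: Iterable[PsmRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_TABLE_COLUMNS) + "\n")
        for r in records:
            mods = ";".join(
                f"{m.position}:{m.name}:{'' if m.ascore is None else f'{m.ascore:g}'}"
                for m in r.mods
            )
            mascot = "" if r.mascot is None else f"{r.mascot:g}"
            pep = "" if r.pep is None else f"{r.pep:g}"
            fh.write(
                f"{r.dataset_id}\t{r.spectrum_id}\t{r.peptide}\t{mods}\t"
                f"{mascot}\t{pep}\n"
            )


# ---------------------------------------------------------------------------
# dataset-metadata (MIAPE-style) checklist

REQUIRED_METADATA_FIELDS = ("raw_data_location", "instrument", "search_software")
WARNING_METADATA_FIELDS = ("enzyme", "reported_fdr")


@dataclass
class MetadataReport:
    dataset_id: str
    field_status: dict[str, str]  # "pass" | "fail" | "warning"
    verdict: bool

    @property
    def failures(self) -> list[str]:
        return [f for f, s in self.field_status.items() if s == "fail"]


def validate_dataset_metadata(meta: DatasetMetadata) -> MetadataReport:
    """Minimum-information checklist: a dataset without access to raw data,
    instrument or search software is not considered for integration."""
    status: dict[str, str] = {}
    for name in REQUIRED_METADATA_FIELDS:
        value = getattr(meta, name)
        status[name] = "pass" if str(value or "").strip() else "fail"
    for name in WARNING_METADATA_FIELDS:
        value = getattr(meta, name)
        present = value is not None and str(value).strip() != ""
        status[name] = "pass" if present else "warning"
    return MetadataReport(
        dataset_id=meta.dataset_id,
        field_status=status,
        verdict=all(s != "fail" for s in status.values()),
    )


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class Rejection:
    record: PsmRecord
    reason: str


def apply_identification_filter(
    records: Iterable[PsmRecord], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[PsmRecord], list[Rejection]]:
    """Partition PSMs into accepted / rejected-with-reason.

    ``any`` mode: accept iff Mascot >= mascot_min OR PEP < pep_max (missing
    scores cannot satisfy a branch). ``all`` mode: both must be present and
    pass. The partition is exhaustive and disjoint.
    """
    accepted: list[PsmRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        mascot_ok = rec.mascot is not None and rec.mascot >= policy.mascot_min
        pep_ok = rec.pep is not None and rec.pep < policy.pep_max
        if rec.mascot is None and rec.pep is None:
            rejected.append(Rejection(rec, "no usable score"))
            continue
        ok = (mascot_ok or pep_ok) if policy.combination == "any" else (
            mascot_ok and pep_ok
        )
        if ok:
            accepted.append(rec)
        else:
            reasons = []
            if not mascot_ok:
                reasons.append(
                    "mascot missing" if rec.mascot is None
                    else f"mascot {rec.mascot:g} < {policy.mascot_min:g}"
                )
            if not pep_ok:
                reasons.append(
                    "pep missing" if rec.pep is None
                    else f"pep {rec.pep:g} >= {policy.pep_max:g}"
                )
            rejected.append(Rejection(rec, "; ".join(reasons)))
    return accepted, rejected


@dataclass(frozen=True)
class SiteCandidate:
    record: PsmRecord
    mod: Modification
    localized: bool
    reason: str = ""


def apply_site_filter(
    records: Iterable[PsmRecord], policy: FilterPolicy = FilterPolicy()
) -> list[SiteCandidate]:
    """One SiteCandidate per modification on identification-accepted PSMs.

    localized=True iff the Ascore is present and >= ascore_min. Non-localized
    candidates are retained (the peptide still supports protein existence)
    but excluded from site annotation downstream.
    """
    candidates: list[SiteCandidate] = []
    for rec in records:
        for mod in rec.mods:
            if mod.ascore is None:
                candidates.append(
                    SiteCandidate(rec, mod, False, "no localization score")
                )
            elif mod.ascore >= policy.ascore_min:
                candidates.append(SiteCandidate(rec, mod, True))
            else:
                candidates.append(
                    SiteCandidate(
                        rec, mod, False,
                        f"ascore {mod.ascore:g} < {policy.ascore_min:g}",
                    )
                )
    return candidates


# metadata sheet I/O (TSV or JSON)

def read_dataset_metadata(path) -> list[DatasetMetadata]:
    """Read a metadata sheet; JSON (list of objects) or TSV by extension."""
    import json

    path = str(path)
    metas: list[DatasetMetadata] = []
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict):
            data = [data]
        for obj in data:
            metas.append(
                DatasetMetadata(
                    dataset_id=obj.get("dataset_id", ""),
                    raw_data_location=obj.get("raw_data_location", ""),
                    instrument=obj.get("instrument", ""),
                    search_software=obj.get("search_software", ""),
                    enzyme=obj.get("enzyme", ""),
                    reported_fdr=obj.get("reported_fdr"),
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            fdr = getattr(row, "reported_fdr", "")
            metas.append(
                DatasetMetadata(
                    dataset_id=row.dataset_id,
                    raw_data_location=getattr(row, "raw_data_location", ""),
                    instrument=getattr(row, "instrument", ""),
                    search_software=getattr(row, "search_software", ""),
                    enzyme=getattr(row, "enzyme", ""),
                    reported_fdr=float(fdr) if str(fdr).strip() else None,
                )
            )
    for meta in metas:
        if not meta.dataset_id:
            raise ConsistencyError(f"{path}: dataset with empty dataset_id")
    return metas
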