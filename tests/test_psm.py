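"""PSM ingestion, metadata checklist, and score-threshold filtering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unicity import (
    DatasetMetadata,
    FilterPolicy,
    Modification,
    PsmRecord,
    apply_identification_filter,
    apply_site_filter,
    read_psm_table,
    validate_dataset_metadata,
    write_psm_table,
)
from unicity.proteome import ConfigError, ConsistencyError

HEADER = "dataset_id\tspectrum_id\tpeptide\tmods\tmascot\tpep\n"


def psm(mascot=None, pep=None, mods=(), peptide="SAMPLEK"):
    return PsmRecord(
        dataset_id="DS1",
        spectrum_id="S1",
        peptide=peptide,
        mods=tuple(mods),
        mascot=mascot,
        pep=pep,
    )


class TestReadPsmTable:
    def test_empty_mods_field(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(HEADER + "DS1\tS1\tSAMPK\t\t55.0\t0.001\n")
        records, issues = read_psm_table(path)
        assert not issues
        assert records[0].mods == ()
        assert records[0].mascot == 55.0 and records[0].pep == 0.001

    def test_mod_with_ascore(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(HEADER + "DS1\tS1\tSAMPK\t3:Phosphoserine:25.0\t55.0\t0.001\n")
        records, _ = read_psm_table(path)
        assert records[0].mods == (Modification(3, "Phosphoserine", 25.0),)

    def test_missing_scores_stay_missing(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(HEADER + "DS1\tS1\tSAMPK\t\t\t\n")
        records, _ = read_psm_table(path)
        assert records[0].mascot is None and records[0].pep is None

    def test_mod_position_out_of_range_is_row_error(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(HEADER + "DS1\tS1\tSAMPK\t9:Phosphoserine:25.0\t55.0\t0.001\n")
        records, issues = read_psm_table(path)
        assert records == [] and len(issues) == 1
        with pytest.raises(ConsistencyError):
            read_psm_table(path, strict=True)

    def test_missing_ascore_in_mods(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(HEADER + "DS1\tS1\tSAMPK\t3:Phosphoserine:\t55.0\t\n")
        records, _ = read_psm_table(path)
        assert records[0].mods[0].ascore is None

    def test_write_read_round_trip(self, tmp_path):
        records = [
            psm(mascot=55.5, pep=0.001, mods=[Modification(3, "Phosphoserine", 25.0)]),
            psm(mascot=None, pep=0.5, mods=[Modification(1, "Phosphothreonine", None)],
                peptide="TAMPK"),
        ]
        write_psm_table(records, tmp_path / "psm.tsv")
        again, issues = read_psm_table(tmp_path / "psm.tsv")
        assert not issues and again == records


class TestMetadataChecklist:
    def full(self):
        return DatasetMetadata(
            dataset_id="DS1",
            raw_data_location="https://repository.example/raw",
            instrument="QExactive",
            search_software="Mascot 2.5",
            enzyme="trypsin",
            reported_fdr=0.01,
        )

    def test_all_fields_present_passes(self):
        assert validate_dataset_metadata(self.full()).verdict is True

    def test_missing_raw_data_fails_naming_field(self):
        meta = self.full()
        meta.raw_data_location = ""
        report = validate_dataset_metadata(meta)
        assert report.verdict is False
        assert report.failures == ["raw_data_location"]

    def test_missing_fdr_is_warning_grade(self):
        meta = self.full()
        meta.reported_fdr = None
        report = validate_dataset_metadata(meta)
        assert report.verdict is True
        assert report.field_status["reported_fdr"] == "warning"


class TestIdentificationFilter:
    def test_mascot_threshold_is_inclusive(self):
        accepted, rejected = apply_identification_filter([psm(mascot=40.0)])
        assert len(accepted) == 1 and not rejected

    def test_pep_branch_rescues_low_mascot(self):
        accepted, _ = apply_identification_filter([psm(mascot=39.0, pep=0.005)])
        assert len(accepted) == 1

    def test_both_branches_fail(self):
        accepted, rejected = apply_identification_filter([psm(mascot=39.0, pep=0.02)])
        assert not accepted and len(rejected) == 1

    def test_no_usable_score_has_distinct_reason(self):
        _, rejected = apply_identification_filter([psm()])
        assert rejected[0].reason == "no usable score"

    def test_conjunctive_mode_requires_both(self):
        policy = FilterPolicy(combination="all")
        accepted, _ = apply_identification_filter(
            [psm(mascot=50.0, pep=0.005), psm(mascot=50.0), psm(pep=0.005)], policy
        )
        assert len(accepted) == 1

    def test_invalid_policy_rejected(self):
        with pytest.raises(ConfigError):
            FilterPolicy(mascot_min=-1)
        with pytest.raises(ConfigError):
            FilterPolicy(combination="either")


class TestSiteFilter:
    def test_ascore_threshold_inclusive(self):
        records = [psm(mascot=50.0, mods=[Modification(1, "Phosphoserine", 19.0)])]
        (cand,) = apply_site_filter(records)
        assert cand.localized is True

    def test_below_threshold_not_localized(self):
        records = [psm(mascot=50.0, mods=[Modification(1, "Phosphoserine", 18.9)])]
        (cand,) = apply_site_filter(records)
        assert cand.localized is False

    def test_missing_ascore_reason(self):
        records = [psm(mascot=50.0, mods=[Modification(1, "Phosphoserine", None)])]
        (cand,) = apply_site_filter(records)
        assert cand.localized is False and cand.reason == "no localization score"

    def test_one_candidate_per_mod(self):
        records = [
            psm(
                mascot=50.0,
                mods=[
                    Modification(1, "Phosphoserine", 30.0),
                    Modification(3, "Phosphothreonine", 10.0),
                ],
            )
        ]
        candidates = apply_site_filter(records)
        assert [c.localized for c in candidates] == [True, False]


def random_records(n, seed):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        out.append(
            PsmRecord(
                dataset_id="DS1",
                spectrum_id=f"S{i}",
                peptide="SAMPLEK",
                mods=(Modification(1, "Phosphoserine",
                                   rng.uniform(0, 40) if rng.random() < 0.9 else None),),
                mascot=rng.uniform(0, 80) if rng.random() < 0.9 else None,
                pep=rng.uniform(0, 0.05) if rng.random() < 0.9 else None,
            )
        )
    return out


class TestFilterProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0, 80), st.floats(0, 0.05), st.floats(0, 40),
        st.floats(0, 20), st.floats(0, 0.02), st.floats(0, 10),
    )
    def test_stricter_policy_accepts_subset(self, seed, m, p, a, dm, dp, da):
        records = random_records(300, seed)
        loose = FilterPolicy(mascot_min=m, pep_max=p + dp, ascore_min=a)
        strict = FilterPolicy(mascot_min=m + dm, pep_max=p, ascore_min=a + da)
        acc_loose, _ = apply_identification_filter(records, loose)
        acc_strict, _ = apply_identification_filter(records, strict)
        assert set(r.spectrum_id for r in acc_strict) <= set(
            r.spectrum_id for r in acc_loose
        )
        loc_loose = sum(c.localized for c in apply_site_filter(acc_loose, loose))
        loc_strict = sum(c.localized for c in apply_site_filter(acc_strict, strict))
        assert loc_strict <= loc_loose

    def test_partition_is_exhaustive_and_disjoint(self):
        records = random_records(500, seed=1)
        accepted, rejected = apply_identification_filter(records)
        assert len(accepted) + len(rejected) == len(records)
        ids = [r.spectrum_id for r in accepted] + [
            r.record.spectrum_id for r in rejected
        ]
        assert sorted(ids) == sorted(r.spectrum_id for r in records)

    def test_filter_is_idempotent(self):
        records = random_records(500, seed=2)
        accepted, _ = apply_identification_filter(records)
        again, rejected = apply_identification_filter(accepted)
        assert again == accepted and not rejected
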