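"""Non-response label construction from treatment records.

A patient is a non-responder to a drug (label 1) if they discontinued that
drug for clinical non-response reasons or died while being treated with it.
The per-drug cohort is the set of patients who received that drug; the
pooled aromatase-inhibitor task (``ALL_AI``) uses patients who received any
of anastrozole, exemestane or letrozole and labels them 1 on non-response to
any of them. Patients with estrogen-receptor-negative tumors who never
received an aromatase inhibitor are known a priori not to respond and can be
appended as prior-knowledge positives.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import AI_DRUGS, ALL_AI, LabelVector, TreatmentRecord
from .errors import ValidationError

#: brand-name and spelling normalization for the three aromatase inhibitors
_DRUG_ALIASES = {
    "anastrozole": "anastrozole",
    "arimidex": "anastrozole",
    "exemestane": "exemestane",
    "aromasin": "exemestane",
    "letrozole": "letrozole",
    "femara": "letrozole",
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def canonicalize_drug(name: str) -> str:
    """Map a drug name (brand or generic, any case) to its canonical generic
    name, or ``"other"`` for non-aromatase-inhibitor drugs."""
    return _DRUG_ALIASES.get(str(name).strip().lower(), "other")


def _parse_flag(value, field: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text == "nan":
        return False
    raise ValidationError(f"cannot interpret {field}={value!r} as a boolean flag")


def read_treatment_records(path) -> list[TreatmentRecord]:
    """Read the treatment CSV: patient_id, drug, discontinued,
    died_on_treatment, er_status."""
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "drug", "discontinued", "died_on_treatment", "er_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"treatment file missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        er = str(row.er_status).strip().lower()
        if er not in ("positive", "negative", "unknown"):
            er = {"pos": "positive", "+": "positive", "neg": "negative", "-": "negative"}.get(er, "unknown")
        records.append(
            TreatmentRecord(
                patient_id=str(row.patient_id).strip().upper(),
                drug=canonicalize_drug(row.drug),
                discontinued_for_nonresponse=_parse_flag(row.discontinued, "discontinued"),
                died_during_treatment=_parse_flag(row.died_on_treatment, "died_on_treatment"),
                er_status=er,
            )
        )
    return records


def write_treatment_records(records: list[TreatmentRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "drug": r.drug,
            "discontinued": int(r.discontinued_for_nonresponse),
            "died_on_treatment": int(r.died_during_treatment),
            "er_status": r.er_status,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_conflicts(records: list[TreatmentRecord]) -> None:
    seen: dict[tuple[str, str], tuple[bool, bool]] = {}
    for r in records:
        key = (r.patient_id, r.drug)
        flags = (r.discontinued_for_nonresponse, r.died_during_treatment)
        if key in seen and seen[key] != flags:
            raise ValidationError(f"conflicting duplicate treatment records for {key}")
        seen[key] = flags


def build_labels(records: list[TreatmentRecord], drug: str = ALL_AI) -> LabelVector:
    """Build the non-response label vector for one drug or the pooled task.

    The cohort is every patient with a record for the requested drug (for
    ``ALL_AI``: any aromatase inhibitor); label 1 iff the discontinuation or
    on-treatment-death flag is set for a qualifying record, else 0. Labels
    are order-independent in the records. Conflicting duplicate records for
    the same (patient, drug) raise an error.
    """
    if drug != ALL_AI and drug not in AI_DRUGS:
        raise ValidationError(f"drug must be one of {AI_DRUGS} or {ALL_AI!r}, got {drug!r}")
    _check_conflicts(records)
    qualifying = set(AI_DRUGS) if drug == ALL_AI else {drug}
    labels: dict[str, int] = {}
    for r in records:
        if r.drug not in qualifying:
            continue
        positive = r.discontinued_for_nonresponse or r.died_during_treatment
        labels[r.patient_id] = max(labels.get(r.patient_id, 0), int(positive))
    data = pd.DataFrame(
        {"label": pd.Series(labels, dtype=int), "source": "observed"}
    ).sort_index()
    return LabelVector(data)


def augment_er_negative(labels: LabelVector, records: list[TreatmentRecord]) -> LabelVector:
    """Append estrogen-receptor-negative patients who are not in the treated
    cohort as prior-knowledge non-responders (label 1, tagged
    ``er_negative_prior``). Patients already in the cohort keep their
    observed label — prior knowledge never overrides an observation."""
    cohort = set(labels.sample_ids)
    er_negative = {r.patient_id for r in records if r.er_status == "negative"}
    extra = sorted(er_negative - cohort)
    if not extra:
        return LabelVector(labels.data.copy())
    addition = pd.DataFrame({"label": 1, "source": "er_negative_prior"}, index=extra)
    data = pd.concat([labels.data, addition]).sort_index()
    return LabelVector(data)
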