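"""Shared fixtures: hand-built reports and FAERS-dialect quarter writers."""

from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest

from faersig.ingest import DrugEntry, IcsrReport


def make_report(
    pid: str = "1",
    case_id: str | None = None,
    receipt: date | None = date(2020, 6, 1),
    event: date | None = date(2020, 1, 15),
    sex: str = "male",
    age: float | None = 50.0,
    weight: float | None = None,
    country: str | None = "US",
    outcomes: set[str] | None = None,
    occupation: str | None = "MD",
    drugs: tuple = (("ADEFOVIR", "PS", date(2019, 1, 1)),),
    reactions: set[str] = frozenset({"osteoporosis"}),
) -> IcsrReport:
    entries = tuple(
        DrugEntry(drug_name=name, role_code=role, therapy_start=start)
        for name, role, start in drugs
    )
    return IcsrReport(
        primary_id=pid,
        case_id=case_id if case_id is not None else pid,
        receipt_date=receipt,
        event_date=event,
        sex=sex,
        age_years=age,
        weight_kg=weight,
        country=country,
        outcome_codes=frozenset(outcomes or set()),
        reporter_occupation=occupation,
        drugs=entries,
        reactions=frozenset(reactions),
    )


@pytest.fixture
def report_factory():
    return make_report


def write_quarter(
    directory: Path,
    demo_rows: list[dict],
    drug_rows: list[dict],
    reac_rows: list[dict],
    ther_rows: list[dict] | None = None,
    outc_rows: list[dict] | None = None,
) -> dict[str, Path]:
    """Write hand-built '$'-delimited quarter tables."""
    directory.mkdir(parents=True, exist_ok=True)
    columns = {
        "DEMO": ["primaryid", "caseid", "event_dt", "fda_dt", "age", "age_cod",
                 "sex", "wt", "wt_cod", "occp_cod", "occr_country"],
        "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
        "REAC": ["primaryid", "pt"],
        "THER": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
        "OUTC": ["primaryid", "outc_cod"],
    }
    tables = {
        "DEMO": demo_rows,
        "DRUG": drug_rows,
        "REAC": reac_rows,
        "THER": ther_rows or [],
        "OUTC": outc_rows or [],
    }
    paths = {}
    for name, rows in tables.items():
        path = directory / f"{name}.txt"
        cols = columns[name]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("$".join(cols) + "\n")
            for row in rows:
                fh.write("$".join(str(row.get(col, "")) for col in cols) + "\n")
        paths[f"{name.lower()}_path"] = path
    return paths


@pytest.fixture
def quarter_writer(tmp_path):
    def _write(**kwargs):
        return write_quarter(tmp_path / "quarter", **kwargs)

    return _write
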