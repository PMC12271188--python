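"""Reading and cleaning FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
'$'-delimited ASCII tables keyed on a report identifier (``primaryid``):
demographics (DEMO), drugs with their reporter-assigned role codes (DRUG),
reaction preferred terms (REAC), therapy date ranges (THER) and outcome codes
(OUTC).  This module joins those tables into :class:`IcsrReport` records,
removes duplicate reports with the two-stage rule used in pharmacovigilance
practice (latest case version, then collapse of six-field redundant
resubmissions) and restricts collections to reports naming a given drug as
the primary suspect.

Only the post-2012 column set is supported.  Rows that cannot be parsed are
counted in a :class:`ParseLog` rather than silently dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ROLE_CODES",
    "OUTCOME_CODES",
    "DrugEntry",
    "IcsrReport",
    "ParseLog",
    "IngestResult",
    "normalize_drug_name",
    "normalize_pt",
    "parse_faers_date",
    "read_quarter",
    "discover_quarters",
    "read_directory",
    "deduplicate",
    "filter_primary_suspect",
]

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS patient outcome codes (congenital anomaly, death, disability,
#: hospitalisation, life-threatening, other, required intervention).
OUTCOME_CODES = ("CA", "DE", "DS", "HO", "LT", "OT", "RI")

# FAERS age-unit codes -> multiplier to years.  Unknown codes leave age missing.
_AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}

_SEX_MAP = {"M": "male", "F": "female"}


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim and collapse internal whitespace.

    Matching is exact after normalization; no ingredient/brand mapping is
    attempted.
    """
    return " ".join(str(name).upper().split())


def normalize_pt(term: str) -> str:
    """Lowercase, trim and collapse internal whitespace of a MedDRA PT."""
    return " ".join(str(term).lower().split())


def parse_faers_date(raw: object) -> tuple[date | None, bool]:
    """Parse a FAERS date string (YYYYMMDD, YYYYMM or YYYY).

    Missing day or month components are completed to the 1st; the second
    element of the returned tuple flags such imputation.  Unparseable or
    empty values yield ``(None, False)``.
    """
    if raw is None:
        return None, False
    s = str(raw).strip().replace("-", "")
    if s.endswith(".0"):  # numeric round trip through spreadsheets
        s = s[:-2]
    if not s.isdigit():
        return None, False
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1), True
        if len(s) == 4:
            return date(int(s), 1, 1), True
    except ValueError:
        return None, False
    return None, False


@dataclass(frozen=True)
class DrugEntry:
    """One drug on a report: normalized name, FAERS role code, therapy dates."""

    drug_name: str
    role_code: str
    therapy_start: date | None = None
    therapy_end: date | None = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"invalid role code {self.role_code!r}")
        if (
            self.therapy_start is not None
            and self.therapy_end is not None
            and self.therapy_end < self.therapy_start
        ):
            raise ValueError("therapy_end precedes therapy_start")


@dataclass(frozen=True)
class IcsrReport:
    """One individual case safety report after table joining.

    ``reactions`` holds normalized (lowercase) MedDRA preferred terms;
    ``drugs`` preserves DRUG-file order.  ``event_date_imputed`` marks event
    dates whose day/month had to be completed to the 1st.
    """

    primary_id: str
    case_id: str
    receipt_date: date | None
    event_date: date | None
    sex: str
    age_years: float | None
    weight_kg: float | None
    country: str | None
    outcome_codes: frozenset[str]
    reporter_occupation: str | None
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    event_date_imputed: bool = False

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.weight_kg is not None and self.weight_kg < 0:
            raise ValueError("weight_kg must be non-negative")

    def drug_names(self) -> frozenset[str]:
        return frozenset(d.drug_name for d in self.drugs)

    def has_primary_suspect(self, drug_name: str) -> bool:
        target = normalize_drug_name(drug_name)
        return any(d.drug_name == target and d.role_code == "PS" for d in self.drugs)


@dataclass
class ParseLog:
    """Rows skipped or repaired during ingestion: (file, line, reason)."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, file: str, line: int, reason: str) -> None:
        self.entries.append((file, line, reason))

    def count(self, reason_substring: str | None = None) -> int:
        if reason_substring is None:
            return len(self.entries)
        return sum(1 for _, _, r in self.entries if reason_substring in r)

    def extend(self, other: "ParseLog") -> None:
        self.entries.extend(other.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("file\tline\treason\n")
            for file, line, reason in self.entries:
                fh.write(f"{file}\t{line}\t{reason}\n")


@dataclass
class IngestResult:
    reports: list[IcsrReport]
    log: ParseLog

    def __iter__(self):
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required FAERS table missing: {path}")
    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        quoting=csv.QUOTE_NONE,
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _blank(value: object) -> bool:
    return str(value).strip() == ""


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    ther_path: str | Path,
    outc_path: str | Path,
) -> IngestResult:
    """Join one quarter's DEMO/DRUG/REAC/THER/OUTC tables into reports.

    Produces one :class:`IcsrReport` per joinable DEMO row.  DEMO rows with
    no reaction row, and orphan rows in the satellite tables, are counted in
    the parse log and skipped.
    """
    log = ParseLog()
    demo = _read_table(demo_path, ["primaryid"])
    drug = _read_table(drug_path, ["primaryid", "role_cod", "drugname"])
    reac = _read_table(reac_path, ["primaryid", "pt"])
    ther = _read_table(ther_path, ["primaryid", "dsg_drug_seq", "start_dt"])
    outc = _read_table(outc_path, ["primaryid", "outc_cod"])

    demo_name = Path(demo_path).name
    drug_name_f = Path(drug_path).name
    reac_name = Path(reac_path).name
    ther_name = Path(ther_path).name
    outc_name = Path(outc_path).name

    demo_pids: set[str] = set()
    for i, pid in enumerate(demo["primaryid"]):
        if not _blank(pid):
            demo_pids.add(str(pid).strip())

    # --- reactions -------------------------------------------------------
    reac_by_pid: dict[str, set[str]] = {}
    for i, row in enumerate(reac.itertuples(index=False)):
        pid = str(row.primaryid).strip()
        if not pid:
            log.add(reac_name, i + 2, "missing primaryid")
            continue
        if pid not in demo_pids:
            log.add(reac_name, i + 2, "orphan row: primaryid not in DEMO")
            continue
        if _blank(row.pt):
            log.add(reac_name, i + 2, "empty PT")
            continue
        reac_by_pid.setdefault(pid, set()).add(normalize_pt(row.pt))

    # --- therapy dates, keyed on (primaryid, drug_seq) -------------------
    ther_by_key: dict[tuple[str, str], tuple[date | None, date | None]] = {}
    for i, row in enumerate(ther.itertuples(index=False)):
        pid = str(row.primaryid).strip()
        if not pid:
            log.add(ther_name, i + 2, "missing primaryid")
            continue
        if pid not in demo_pids:
            log.add(ther_name, i + 2, "orphan row: primaryid not in DEMO")
            continue
        seq = str(row.dsg_drug_seq).strip()
        start, _ = parse_faers_date(row.start_dt)
        end, _ = parse_faers_date(getattr(row, "end_dt", None))
        if start is not None and end is not None and end < start:
            log.add(ther_name, i + 2, "therapy end precedes start; end dropped")
            end = None
        # keep earliest start per (pid, seq)
        prev = ther_by_key.get((pid, seq))
        if prev is None or (start is not None and (prev[0] is None or start < prev[0])):
            ther_by_key[(pid, seq)] = (start, end)

    # --- drugs -----------------------------------------------------------
    drug_rows: dict[str, list[tuple[float, DrugEntry]]] = {}
    for i, row in enumerate(drug.itertuples(index=False)):
        pid = str(row.primaryid).strip()
        if not pid:
            log.add(drug_name_f, i + 2, "missing primaryid")
            continue
        if pid not in demo_pids:
            log.add(drug_name_f, i + 2, "orphan row: primaryid not in DEMO")
            continue
        role = str(row.role_cod).strip().upper()
        if role not in ROLE_CODES:
            log.add(drug_name_f, i + 2, f"unknown role code {role!r}")
            continue
        if _blank(row.drugname):
            log.add(drug_name_f, i + 2, "empty drug name")
            continue
        seq = str(getattr(row, "drug_seq", "")).strip()
        start, end = ther_by_key.get((pid, seq), (None, None))
        entry = DrugEntry(
            drug_name=normalize_drug_name(row.drugname),
            role_code=role,
            therapy_start=start,
            therapy_end=end,
        )
        try:
            seq_key = float(seq) if seq else float(i)
        except ValueError:
            seq_key = float(i)
        drug_rows.setdefault(pid, []).append((seq_key, entry))

    # --- outcomes ---------------------------------------------------------
    outc_by_pid: dict[str, set[str]] = {}
    for i, row in enumerate(outc.itertuples(index=False)):
        pid = str(row.primaryid).strip()
        if not pid:
            log.add(outc_name, i + 2, "missing primaryid")
            continue
        if pid not in demo_pids:
            log.add(outc_name, i + 2, "orphan row: primaryid not in DEMO")
            continue
        code = str(row.outc_cod).strip().upper()
        if code in OUTCOME_CODES:
            outc_by_pid.setdefault(pid, set()).add(code)

    # --- demographics & assembly -----------------------------------------
    reports: list[IcsrReport] = []
    seen_pids: set[str] = set()
    for i, row in enumerate(demo.itertuples(index=False)):
        line = i + 2
        pid = str(row.primaryid).strip()
        if not pid:
            log.add(demo_name, line, "missing primaryid")
            continue
        if pid in seen_pids:
            log.add(demo_name, line, "duplicate primaryid within DEMO; row skipped")
            continue
        seen_pids.add(pid)
        reactions = reac_by_pid.get(pid)
        if not reactions:
            log.add(demo_name, line, "no joinable REAC row; report excluded")
            continue

        case_id = str(getattr(row, "caseid", "")).strip() or pid
        event_date, imputed = parse_faers_date(getattr(row, "event_dt", None))
        receipt_date, _ = parse_faers_date(getattr(row, "fda_dt", None))

        age_years: float | None = None
        raw_age = getattr(row, "age", "")
        if not _blank(raw_age):
            try:
                value = float(str(raw_age).strip())
            except ValueError:
                log.add(demo_name, line, "unparseable age; set missing")
            else:
                code = str(getattr(row, "age_cod", "YR")).strip().upper() or "YR"
                mult = _AGE_TO_YEARS.get(code)
                if mult is None:
                    log.add(demo_name, line, f"unknown age unit {code!r}; age missing")
                elif value < 0:
                    log.add(demo_name, line, "negative age; set missing")
                else:
                    age_years = value * mult

        weight_kg: float | None = None
        raw_wt = getattr(row, "wt", "")
        if not _blank(raw_wt):
            try:
                value = float(str(raw_wt).strip())
            except ValueError:
                log.add(demo_name, line, "unparseable weight; set missing")
            else:
                code = str(getattr(row, "wt_cod", "KG")).strip().upper() or "KG"
                mult = _WT_TO_KG.get(code)
                if mult is None:
                    log.add(demo_name, line, f"unknown weight unit {code!r}; weight missing")
                elif value < 0:
                    log.add(demo_name, line, "negative weight; set missing")
                else:
                    weight_kg = value * mult

        sex = _SEX_MAP.get(str(getattr(row, "sex", "")).strip().upper(), "unknown")
        country = str(
            getattr(row, "occr_country", "") or getattr(row, "reporter_country", "")
        ).strip().upper() or None
        occupation = str(getattr(row, "occp_cod", "")).strip().upper() or None

        entries = [e for _, e in sorted(drug_rows.get(pid, []), key=lambda t: t[0])]

        reports.append(
            IcsrReport(
                primary_id=pid,
                case_id=case_id,
                receipt_date=receipt_date,
                event_date=event_date,
                sex=sex,
                age_years=age_years,
                weight_kg=weight_kg,
                country=country,
                outcome_codes=frozenset(outc_by_pid.get(pid, set())),
                reporter_occupation=occupation,
                drugs=tuple(entries),
                reactions=frozenset(reactions),
                event_date_imputed=imputed,
            )
        )
    return IngestResult(reports, log)


def discover_quarters(input_dir: str | Path) -> list[dict[str, Path]]:
    """Find quarter file sets ``DEMO<tag>`` .. ``OUTC<tag>`` in a directory.

    Files are matched by the suffix following the table name, e.g.
    ``DEMO24Q1.txt`` pairs with ``DRUG24Q1.txt``.
    """
    input_dir = Path(input_dir)
    quarters = []
    for demo in sorted(input_dir.glob("DEMO*")):
        tag = demo.name[len("DEMO"):]
        paths = {"demo": demo}
        ok = True
        for table in ("DRUG", "REAC", "THER", "OUTC"):
            candidate = input_dir / f"{table}{tag}"
            if not candidate.exists():
                ok = False
                break
            paths[table.lower()] = candidate
        if ok:
            quarters.append(paths)
    return quarters


def read_directory(input_dir: str | Path) -> IngestResult:
    """Read every quarter file set found in ``input_dir`` and concatenate."""
    quarters = discover_quarters(input_dir)
    if not quarters:
        raise FileNotFoundError(f"no FAERS quarter file sets found in {input_dir}")
    reports: list[IcsrReport] = []
    log = ParseLog()
    for paths in quarters:
        res = read_quarter(
            paths["demo"], paths["drug"], paths["reac"], paths["ther"], paths["outc"]
        )
        reports.extend(res.reports)
        log.extend(res.log)
    return IngestResult(reports, log)


def _pid_key(pid: str) -> tuple[int, int | str]:
    s = str(pid)
    return (0, int(s)) if s.isdigit() else (1, s)


def _six_field_key(report: IcsrReport):
    """Redundancy key: event date, age, sex, reaction set, drug-name set, country.

    ``None`` acts as an explicit missing sentinel, so two reports missing the
    same field can still be judged duplicates.
    """
    return (
        report.event_date,
        report.age_years,
        report.sex,
        report.reactions,
        report.drug_names(),
        report.country,
    )


def deduplicate(reports: Iterable[IcsrReport]) -> list[IcsrReport]:
    """Two-stage duplicate removal.

    Stage 1 keeps, for each ``case_id``, the record with the greatest
    ``primary_id`` (the latest case version).  Stage 2 collapses groups that
    are identical on the six-field redundancy key to the record with the
    latest receipt date (ties broken by greatest ``primary_id``).  Output is
    sorted by ``primary_id`` for determinism; surviving records are returned
    unaltered.
    """
    latest: dict[str, IcsrReport] = {}
    for r in reports:
        cur = latest.get(r.case_id)
        if cur is None or _pid_key(r.primary_id) > _pid_key(cur.primary_id):
            latest[r.case_id] = r

    groups: dict[object, IcsrReport] = {}
    for r in latest.values():
        key = _six_field_key(r)
        cur = groups.get(key)
        if cur is None:
            groups[key] = r
            continue
        r_rank = (r.receipt_date or date.min, _pid_key(r.primary_id))
        cur_rank = (cur.receipt_date or date.min, _pid_key(cur.primary_id))
        if r_rank > cur_rank:
            groups[key] = r

    return sorted(groups.values(), key=lambda r: _pid_key(r.primary_id))


def filter_primary_suspect(
    reports: Iterable[IcsrReport], drug_name: str
) -> list[IcsrReport]:
    """Reports naming ``drug_name`` as the primary suspect (role code PS).

    Reports where the drug appears only as secondary suspect, concomitant or
    interacting are excluded.  A drug name unknown to the whole collection
    produces an empty result plus a warning.
    """
    target = normalize_drug_name(drug_name)
    reports = list(reports)
    hits = [r for r in reports if r.has_primary_suspect(target)]
    if not hits:
        seen_anywhere = any(
            target in r.drug_names() for r in reports
        )
        if not seen_anywhere:
            warnings.warn(
                f"drug {target!r} does not appear in any report", stacklevel=2
            )
    return hits
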