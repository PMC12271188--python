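"""Synthetic spontaneous-report generator with known ground truth.

Emits FAERS-dialect quarterly tables (DEMO/DRUG/REAC/THER/OUTC, '$'-delimited)
for a configurable individual-case-safety-report stream in which everything
the pipeline estimates is planted by construction:

* each report draws one primary-suspect drug by marginal share;
* each reaction PT is drawn independently given the drug, with probability
  ``background_rate * rho(drug, PT)`` capped at 0.99 — ``rho`` is the planted
  relative reporting rate that disproportionality statistics should recover;
* onset delay is Weibull(shape, scale) per drug, added to a therapy start
  drawn uniformly over 2004-2024 and rounded to whole days;
* demographics (sex mix, age, weight, country, outcome, occupation) follow
  configurable distributions with explicit missingness rates;
* version duplicates (same case, higher primaryid, later receipt) and
  six-field redundancy duplicates (new case, identical dedup key) are
  injected at configurable rates and recorded in the manifest.

The default configuration is a study-like scenario: a rare first-generation
drug versus a common second-generation drug (report shares mirroring a
~1,800 vs ~69,000 imbalance), ten osteoporosis PTs plus fifty background
PTs, planted rate ratios of the order seen in published signal tables, and
Weibull onset parameters of published magnitude.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import DrugEntry, IcsrReport, normalize_drug_name, normalize_pt
from .stats import ContingencyTable

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "default_config",
    "generate",
    "inject_duplicates",
    "simulate_pair_table",
]

_EPOCH = date(1970, 1, 1)


def _default_drugs() -> tuple[tuple[str, float], ...]:
    # the two study drugs keep their ~1:5-1:40 report imbalance but stay a
    # small fraction of the stream, as in a full spontaneous-report database
    # where the background dominates every drug
    background = tuple(
        (f"COMPARATOR {letter}", 0.88 / 6) for letter in "ABCDEF"
    )
    return (("ADEFOVIR", 0.02), ("TENOFOVIR", 0.10)) + background


def _default_events() -> tuple[tuple[str, float], ...]:
    osteo = (
        ("osteoporosis", 0.004),
        ("bone density decreased", 0.003),
        ("bone loss", 0.002),
        ("osteopenia", 0.003),
        ("osteoporotic fracture", 0.001),
        ("osteoporosis postmenopausal", 0.0008),
        ("bone formation decreased", 0.0005),
        ("bone marrow oedema syndrome", 0.0005),
        ("resorption bone increased", 0.0005),
        ("senile osteoporosis", 0.0004),
    )
    # ~2 background reactions per report on average, as spontaneous reports
    # typically carry several PTs
    background = tuple(
        (f"background reaction {i:02d}", 0.04) for i in range(1, 51)
    )
    return osteo + background


def _default_planted_rr() -> dict[tuple[str, str], float]:
    return {
        ("ADEFOVIR", "osteoporosis"): 38.0,
        ("ADEFOVIR", "bone density decreased"): 11.0,
        ("TENOFOVIR", "bone density decreased"): 25.0,
        ("TENOFOVIR", "bone loss"): 25.0,
        ("TENOFOVIR", "osteopenia"): 15.0,
        ("TENOFOVIR", "osteoporosis"): 8.0,
        ("TENOFOVIR", "osteoporotic fracture"): 6.0,
    }


def _default_tto() -> dict[str, tuple[float, float]]:
    # (shape, scale in days); published-magnitude onset distributions for the
    # two study drugs, constant-hazard-like background elsewhere.
    return {
        "ADEFOVIR": (1.07, 1331.68),
        "TENOFOVIR": (1.29, 2287.95),
    }


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic report stream."""

    n_reports: int = 20_000
    drugs: tuple[tuple[str, float], ...] = field(default_factory=_default_drugs)
    events: tuple[tuple[str, float], ...] = field(default_factory=_default_events)
    planted_rr: Mapping[tuple[str, str], float] = field(
        default_factory=_default_planted_rr
    )
    tto: Mapping[str, tuple[float, float]] = field(default_factory=_default_tto)
    default_tto: tuple[float, float] = (1.0, 800.0)
    sex_mix: tuple[float, float, float] = (0.62, 0.26, 0.12)  # male, female, unknown
    age_mean: float = 55.0
    age_sd: float = 18.0
    age_missing: float = 0.30
    weight_missing: float = 0.85
    event_date_missing: float = 0.15
    therapy_start_missing: float = 0.10
    country_missing: float = 0.05
    duplicate_rate: float = 0.0
    six_field_dup_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        shares = [s for _, s in self.drugs]
        if not shares or any(s <= 0 for s in shares):
            raise ValueError("drug shares must be positive")
        if abs(sum(shares) - 1.0) > 1e-6:
            raise ValueError("drug shares must sum to 1")
        if not self.events or any(not (0 < r < 1) for _, r in self.events):
            raise ValueError("event background rates must lie in (0, 1)")
        if any(rho < 0 or not math.isfinite(rho) for rho in self.planted_rr.values()):
            raise ValueError("planted rate ratios must be finite and >= 0")
        for rate_name in ("duplicate_rate", "six_field_dup_rate"):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{rate_name} must lie in [0, 1)")
        if abs(sum(self.sex_mix) - 1.0) > 1e-6:
            raise ValueError("sex mix must sum to 1")


def default_config(**overrides) -> SyntheticConfig:
    """The study-like default scenario, with keyword overrides."""
    return dataclasses.replace(SyntheticConfig(), **overrides)


_COUNTRIES = ("US", "CN", "JP", "DE", "FR")
_COUNTRY_P = (0.4, 0.25, 0.15, 0.1, 0.1)
_OUTCOMES = ("OT", "HO", "DE", "DS", "LT", "CA", "RI", "")
_OUTCOME_P = (0.45, 0.20, 0.05, 0.03, 0.02, 0.01, 0.005, 0.235)
_OCCUPATIONS = ("MD", "CN", "OT", "PH", "HP", "")
_OCCUPATION_P = (0.35, 0.2, 0.2, 0.05, 0.05, 0.15)


def _date_strings(ordinals: np.ndarray, missing: np.ndarray) -> list[str]:
    out = []
    for o, miss in zip(ordinals, missing):
        if miss:
            out.append("")
        else:
            out.append((_EPOCH + timedelta(days=int(o))).strftime("%Y%m%d"))
    return out


@dataclass
class SyntheticDataset:
    """Generated quarter tables plus the ground-truth manifest."""

    config: SyntheticConfig
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write DEMO/DRUG/REAC/THER/OUTC '$'-delimited files + manifest.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, frame in (
            ("DEMO", self.demo),
            ("DRUG", self.drug),
            ("REAC", self.reac),
            ("THER", self.ther),
            ("OUTC", self.outc),
        ):
            path = out_dir / f"{name}.txt"
            frame.to_csv(path, sep="$", index=False, lineterminator="\n")
            paths[name.lower()] = path
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )
        paths["manifest"] = manifest_path
        return paths

    def to_reports(self) -> list[IcsrReport]:
        """Build the in-memory report truth directly from the frames.

        This is independent of the FAERS reader and serves as the reference
        side of round-trip tests.
        """
        reac_by_pid: dict[str, set[str]] = {}
        for row in self.reac.itertuples(index=False):
            reac_by_pid.setdefault(str(row.primaryid), set()).add(
                normalize_pt(row.pt)
            )
        ther_by_pid: dict[str, tuple[date | None, date | None]] = {}
        for row in self.ther.itertuples(index=False):
            start = _parse(row.start_dt)
            end = _parse(getattr(row, "end_dt", ""))
            ther_by_pid[str(row.primaryid)] = (start, end)
        drug_by_pid: dict[str, list[DrugEntry]] = {}
        for row in self.drug.itertuples(index=False):
            pid = str(row.primaryid)
            start, end = ther_by_pid.get(pid, (None, None))
            drug_by_pid.setdefault(pid, []).append(
                DrugEntry(
                    drug_name=normalize_drug_name(row.drugname),
                    role_code=str(row.role_cod),
                    therapy_start=start,
                    therapy_end=end,
                )
            )
        outc_by_pid: dict[str, set[str]] = {}
        for row in self.outc.itertuples(index=False):
            outc_by_pid.setdefault(str(row.primaryid), set()).add(str(row.outc_cod))
        sex_map = {"M": "male", "F": "female", "": "unknown"}
        reports = []
        for row in self.demo.itertuples(index=False):
            pid = str(row.primaryid)
            reports.append(
                IcsrReport(
                    primary_id=pid,
                    case_id=str(row.caseid),
                    receipt_date=_parse(row.fda_dt),
                    event_date=_parse(row.event_dt),
                    sex=sex_map.get(str(row.sex), "unknown"),
                    age_years=float(row.age) if str(row.age) != "" else None,
                    weight_kg=float(row.wt) if str(row.wt) != "" else None,
                    country=str(row.occr_country) or None,
                    outcome_codes=frozenset(outc_by_pid.get(pid, set())),
                    reporter_occupation=str(row.occp_cod) or None,
                    drugs=tuple(drug_by_pid.get(pid, [])),
                    reactions=frozenset(reac_by_pid.get(pid, set())),
                )
            )
        return reports


def _six_field_keys(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> list[tuple]:
    """Six-field dedup key per DEMO row, computed from the raw frames."""
    reac_sets: dict[str, frozenset[str]] = (
        reac.groupby("primaryid")["pt"].agg(frozenset).to_dict()
    )
    drug_sets: dict[str, frozenset[str]] = (
        drug.groupby("primaryid")["drugname"].agg(frozenset).to_dict()
    )
    keys = []
    for row in demo.itertuples(index=False):
        pid = str(row.primaryid)
        keys.append(
            (
                str(row.event_dt),
                str(row.age),
                str(row.sex),
                reac_sets.get(pid, frozenset()),
                drug_sets.get(pid, frozenset()),
                str(row.occr_country),
            )
        )
    return keys


def _parse(raw: object) -> date | None:
    s = str(raw).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    return date(int(s[:4]), int(s[4:6]), int(s[6:8]))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a synthetic report stream; deterministic given the seed.

    Duplicates are injected afterwards when the configured rates are
    positive.  The manifest records every planted parameter and every
    injected duplicate's source record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = [normalize_drug_name(name) for name, _ in config.drugs]
    shares = np.array([s for _, s in config.drugs], dtype=float)
    shares = shares / shares.sum()
    drug_idx = rng.choice(len(drug_names), size=n, p=shares)

    event_names = [normalize_pt(name) for name, _ in config.events]
    base_rates = np.array([r for _, r in config.events], dtype=float)
    rr = {(normalize_drug_name(d), normalize_pt(p)): float(v)
          for (d, p), v in config.planted_rr.items()}

    # per-report event probabilities: background rate x planted rate ratio
    probs = np.tile(base_rates, (len(drug_names), 1))
    for (d, p), rho in rr.items():
        if d in drug_names and p in event_names:
            probs[drug_names.index(d), event_names.index(p)] *= rho
    probs = np.minimum(probs, 0.99)
    event_matrix = rng.random((n, len(event_names))) < probs[drug_idx]

    # every report must carry at least one reaction to enter analysis
    empty = ~event_matrix.any(axis=1)
    if empty.any():
        fallback = rng.integers(0, len(event_names), size=int(empty.sum()))
        event_matrix[np.flatnonzero(empty), fallback] = True

    # therapy start uniform over 2004-01-01 .. 2024-06-30; onset Weibull
    lo = (date(2004, 1, 1) - _EPOCH).days
    hi = (date(2024, 6, 30) - _EPOCH).days
    start_ord = rng.integers(lo, hi + 1, size=n)
    shapes = np.empty(n)
    scales = np.empty(n)
    tto_map = {normalize_drug_name(k): v for k, v in config.tto.items()}
    for i, name in enumerate(drug_names):
        mask = drug_idx == i
        shape, scale = tto_map.get(name, config.default_tto)
        shapes[mask], scales[mask] = shape, scale
    # Weibull draws via inverse CDF so the per-report shape can vary
    u = rng.random(n)
    delays = np.rint(scales * (-np.log1p(-u)) ** (1.0 / shapes)).astype(int)
    event_ord = start_ord + delays
    receipt_ord = event_ord + rng.integers(5, 120, size=n)

    event_missing = rng.random(n) < config.event_date_missing
    ther_missing = rng.random(n) < config.therapy_start_missing

    sex = rng.choice(np.array(["M", "F", ""]), size=n, p=np.array(config.sex_mix))
    age = np.round(np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 1, 95))
    age_missing = rng.random(n) < config.age_missing
    wt = np.round(np.clip(rng.normal(70.0, 15.0, size=n), 35, 150), 1)
    wt_missing = rng.random(n) < config.weight_missing
    country = rng.choice(np.array(_COUNTRIES), size=n, p=np.array(_COUNTRY_P))
    country_missing = rng.random(n) < config.country_missing
    outc = rng.choice(np.array(_OUTCOMES), size=n, p=np.array(_OUTCOME_P))
    occp = rng.choice(np.array(_OCCUPATIONS), size=n, p=np.array(_OCCUPATION_P))

    pids = np.arange(100_001, 100_001 + n)
    caseids = np.arange(5_000_001, 5_000_001 + n)

    demo = pd.DataFrame(
        {
            "primaryid": pids.astype(str),
            "caseid": caseids.astype(str),
            "event_dt": _date_strings(event_ord, event_missing),
            "fda_dt": _date_strings(receipt_ord, np.zeros(n, dtype=bool)),
            "age": np.where(age_missing, "", age.astype(int).astype(str)),
            "age_cod": np.where(age_missing, "", "YR"),
            "sex": sex,
            "wt": np.where(wt_missing, "", wt.astype(str)),
            "wt_cod": np.where(wt_missing, "", "KG"),
            "occp_cod": occp,
            "occr_country": np.where(country_missing, "", country),
        }
    )
    drug = pd.DataFrame(
        {
            "primaryid": pids.astype(str),
            "drug_seq": np.full(n, "1"),
            "role_cod": np.full(n, "PS"),
            "drugname": [drug_names[i] for i in drug_idx],
        }
    )
    pid_rep, evt_rep = np.nonzero(event_matrix)
    reac = pd.DataFrame(
        {
            "primaryid": pids[pid_rep].astype(str),
            "pt": [event_names[j] for j in evt_rep],
        }
    )
    ther = pd.DataFrame(
        {
            "primaryid": pids.astype(str),
            "dsg_drug_seq": np.full(n, "1"),
            "start_dt": _date_strings(start_ord, ther_missing),
            "end_dt": np.full(n, ""),
        }
    )
    has_outc = outc != ""
    outc_df = pd.DataFrame(
        {
            "primaryid": pids[has_outc].astype(str),
            "outc_cod": outc[has_outc],
        }
    )

    # chance six-field collisions among independent base reports are genuine
    # duplicates under the redundancy rule; record them as ground truth
    keys = _six_field_keys(demo, drug, reac)
    key_counts: dict[tuple, int] = {}
    for key in keys:
        key_counts[key] = key_counts.get(key, 0) + 1
    baseline_collisions = sum(v - 1 for v in key_counts.values() if v > 1)

    manifest = {
        "seed": config.seed,
        "baseline_six_field_collisions": baseline_collisions,
        "n_reports": n,
        "drug_shares": {name: float(s) for name, s in zip(drug_names, shares)},
        "event_rates": {name: float(r) for name, r in zip(event_names, base_rates)},
        "planted_rr": {f"{d}|{p}": v for (d, p), v in rr.items()},
        "tto": {k: list(v) for k, v in tto_map.items()},
        "default_tto": list(config.default_tto),
        "true_drug_counts": {
            name: int((drug_idx == i).sum()) for i, name in enumerate(drug_names)
        },
        "duplicates": {"version": [], "six_field": []},
    }

    dataset = SyntheticDataset(
        config=config,
        demo=demo,
        drug=drug,
        reac=reac,
        ther=ther,
        outc=outc_df,
        manifest=manifest,
    )
    if config.duplicate_rate > 0 or config.six_field_dup_rate > 0:
        dataset = inject_duplicates(dataset)
    return dataset


def inject_duplicates(dataset: SyntheticDataset) -> SyntheticDataset:
    """Re-emit a fraction of reports as version and redundancy duplicates.

    Version duplicates share the case identifier but carry a higher
    ``primaryid`` and a later receipt date, emulating updated case reports.
    Redundancy duplicates carry a fresh case identifier but an identical
    six-field dedup key (event date, age, sex, reactions, drug set, country).
    The manifest records every (source, duplicate) primaryid pair; the
    two-stage dedup rule should remove exactly one record per injected
    duplicate.
    """
    config = dataset.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    demo = dataset.demo
    n = len(demo)
    n_version = int(round(config.duplicate_rate * n))
    n_six = int(round(config.six_field_dup_rate * n))
    if n_version + n_six == 0:
        return dataset

    src_version = rng.choice(n, size=n_version, replace=False) if n_version else np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(n), src_version)
    src_six = (
        rng.choice(remaining, size=n_six, replace=False) if n_six else np.array([], dtype=int)
    )

    max_pid = demo["primaryid"].astype(int).max()
    max_case = demo["caseid"].astype(int).max()
    next_pid = max_pid + 1
    next_case = max_case + 1

    def _shift_date(s: str, days: int) -> str:
        d = _parse(s)
        if d is None:
            return s
        return (d + timedelta(days=days)).strftime("%Y%m%d")

    new_demo, new_drug, new_reac, new_ther, new_outc = [], [], [], [], []
    version_log, six_log = [], []

    drug_by_pid = dict(tuple(dataset.drug.groupby("primaryid", sort=False)))
    reac_by_pid = dict(tuple(dataset.reac.groupby("primaryid", sort=False)))
    ther_by_pid = dict(tuple(dataset.ther.groupby("primaryid", sort=False)))
    outc_by_pid = dict(tuple(dataset.outc.groupby("primaryid", sort=False)))

    def _emit(src_idx: int, dup_pid: str, dup_case: str, receipt_shift: int) -> None:
        row = demo.iloc[src_idx].copy()
        src_pid = str(row["primaryid"])
        row["primaryid"] = dup_pid
        row["caseid"] = dup_case
        row["fda_dt"] = _shift_date(str(row["fda_dt"]), receipt_shift)
        new_demo.append(row)
        for store, bucket in (
            (drug_by_pid, new_drug),
            (reac_by_pid, new_reac),
            (ther_by_pid, new_ther),
            (outc_by_pid, new_outc),
        ):
            part = store.get(src_pid)
            if part is not None:
                part = part.copy()
                part["primaryid"] = dup_pid
                bucket.append(part)

    base_keys = _six_field_keys(demo, dataset.drug, dataset.reac)
    base_key_counts: dict[tuple, int] = {}
    for key in base_keys:
        base_key_counts[key] = base_key_counts.get(key, 0) + 1

    for src_idx in src_version:
        dup_pid = str(next_pid)
        src_row = demo.iloc[src_idx]
        _emit(int(src_idx), dup_pid, str(src_row["caseid"]), receipt_shift=30)
        version_log.append(
            {
                "source_primaryid": str(src_row["primaryid"]),
                "dup_primaryid": dup_pid,
                "caseid": str(src_row["caseid"]),
                "expected_survivor": dup_pid,
                # after the case-version stage the survivor can still lose a
                # redundancy tie to an unrelated report sharing its key
                "source_key_unique": base_key_counts[base_keys[int(src_idx)]] == 1,
            }
        )
        next_pid += 1

    for src_idx in src_six:
        dup_pid = str(next_pid)
        dup_case = str(next_case)
        src_row = demo.iloc[src_idx]
        six_log.append(
            {
                "source_primaryid": str(src_row["primaryid"]),
                "dup_primaryid": dup_pid,
                "dup_caseid": dup_case,
                "expected_survivor": dup_pid,
                # survivor prediction only holds when the source's key group
                # is just {source, duplicate}
                "source_key_unique": base_key_counts[base_keys[int(src_idx)]] == 1,
            }
        )
        _emit(int(src_idx), dup_pid, dup_case, receipt_shift=45)
        next_pid += 1
        next_case += 1

    manifest = dict(dataset.manifest)
    manifest["duplicates"] = {"version": version_log, "six_field": six_log}

    return SyntheticDataset(
        config=config,
        demo=pd.concat([demo, pd.DataFrame(new_demo)], ignore_index=True),
        drug=pd.concat([dataset.drug, *new_drug], ignore_index=True)
        if new_drug
        else dataset.drug,
        reac=pd.concat([dataset.reac, *new_reac], ignore_index=True)
        if new_reac
        else dataset.reac,
        ther=pd.concat([dataset.ther, *new_ther], ignore_index=True)
        if new_ther
        else dataset.ther,
        outc=pd.concat([dataset.outc, *new_outc], ignore_index=True)
        if new_outc
        else dataset.outc,
        manifest=manifest,
    )


def simulate_pair_table(
    n_reports: int,
    drug_share: float,
    event_rate: float,
    rho: float,
    rng: np.random.Generator,
) -> ContingencyTable:
    """Draw one drug-event 2x2 table directly from the generative model.

    Equivalent in distribution to generating ``n_reports`` full reports with
    one independent event and counting, but without materialising them;
    intended for repeated calibration runs.
    """
    n_drug = int(rng.binomial(n_reports, drug_share))
    a = int(rng.binomial(n_drug, min(event_rate * rho, 0.99)))
    c = int(rng.binomial(n_reports - n_drug, event_rate))
    return ContingencyTable(a=a, b=n_drug - a, c=c, d=n_reports - n_drug - c)
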