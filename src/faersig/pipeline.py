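"""End-to-end study orchestration: descriptives, signal tables, subgroups, TTO.

``run_analysis`` reads FAERS-dialect files, deduplicates, and writes per
drug: a demographics table, PT-level and SMQ-level signal tables (the SMQ
table carries an overall row plus male/female/younger/older subgroup rows),
a time-to-onset table and a run log.  All outputs are TSV with a header
comment naming the tool version and the configuration hash, and are
byte-identical across re-runs with fixed inputs.

Subgroup disproportionality restricts both numerator and background to the
stratum (a stratum-internal 2x2); the age cutoff for subgrouping is 60 years
(cutoff inclusive on the high side), while the descriptive table uses the
finer bands <18 / 18-64.9 / 65-85 / >85.  The MGPS prior is fitted once on
all (primary-suspect drug, PT) pairs in the full deduplicated dataset and
reused for subgroup shrinkage estimates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ingest import (
    IcsrReport,
    OUTCOME_CODES,
    deduplicate,
    filter_primary_suspect,
    normalize_drug_name,
    read_directory,
)
from .smq import SmqDefinition, aggregate_smq, count_pt_pairs, default_osteoporosis_smq, load_smq
from .stats import (
    ContingencyTable,
    MgpsPrior,
    SignalEstimate,
    SignalThresholds,
    bonferroni,
    build_contingency,
    contingency_from_totals,
    ebgm_estimate,
    evaluate_signal,
    fit_mgps_prior,
    ic_estimate,
    prr_estimate,
    pvalue_2x2,
    ror_estimate,
)
from .tto import compare_tto, compute_tto, tto_summary, weibull_mle

__all__ = [
    "StudyConfig",
    "percent",
    "summarize_demographics",
    "stratify",
    "database_pair_tables",
    "signal_rows_for_drug",
    "run_analysis",
]

logger = logging.getLogger("faersig")

_AGE_BANDS = (("<18", 0.0, 18.0), ("18-64.9", 18.0, 65.0), ("65-85", 65.0, 85.0 + 1e-9),
              (">85", 85.0 + 1e-9, math.inf))
_WEIGHT_BANDS = (("<50 kg", 0.0, 50.0), ("50-100 kg", 50.0, 100.0 + 1e-9),
                 (">100 kg", 100.0 + 1e-9, math.inf))
_OCCP_LABELS = {
    "CN": "Consumer",
    "HP": "Health professional",
    "LW": "Lawyer",
    "MD": "Physician",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "RN": "Registered Nurse",
}
# one outcome per report for percentage accounting: most serious first
_OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclass
class StudyConfig:
    """Study parameters: drugs, SMQ file, strata cutoffs, thresholds."""

    drug_names: tuple[str, ...]
    smq_file: str | None = None
    smq_name: str = "osteoporosis"
    age_cutoff_years: float = 60.0
    sex_strata: bool = True
    bonferroni_m: int | None = None
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    z: float = 1.96
    continuity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.drug_names:
            raise ValueError("at least one drug name required")
        if self.age_cutoff_years <= 0:
            raise ValueError("age cutoff must be positive")
        self.drug_names = tuple(normalize_drug_name(d) for d in self.drug_names)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        thresholds = SignalThresholds(**raw.pop("thresholds", {}))
        known = {
            "drug_names", "smq_file", "smq_name", "age_cutoff_years",
            "sex_strata", "bonferroni_m", "z", "continuity", "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        raw["drug_names"] = tuple(raw.get("drug_names", ()))
        return cls(thresholds=thresholds, **raw)

    def sha(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def load_smq(self) -> SmqDefinition:
        if self.smq_file is None:
            return default_osteoporosis_smq()
        return load_smq(self.smq_file, name=self.smq_name)


def percent(count: int, total: int) -> float | None:
    """Percentage of a column total, one decimal; ``None`` on an empty total."""
    if total == 0:
        return None
    return round(100.0 * count / total, 1)


def _band_label(value: float | None, bands) -> str | None:
    if value is None:
        return None
    for label, lo, hi in bands:
        if lo <= value < hi:
            return label
    return None


def _primary_outcome(report: IcsrReport) -> str:
    for code in _OUTCOME_PRIORITY:
        if code in report.outcome_codes:
            return code
    return "Missing"


def summarize_demographics(
    reports: Iterable[IcsrReport], drug: str, smq: SmqDefinition
) -> pd.DataFrame:
    """Descriptive table for one drug: counts and percentages per block.

    Blocks: sex, age bands, weight bands, outcome codes (one per report, most
    serious first), reporter occupation.  Two column pairs: all
    primary-suspect reports of the drug, and the subset carrying at least one
    SMQ member PT.  Percentages are of the column total including missing,
    printed to one decimal; empty columns leave percentages blank.
    """
    ps_reports = [r for r in reports if r.has_primary_suspect(drug)]
    members = smq.member_set
    smq_reports = [r for r in ps_reports if r.reactions & members]

    def _counts(rows: list[IcsrReport]) -> list[tuple[str, str, int]]:
        total = len(rows)
        out: list[tuple[str, str, int]] = [("Total", "Number of reports", total)]
        sex_counts = {"Female": 0, "Male": 0, "Missing/unknown": 0}
        for r in rows:
            key = {"female": "Female", "male": "Male"}.get(r.sex, "Missing/unknown")
            sex_counts[key] += 1
        out += [("Sex", k, v) for k, v in sex_counts.items()]

        age_counts = {label: 0 for label, _, _ in _AGE_BANDS}
        age_counts["Missing/unknown"] = 0
        for r in rows:
            label = _band_label(r.age_years, _AGE_BANDS) or "Missing/unknown"
            age_counts[label] += 1
        out += [("Age", k, v) for k, v in age_counts.items()]

        wt_counts = {label: 0 for label, _, _ in _WEIGHT_BANDS}
        wt_counts["Missing/unknown"] = 0
        for r in rows:
            label = _band_label(r.weight_kg, _WEIGHT_BANDS) or "Missing/unknown"
            wt_counts[label] += 1
        out += [("Weight", k, v) for k, v in wt_counts.items()]

        outc_counts = {code: 0 for code in OUTCOME_CODES}
        outc_counts["Missing"] = 0
        for r in rows:
            outc_counts[_primary_outcome(r)] += 1
        out += [("Outcome", k, v) for k, v in outc_counts.items()]

        occ_counts = {label: 0 for label in _OCCP_LABELS.values()}
        occ_counts["Missing"] = 0
        for r in rows:
            label = _OCCP_LABELS.get(r.reporter_occupation or "", "Missing")
            occ_counts[label] += 1
        out += [("Occupation", k, v) for k, v in occ_counts.items()]
        return out

    all_counts = _counts(ps_reports)
    smq_counts = _counts(smq_reports)
    n_all = len(ps_reports)
    n_smq = len(smq_reports)
    records = []
    for (block, category, count_all), (_, _, count_smq) in zip(all_counts, smq_counts):
        pct_all = percent(count_all, n_all) if block != "Total" else None
        pct_smq = percent(count_smq, n_smq) if block != "Total" else None
        records.append(
            {
                "block": block,
                "category": category,
                "all_n": count_all,
                "all_pct": "" if pct_all is None else pct_all,
                "smq_n": count_smq,
                "smq_pct": "" if pct_smq is None else pct_smq,
            }
        )
    return pd.DataFrame.from_records(records)


def stratify(
    reports: Iterable[IcsrReport], axis: str, age_cutoff: float = 60.0
) -> dict[str, list[IcsrReport]]:
    """Disjoint strata by sex or age.

    ``sex`` -> {male, female}, unknown dropped from both strata (retained in
    any overall analysis).  ``age`` -> {younger: < cutoff, older: >= cutoff},
    missing age dropped.
    """
    reports = list(reports)
    if axis == "sex":
        return {
            "male": [r for r in reports if r.sex == "male"],
            "female": [r for r in reports if r.sex == "female"],
        }
    if axis == "age":
        return {
            "younger": [
                r for r in reports if r.age_years is not None and r.age_years < age_cutoff
            ],
            "older": [
                r for r in reports if r.age_years is not None and r.age_years >= age_cutoff
            ],
        }
    raise ValueError(f"unknown stratification axis {axis!r}")


def database_pair_tables(reports: Sequence[IcsrReport]) -> list[ContingencyTable]:
    """2x2 tables for every (primary-suspect drug, PT) pair in the dataset.

    These form the universe over which the MGPS prior is fitted.
    """
    rows_drug = []
    rows_pair = []
    event_counts: dict[str, int] = {}
    for r in reports:
        ps_drugs = {d.drug_name for d in r.drugs if d.role_code == "PS"}
        for pt in r.reactions:
            event_counts[pt] = event_counts.get(pt, 0) + 1
        for drug in ps_drugs:
            rows_drug.append(drug)
            for pt in r.reactions:
                rows_pair.append((drug, pt))
    grand_total = len(reports)
    drug_totals = pd.Series(rows_drug).value_counts().to_dict() if rows_drug else {}
    pair_totals = pd.Series(rows_pair).value_counts().to_dict() if rows_pair else {}
    tables = []
    for (drug, pt), a in sorted(pair_totals.items()):
        tables.append(
            contingency_from_totals(a, drug_totals[drug], event_counts[pt], grand_total)
        )
    return tables


def _estimates_for_table(
    table: ContingencyTable,
    prior: MgpsPrior | None,
    config: StudyConfig,
) -> tuple[list[SignalEstimate], float]:
    thresholds = config.thresholds
    ests = [
        ror_estimate(table, z=config.z, continuity=config.continuity, thresholds=thresholds),
        prr_estimate(table, z=config.z, thresholds=thresholds),
        ic_estimate(table, thresholds=thresholds),
    ]
    if prior is not None and table.expected > 0:
        ests.append(ebgm_estimate(table, prior, thresholds=thresholds))
    p = pvalue_2x2(table)
    return ests, p


def _fmt(x: object, digits: int = 2) -> str:
    if x is None:
        return "-"
    if isinstance(x, float):
        if math.isnan(x):
            return "-"
        return f"{x:.{digits}f}"
    return str(x)


def _row_from_estimates(
    drug: str,
    level: str,
    event: str,
    table: ContingencyTable | None,
    ests: list[SignalEstimate],
    p: float | None,
) -> dict:
    by_method = {e.method: e for e in ests}
    decision = evaluate_signal(ests)
    ror = by_method.get("ROR")
    prr = by_method.get("PRR")
    ic = by_method.get("IC")
    ebgm = by_method.get("EBGM")
    return {
        "drug": drug,
        "level": level,
        "event": event,
        "N": table.a if table is not None else 0,
        "ROR": _fmt(ror.point) if ror else "-",
        "ROR_CI": f"{_fmt(ror.interval_low)}-{_fmt(ror.interval_high)}"
        if ror and ror.defined
        else "-",
        "PRR": _fmt(prr.point) if prr else "-",
        "PRR_chi2": _fmt(prr.chi2) if prr and prr.defined else "-",
        "EBGM": _fmt(ebgm.point) if ebgm else "-",
        "EBGM05": _fmt(ebgm.interval_low) if ebgm else "-",
        "IC": _fmt(ic.point) if ic else "-",
        "IC025": _fmt(ic.interval_low) if ic else "-",
        "p_value": p,
        "p_adjusted": None,  # filled after the Bonferroni pass
        "flag_ROR": decision.flags.get("ROR", False),
        "flag_PRR": decision.flags.get("PRR", False),
        "flag_IC": decision.flags.get("IC", False),
        "flag_EBGM": decision.flags.get("EBGM", False),
        "consensus": decision.consensus,
    }


def signal_rows_for_drug(
    reports: Sequence[IcsrReport],
    drug: str,
    smq: SmqDefinition,
    prior: MgpsPrior | None,
    config: StudyConfig,
) -> tuple[list[dict], list[dict]]:
    """PT-level rows and SMQ-level rows (overall + four subgroup strata)."""
    pt_rows: list[dict] = []
    counts = count_pt_pairs(reports, drug, smq)
    for pt in smq.member_pts:
        a = counts.pt_a[pt]
        if a == 0:
            pt_rows.append(
                {
                    "drug": drug, "level": "PT", "event": pt, "N": 0,
                    "ROR": "-", "ROR_CI": "-", "PRR": "-", "PRR_chi2": "-",
                    "EBGM": "-", "EBGM05": "-", "IC": "-", "IC025": "-",
                    "p_value": None, "p_adjusted": None,
                    "flag_ROR": False, "flag_PRR": False, "flag_IC": False,
                    "flag_EBGM": False, "consensus": False,
                }
            )
            continue
        table = build_contingency(counts, drug, pt)
        ests, p = _estimates_for_table(table, prior, config)
        pt_rows.append(_row_from_estimates(drug, "PT", pt, table, ests, p))

    smq_rows: list[dict] = []

    def _smq_row(label: str, stratum_reports: Sequence[IcsrReport]) -> None:
        sc = aggregate_smq(count_pt_pairs(stratum_reports, drug, smq))
        if sc.a == 0 or sc.grand_total == 0:
            smq_rows.append(
                {
                    "drug": drug, "level": "SMQ", "event": label, "N": sc.a,
                    "ROR": "-", "ROR_CI": "-", "PRR": "-", "PRR_chi2": "-",
                    "EBGM": "-", "EBGM05": "-", "IC": "-", "IC025": "-",
                    "p_value": None, "p_adjusted": None,
                    "flag_ROR": False, "flag_PRR": False, "flag_IC": False,
                    "flag_EBGM": False, "consensus": False,
                }
            )
            return
        table = build_contingency(sc, drug)
        ests, p = _estimates_for_table(table, prior, config)
        smq_rows.append(_row_from_estimates(drug, "SMQ", label, table, ests, p))

    _smq_row("SMQ-TOTAL", reports)
    if config.sex_strata:
        sex_strata = stratify(reports, "sex")
        _smq_row("SMQ-MALE", sex_strata["male"])
        _smq_row("SMQ-FEMALE", sex_strata["female"])
    age_strata = stratify(reports, "age", age_cutoff=config.age_cutoff_years)
    _smq_row("SMQ-YOUNGER", age_strata["younger"])
    _smq_row("SMQ-OLDER", age_strata["older"])
    return pt_rows, smq_rows


def _write_tsv(frame: pd.DataFrame, path: Path, config_sha: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# faersig {__version__} config={config_sha}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


class DataError(RuntimeError):
    """Input data unusable for the requested analysis."""


def run_analysis(
    config: StudyConfig, input_dir: str | Path, output_dir: str | Path
) -> dict[str, Path]:
    """Run the full analysis and write per-drug TSV tables plus a run log.

    Deterministic given inputs and configuration.  Any stage failure raises
    with the stage name and cause.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    sha = config.sha()
    written: dict[str, Path] = {}

    stage = "ingest"
    try:
        ingest = read_directory(input_dir)
        raw_count = len(ingest.reports)
        reports = deduplicate(ingest.reports)
        logger.info(
            "ingest: %d raw reports, %d after dedup, %d parse-log entries",
            raw_count, len(reports), ingest.log.count(),
        )
        parse_log_path = output_dir / "parse_log.tsv"
        ingest.log.to_tsv(parse_log_path)
        written["parse_log"] = parse_log_path

        stage = "smq"
        smq = config.load_smq()

        stage = "mgps_prior"
        tables = database_pair_tables(reports)
        prior = fit_mgps_prior(tables) if len(tables) >= 2 else None
        if prior is None:
            logger.warning("fewer than two drug-event pairs; EBGM skipped")

        stage = "signals"
        all_rows: list[dict] = []
        per_drug_rows: dict[str, tuple[list[dict], list[dict]]] = {}
        tto_samples: dict[str, np.ndarray] = {}
        for drug in config.drug_names:
            pt_rows, smq_rows = signal_rows_for_drug(reports, drug, smq, prior, config)
            per_drug_rows[drug] = (pt_rows, smq_rows)
            all_rows.extend(pt_rows)
            all_rows.extend(smq_rows)

        tested = [r for r in all_rows if r["p_value"] is not None]
        m = config.bonferroni_m if config.bonferroni_m is not None else len(tested)
        if tested:
            adjusted = bonferroni([r["p_value"] for r in tested], m=m)
            for row, p_adj in zip(tested, adjusted):
                row["p_adjusted"] = float(p_adj)

        stage = "write"
        run_log_rows = [
            {"key": "tool_version", "value": __version__},
            {"key": "config_sha", "value": sha},
            {"key": "raw_reports", "value": raw_count},
            {"key": "deduplicated_reports", "value": len(reports)},
            {"key": "duplicates_removed", "value": raw_count - len(reports)},
            {"key": "parse_log_entries", "value": ingest.log.count()},
            {"key": "bonferroni_m", "value": m},
            {"key": "subgroup_background", "value": "stratum-internal"},
        ]
        for drug in config.drug_names:
            ps_reports = filter_primary_suspect(reports, drug)
            if not ps_reports:
                logger.warning("drug %s: no primary-suspect reports", drug)
            slug = drug.lower().replace(" ", "_")

            demo = summarize_demographics(reports, drug, smq)
            path = output_dir / f"{slug}_demographics.tsv"
            _write_tsv(demo, path, sha)
            written[f"{slug}_demographics"] = path

            pt_rows, smq_rows = per_drug_rows[drug]
            path = output_dir / f"{slug}_pt_signals.tsv"
            _write_tsv(pd.DataFrame(pt_rows), path, sha)
            written[f"{slug}_pt_signals"] = path
            path = output_dir / f"{slug}_smq_signals.tsv"
            _write_tsv(pd.DataFrame(smq_rows), path, sha)
            written[f"{slug}_smq_signals"] = path

            sample = compute_tto(ps_reports, drug, smq)
            tto_samples[drug] = sample.durations
            summary = tto_summary(sample.durations)
            tto_row = {
                "drug": drug,
                "n_used": sample.n,
                "n_excluded_missing": sample.n_missing,
                "n_excluded_nonpositive": sample.n_nonpositive,
                "mean_days": _fmt(summary["mean"]),
                "sd_days": _fmt(summary["sd"]),
                "median_days": _fmt(summary["median"]),
                "pct_after_1yr": _fmt(summary["pct_after_1yr"], 2),
            }
            if sample.n >= 3 and np.unique(sample.durations).size > 1:
                fit = weibull_mle(sample.durations, z=config.z)
                tto_row.update(
                    {
                        "scale_alpha": _fmt(fit.scale_alpha),
                        "scale_ci": f"{_fmt(fit.scale_ci[0])}-{_fmt(fit.scale_ci[1])}",
                        "shape_beta": _fmt(fit.shape_beta, 3),
                        "shape_ci": f"{_fmt(fit.shape_ci[0], 3)}-{_fmt(fit.shape_ci[1], 3)}",
                        "failure_class": fit.failure_class,
                    }
                )
            else:
                tto_row.update(
                    {
                        "scale_alpha": "-", "scale_ci": "-", "shape_beta": "-",
                        "shape_ci": "-", "failure_class": "-",
                    }
                )
            path = output_dir / f"{slug}_tto.tsv"
            _write_tsv(pd.DataFrame([tto_row]), path, sha)
            written[f"{slug}_tto"] = path

        if len(config.drug_names) >= 2:
            d1, d2 = config.drug_names[:2]
            if tto_samples[d1].size and tto_samples[d2].size:
                p_cmp = compare_tto(tto_samples[d1], tto_samples[d2])
                run_log_rows.append(
                    {"key": f"tto_mannwhitney_p_{d1.lower()}_vs_{d2.lower()}",
                     "value": f"{p_cmp:.6g}"}
                )

        path = output_dir / "run_log.tsv"
        _write_tsv(pd.DataFrame(run_log_rows), path, sha)
        written["run_log"] = path
    except Exception as exc:
        raise DataError(f"analysis stage {stage!r} failed: {exc}") from exc
    return written
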