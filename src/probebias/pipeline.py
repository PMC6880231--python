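"""End-to-end pipeline stages and the reference-table reproduction report.

Two entry points:

* :func:`run_pipeline` — simulate (or load) a cohort's trial logs, score
  them into timelines, and run the cohort statistics, writing CSV/JSON
  reports to an output directory.

* :func:`reproduce_reference` — recompute every desk-reproducible headline
  number from the packaged study tables: the overall-change column and
  baseline classification counts, the headline proportions, the group mean
  ages, and the uncorrected Pearson chi-square battery over the demographic
  tables, compared with the printed values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pbio
from .fixtures import PaperFixtures, load_fixtures
from .records import BaselineClass, FilterConfig
from .scoring import NoPostSessionError, overall_change, score_cohort
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    ContingencyTable,
    SmallExpectedCountWarning,
    build_table,
    chi_square_battery,
    classify_timelines,
    headline_proportions,
    pearson_chi_square,
    summarize_groups,
)

DEMOGRAPHIC_FACTORS = [
    "substance",
    "nationality",
    "gender",
    "race",
    "education",
    "employment",
    "housing",
    "psychiatric_disorder",
    "physical_disorder",
]


def fixture_contingency_tables(fx: PaperFixtures) -> dict[str, ContingencyTable]:
    """Per-factor 2×C tables straight from the packaged demographic counts."""
    out = {}
    for factor, sub in fx.table2.groupby("factor", sort=False):
        out[factor] = ContingencyTable(
            factor_name=str(factor),
            row_labels=["positive", "absent"],
            column_labels=sub["level"].astype(str).tolist(),
            counts=np.array([sub["positive_n"].tolist(), sub["negative_n"].tolist()]),
        )
    return out


def reproduce_reference(rounding_tolerance_ms: float = 0.1) -> dict:
    """Recompute the study's headline numbers from the packaged tables.

    Returns a JSON-serialisable dict.  Overall-change magnitudes recomputed
    from the rounded session scores may differ from the printed column by
    one unit in the last decimal (the published changes were evidently
    computed before rounding); ``rounding_tolerance_ms`` bounds the allowed
    discrepancy when flagging rows as matching.
    """
    fx = load_fixtures()
    timelines = fx.timelines()

    # --- Table-1 column: overall change and direction per participant
    change_rows = []
    for tl, (_, printed) in zip(timelines, fx.table1.iterrows()):
        entry = {"participant": tl.participant_id}
        try:
            ch = overall_change(tl)
            entry["recomputed_change"] = round(ch.magnitude_ms, 1)
            entry["recomputed_direction"] = ch.direction.value
        except NoPostSessionError:
            entry["recomputed_change"] = None
            entry["recomputed_direction"] = None
        printed_change = printed["printed_change"]
        entry["printed_change"] = (
            None if pd.isna(printed_change) else float(printed_change)
        )
        printed_dir = printed["printed_direction"]
        entry["printed_direction"] = None if pd.isna(printed_dir) else str(printed_dir)
        if entry["printed_change"] is None or entry["recomputed_change"] is None:
            entry["match"] = entry["printed_change"] == entry["recomputed_change"]
        else:
            entry["match"] = (
                abs(entry["recomputed_change"] - entry["printed_change"])
                <= rounding_tolerance_ms + 1e-9
                and entry["recomputed_direction"] == entry["printed_direction"]
            )
        change_rows.append(entry)

    # --- headline proportions
    head = headline_proportions(timelines)

    # --- group descriptives from the substance-history tables
    mean_age_positive = float(fx.table3["age"].mean())
    mean_age_absent = float(fx.table4["age"].mean())

    # --- chi-square battery over the demographic tables
    battery_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        for factor, table in fixture_contingency_tables(fx).items():
            res = pearson_chi_square(table)
            printed = fx.chisquare_printed.set_index("factor").loc[factor]
            battery_rows.append(
                {
                    "factor": factor,
                    "statistic": round(res.statistic, 3),
                    "df": res.df,
                    "p_value": round(res.p_value, 2),
                    "min_expected": round(res.min_expected, 3),
                    "printed_statistic": float(printed["statistic"]),
                    "printed_df": int(printed["df"]),
                    "printed_p": float(printed["p"]),
                    "printed_reproducible": bool(printed["reproducible"]),
                    "match": bool(printed["reproducible"])
                    and round(res.statistic, 3) == float(printed["statistic"])
                    and res.df == int(printed["df"])
                    and round(res.p_value, 2) == float(printed["p"]),
                }
            )

    return {
        "table1": {
            "n_participants": len(timelines),
            "n_positive_baseline": head.n_positive,
            "n_absent_baseline": head.n_absent,
            "fraction_absent": head.fraction_absent,
            "no_reduction_ids": list(head.no_reduction_ids),
            "fraction_no_reduction_among_positive": (
                head.fraction_no_reduction_among_positive
            ),
            "changes": change_rows,
            "n_evaluable_changes": sum(
                1 for r in change_rows if r["recomputed_change"] is not None
            ),
            "n_matching_changes": sum(
                1
                for r in change_rows
                if r["match"] and r["printed_change"] is not None
            ),
        },
        "group_means": {
            "mean_age_positive": round(mean_age_positive, 1),
            "mean_age_absent": round(mean_age_absent, 1),
        },
        "chi_square": battery_rows,
    }


def reproduction_markdown(report: dict) -> str:
    """Human-readable summary of :func:`reproduce_reference` output."""
    t1 = report["table1"]
    lines = [
        "# Reference-table reproduction report",
        "",
        f"- Participants scored: {t1['n_participants']}",
        f"- Baseline bias present / absent: {t1['n_positive_baseline']} / "
        f"{t1['n_absent_baseline']} "
        f"({t1['fraction_absent'] * 100:.0f}% absent)",
        f"- Positive-baseline participants without a reduction: "
        f"{len(t1['no_reduction_ids'])} "
        f"({t1['fraction_no_reduction_among_positive'] * 100:.0f}%): "
        + ", ".join(t1["no_reduction_ids"]),
        f"- Overall-change column: {t1['n_matching_changes']} of "
        f"{t1['n_evaluable_changes']} evaluable rows match the printed values",
        "",
        f"- Mean age, positive group: {report['group_means']['mean_age_positive']}",
        f"- Mean age, absent group: {report['group_means']['mean_age_absent']}",
        "",
        "| factor | chi-square | df | p | printed | match |",
        "|---|---|---|---|---|---|",
    ]
    for row in report["chi_square"]:
        printed = (
            f"{row['printed_statistic']} (df {row['printed_df']}, p {row['printed_p']})"
            if row["printed_reproducible"]
            else f"{row['printed_statistic']} (documented discrepancy)"
        )
        lines.append(
            f"| {row['factor']} | {row['statistic']} | {row['df']} | "
            f"{row['p_value']} | {printed} | {'yes' if row['match'] else 'no'} |"
        )
    return "\n".join(lines) + "\n"


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: Path
    simulation: Optional[SimulationConfig] = None
    trials_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    n_planned_sessions: int = 5
    precision: int = 1


def run_pipeline(cfg: RunConfig) -> dict:
    """simulate (or load) → score → cohort stats; returns paths of the outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if cfg.simulation is not None:
        cohort = simulate_cohort(cfg.simulation)
        trials = cohort.trials
        metadata = cohort.metadata
        pbio.write_trial_log(trials, out / "trials.csv")
        pbio.write_metadata(metadata, out / "metadata.csv")
        cohort.craving.to_csv(out / "craving_vas.csv", index=False)
        outputs["trials"] = str(out / "trials.csv")
        outputs["metadata"] = str(out / "metadata.csv")
        outputs["craving"] = str(out / "craving_vas.csv")
        n_sessions = cfg.simulation.schedule.n_planned_days
    else:
        if cfg.trials_path is None or cfg.metadata_path is None:
            raise ValueError("need either a simulation config or trial/metadata paths")
        trials = pbio.read_trial_log(cfg.trials_path)
        metadata = pbio.read_metadata(cfg.metadata_path)
        n_sessions = cfg.n_planned_sessions

    timelines = score_cohort(
        trials, metadata, cfg.filter_config, n_planned_sessions=n_sessions
    )
    pbio.write_timeline_report(
        timelines,
        out / "timelines.csv",
        out / "timelines.json",
        precision=cfg.precision,
    )
    outputs["timelines"] = str(out / "timelines.csv")

    classifications = classify_timelines(timelines)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        tables = [
            build_table(metadata, classifications, f)
            for f in DEMOGRAPHIC_FACTORS
            if f in metadata.columns
            and metadata[f].nunique() >= 2
        ]
        battery = chi_square_battery(tables) if tables else pd.DataFrame()
    battery_out = battery.copy()
    if not battery_out.empty:
        battery_out["statistic"] = battery_out["statistic"].round(3)
        battery_out["p_value"] = battery_out["p_value"].round(2)
        battery_out["min_expected"] = battery_out["min_expected"].round(3)
    battery_out.to_csv(out / "chi_square.csv", index=False)
    outputs["chi_square"] = str(out / "chi_square.csv")

    head = headline_proportions(timelines)
    groups = summarize_groups(metadata, classifications)
    summary = {
        "n_scored": head.n_scored,
        "n_positive": head.n_positive,
        "n_absent": head.n_absent,
        "fraction_absent": head.fraction_absent,
        "fraction_no_reduction_among_positive": (
            None
            if np.isnan(head.fraction_no_reduction_among_positive)
            else head.fraction_no_reduction_among_positive
        ),
        "no_reduction_ids": list(head.no_reduction_ids),
        "groups": {
            label: {
                "n": g.n,
                "numeric": {
                    k: {"mean": v[0], "sd": v[1]} for k, v in g.numeric.items()
                },
                "categorical": g.categorical,
            }
            for label, g in groups.items()
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8"
    )
    outputs["summary"] = str(out / "summary.json")
    return outputs
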