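"""End-to-end orchestration: cohort in, report bundle out.

``run_pipeline`` wires the stages together — cohort and life-table CSVs in;
observed/expected/relative survival curves, per-group inverse Gompertz
fits, the %LN+ cutoff scan, pairwise tests, and a markdown report out.
Every stochastic stage consumes the single configured seed, and outputs
embed the seed and a config hash, so reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stratify as _strat
from .life_tables import LifeTable, ederer2_expected
from .records import PatientRecord, read_cohort_csv
from .stratify import (
    DEFAULT_BOUNDARIES,
    DEFAULT_CUTOFFS,
    MIN_GROUP_SIZE,
    StratificationResult,
    cutoff_scan,
    percent_ln_positive,
    stratify_by_ln_count,
    stratify_groups,
)
from .survival import km_estimate, relative_survival

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cohort_csv: str
    lifetable_csv: str
    out_dir: str
    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    truncate_month: int | None = None
    seed: int = 0
    min_group: int = MIN_GROUP_SIZE
    max_months: int = 240
    ln_count_mode: bool = False
    run_scan: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cohort_summary(cohort: Sequence[PatientRecord]) -> dict:
    """Cohort composition: counts/percentages by race, grade and radiation,
    mean +/- SD age, and a %LN+ histogram in 5% bins."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n = len(cohort)

    def _tab(values):
        counts = pd.Series(list(values)).value_counts()
        return {
            str(k): {"n": int(v), "percent": round(100.0 * v / n, 2)}
            for k, v in counts.items()
        }

    ages = np.array([r.age_at_dx for r in cohort], dtype=float)
    fracs = np.array(
        [percent_ln_positive(r) for r in cohort if r.nodes_examined >= 1]
    )
    edges = np.arange(0.0, 1.0 + 1e-9, 0.05)
    hist, _ = np.histogram(fracs, bins=edges)
    return {
        "n": n,
        "age_mean": round(float(ages.mean()), 2),
        "age_sd": round(float(ages.std(ddof=1)) if n > 1 else 0.0, 2),
        "race": _tab(r.race for r in cohort),
        "grade": _tab(r.grade for r in cohort),
        "radiation": _tab(r.radiation for r in cohort),
        "pct_ln_positive_histogram": {
            f"[{lo:.2f},{hi:.2f})": int(c)
            for lo, hi, c in zip(edges[:-1], edges[1:], hist)
        },
    }


def _write_report(
    path: Path,
    config: RunConfig,
    summary: dict,
    strat: StratificationResult,
    scan_rows,
) -> None:
    lines = [
        "# Relative-survival stratification report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash()}",
        "",
        "## Cohort composition",
        "",
        f"- n = {summary['n']}",
        f"- age = {summary['age_mean']} ± {summary['age_sd']}",
        "",
        "| field | level | n | % |",
        "|---|---|---|---|",
    ]
    for fieldname in ("race", "grade", "radiation"):
        for level, row in summary[fieldname].items():
            lines.append(
                f"| {fieldname} | {level} | {row['n']} | {row['percent']} |"
            )
    lines += [
        "",
        "## Per-group inverse Gompertz fits",
        "",
        "| group | n | b1 | b2 | b3 | IP (years) | R² |",
        "|---|---|---|---|---|---|---|",
    ]
    for g in strat.groups:
        if g.fit is None:
            lines.append(f"| {g.label} | {g.n} | - | - | - | - | - |")
        else:
            f = g.fit
            lines.append(
                f"| {g.label} | {g.n} | {f.b1:.3f} | {f.b2:.3f} | {f.b3:.3f} "
                f"| {f.ip_years:.1f} | {f.r_squared:.4f} |"
            )
    lines += ["", "## Pairwise relative-survival Z-tests", ""]
    lines += ["| group A | group B | month | z | p |", "|---|---|---|---|---|"]
    for t in strat.pairwise_tests:
        lines.append(
            f"| {t.group_a} | {t.group_b} | {t.month} | {t.z:.3f} | {t.p:.3g} |"
        )
    lines += ["", "## Pairwise log-rank tests", ""]
    lines += ["| group A | group B | statistic | p |", "|---|---|---|---|"]
    for a, b, s, p in strat.logrank_tests:
        lines.append(f"| {a} | {b} | {s:.3f} | {p:.3g} |")
    if scan_rows:
        lines += ["", "## %LN+ cutoff scan", ""]
        lines += ["| cutoff | n | IP (years) |", "|---|---|---|"]
        for r in scan_rows:
            ip = "skipped" if r.skipped else f"{r.ip_years:.2f}"
            lines.append(f"| {r.cutoff:.3f} | {r.n} | {ip} |")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns a dict of
    output paths plus the in-memory results. Partial outputs are removed if
    any stage fails."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        cohort = read_cohort_csv(config.cohort_csv)
        table = LifeTable.read_csv(config.lifetable_csv)
        logger.info("loaded cohort n=%d from %s", len(cohort), config.cohort_csv)

        meta = {"seed": config.seed, "config_hash": config.config_hash()}

        # whole-cohort curves
        expected = ederer2_expected(cohort, table, config.max_months)
        observed = km_estimate(cohort, config.max_months)
        rs = relative_survival(observed, expected)
        n_corr = int(np.sum(rs.corrections_applied != "none"))
        logger.info(
            "whole cohort: %d months, %d corrected RS values", len(rs) - 1, n_corr
        )
        for name, frame in [
            ("observed_survival.csv", observed.to_frame()),
            ("expected_survival.csv", expected.to_frame()),
            ("relative_survival.csv", rs.to_frame()),
        ]:
            p = out / name
            frame.assign(**meta).to_csv(p, index=False)
            created.append(p)

        summary = cohort_summary(cohort)
        p = out / "cohort_summary.json"
        p.write_text(json.dumps({**meta, **summary}, indent=2))
        created.append(p)

        if config.ln_count_mode:
            strat = stratify_by_ln_count(
                cohort, table, seed=config.seed,
                max_months=config.max_months,
                truncate_month=config.truncate_month,
            )
        else:
            strat = stratify_groups(
                cohort, table, boundaries=config.boundaries, seed=config.seed,
                max_months=config.max_months,
                truncate_month=config.truncate_month,
            )
        for g in strat.groups:
            logger.info(
                "group %s: n=%d converged=%s",
                g.label, g.n, g.fit.converged if g.fit else None,
            )
        p = out / "stratification.json"
        p.write_text(json.dumps({**meta, **strat.to_dict()}, indent=2))
        created.append(p)
        p = out / "group_fits.csv"
        strat.summary_frame().assign(**meta).to_csv(p, index=False)
        created.append(p)
        for g in strat.groups:
            if g.rs_curve is not None:
                safe = g.label.replace("<", "lt").replace(">=", "ge").replace("%", "")
                p = out / f"relative_survival_group_{safe}.csv"
                g.rs_curve.to_frame().assign(**meta).to_csv(p, index=False)
                created.append(p)

        scan_rows = []
        if config.run_scan:
            scan_rows = cutoff_scan(
                cohort, table, cutoffs=config.cutoffs, seed=config.seed,
                max_months=config.max_months, min_group=config.min_group,
                truncate_month=config.truncate_month,
            )
            p = out / "scan_table.csv"
            StratificationResult(groups=[], scan_table=scan_rows).scan_frame().assign(
                **meta
            ).to_csv(p, index=False)
            created.append(p)

        p = out / "report.md"
        _write_report(p, config, summary, strat, scan_rows)
        created.append(p)
        return {
            "out_dir": str(out),
            "paths": [str(p) for p in created],
            "summary": summary,
            "stratification": strat,
            "scan_table": scan_rows,
            "relative_survival": rs,
        }
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
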