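"""Emission of the projection's output tables.

Two table shapes mirror the study's presentation: a cases table (persons
per stage, five-year rows, comma-grouped) and a costs table (million GBP
to one decimal, with a discounted-total column).  PSA summaries add
"(low-high)" uncertainty-interval suffixes per cell.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .model import ProjectionResult
from .psa import PsaResult
from .stages import ESKD, STAGES

_CASE_COLS = list(STAGES) + [ESKD]


def summary_years(start_year: int, horizon: int, interval: int = 5) -> list[int]:
    years = list(range(start_year, start_year + horizon + 1, interval))
    last = start_year + horizon
    if years[-1] != last:
        years.append(last)
    return years


def summarize_cases(result: ProjectionResult, interval: int = 5) -> pd.DataFrame:
    """Numeric five-year-interval case counts per stage plus total."""
    years = summary_years(result.start_year, len(result.stocks) - 1, interval)
    df = result.counts.loc[years, _CASE_COLS].copy()
    df["Total"] = df.sum(axis=1)
    return df


def summarize_costs(result: ProjectionResult, interval: int = 5) -> pd.DataFrame:
    """Five-year-interval costs per stage in million GBP, one decimal."""
    if result.costs is None:
        raise ValueError("projection was run without a cost table")
    years = summary_years(result.start_year, len(result.stocks) - 1, interval)
    df = (result.costs.loc[years, _CASE_COLS] / 1e6).round(1)
    df["Total"] = (result.cost_totals.loc[years, "total"] / 1e6).round(1)
    df["Discounted"] = (result.cost_totals.loc[years, "total_discounted"] / 1e6).round(1)
    return df


def format_summary(result, metric: str = "cases", interval: int = 5) -> pd.DataFrame:
    """Presentation table: counts comma-grouped / costs in M GBP.

    For a deterministic :class:`ProjectionResult` the cells are plain
    values; for a :class:`PsaResult` each cell is "mean (low-high)".
    """
    if isinstance(result, PsaResult):
        return _format_psa(result, metric=metric, interval=interval)
    if metric == "cases":
        df = summarize_cases(result, interval)
        return df.map(lambda v: f"{v:,.0f}")
    if metric == "costs":
        return summarize_costs(result, interval).map(lambda v: f"{v:,.1f}")
    raise ValueError(f"unknown metric {metric!r}")


def _format_psa(psa: PsaResult, metric: str, interval: int) -> pd.DataFrame:
    key = "cases" if metric == "cases" else "cost_gbp"
    sub = psa.summary[psa.summary["metric"] == key]
    years = sorted(sub["year"].unique())
    wanted = years[::interval]
    if years[-1] not in wanted:
        wanted.append(years[-1])
    scale, fmt = (1.0, ",.0f") if metric == "cases" else (1e6, ",.1f")
    cols = _CASE_COLS + (["total_ckd"] if metric == "cases" else ["total"])
    out = {}
    for state in cols:
        cell = {}
        rows = sub[sub["state"] == state].set_index("year")
        for y in wanted:
            r = rows.loc[y]
            cell[y] = (f"{r['mean'] / scale:{fmt}} "
                       f"({r['ui_low'] / scale:{fmt}}-{r['ui_high'] / scale:{fmt}})")
        out[state] = cell
    df = pd.DataFrame(out)
    df.index.name = "year"
    return df


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    config: str
    scenario: str
    horizon: int
    discount_rate: float
    psa: bool
    iterations: int | None
    seed: int | None
    tool_version: str
    timestamp: str

    @classmethod
    def create(cls, **kw) -> "RunManifest":
        from . import __version__
        return cls(tool_version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat(), **kw)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def write_outputs(outdir: Path, results: list[ProjectionResult],
                  psa_results: list[PsaResult] | None = None) -> list[Path]:
    """Write tidy CSVs and summary tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cases = pd.concat([r.counts_tidy() for r in results], ignore_index=True)
    p = outdir / "cases.csv"
    cases.to_csv(p, index=False)
    written.append(p)

    cost_rows = []
    for r in results:
        if r.costs is None:
            continue
        disc = (r.cost_totals["total_discounted"] / r.cost_totals["total"]).fillna(1.0)
        for year in r.costs.index:
            for state in _CASE_COLS:
                c = float(r.costs.loc[year, state])
                cost_rows.append((year, r.scenario, state, c,
                                  c * float(disc.loc[year])))
    if cost_rows:
        p = outdir / "costs.csv"
        pd.DataFrame(cost_rows, columns=["year", "scenario", "state", "cost_gbp",
                                         "cost_gbp_discounted"]).to_csv(p, index=False)
        written.append(p)

    for r in results:
        p = outdir / f"summary_cases_{r.scenario}.csv"
        format_summary(r, "cases").to_csv(p)
        written.append(p)
        if r.costs is not None:
            p = outdir / f"summary_costs_{r.scenario}.csv"
            format_summary(r, "costs").to_csv(p)
            written.append(p)

    for psa in psa_results or []:
        p = outdir / f"psa_summary_{psa.scenario}.csv"
        psa.summary.to_csv(p, index=False)
        written.append(p)
    return written
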