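"""CSV dialects, JSON results and report generation.

Two plain-text dialects carry all pipeline data (comma-separated, UTF-8,
'.' decimal, mandatory header, units embedded in column names):

time-course CSV
    variant, condition, replicate, time_min, product_nM, substrate_total_nM

melt CSV
    variant, replicate, temperature_C, theta222

Validation is row-addressed: a bad value is reported with the 1-based data
row that contains it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import BurstFit, DomainError, MeltCurve, TimeCourse

__all__ = [
    "ParseError",
    "RunConfig",
    "TIME_COURSE_COLUMNS",
    "MELT_COLUMNS",
    "read_time_course_csv",
    "write_time_course_csv",
    "read_melt_csv",
    "write_melt_csv",
    "burst_fit_to_dict",
    "melt_summary_to_dict",
    "write_results",
]

TIME_COURSE_COLUMNS = [
    "variant",
    "condition",
    "replicate",
    "time_min",
    "product_nM",
    "substrate_total_nM",
]

MELT_COLUMNS = ["variant", "replicate", "temperature_C", "theta222"]

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """A CSV file violates the dialect; the message names the row."""


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run, written next to its
    outputs so the run can be reproduced byte-identically."""

    seed: int = 0
    outdir: str = "."
    inputs: list = dataclasses.field(default_factory=list)
    bootstrap_draws: int = 2000
    model_alpha: float = 0.01
    smoothing_window: int = 11
    smoothing_order: int = 3
    dh_init: float = 200.0
    report_format: str = "text"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, outdir: Union[str, Path]) -> Path:
        path = Path(outdir) / "run_config.json"
        path.write_text(self.to_json() + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _require_columns(df: pd.DataFrame, required: list, path: Union[str, Path]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_time_course_csv(path: Union[str, Path]) -> list:
    """Read a time-course CSV into TimeCourse objects (one per
    variant × condition group, replicate points pooled)."""
    df = pd.read_csv(path)
    _require_columns(df, TIME_COURSE_COLUMNS, path)
    for i, row in df.iterrows():
        rowno = int(i) + 1
        try:
            t = float(row["time_min"])
            p = float(row["product_nM"])
            s = float(row["substrate_total_nM"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {rowno}: non-numeric value") from exc
        if t < 0:
            raise ParseError(f"{path}: row {rowno}: negative time {t}")
        if p < 0:
            raise ParseError(f"{path}: row {rowno}: negative product {p}")
        if s <= 0:
            raise ParseError(f"{path}: row {rowno}: non-positive substrate total {s}")
        if p > s + 1e-9:
            raise ParseError(
                f"{path}: row {rowno}: product {p} nM exceeds substrate total {s} nM"
            )
    out = []
    for (variant, condition), g in df.groupby(["variant", "condition"], sort=True):
        s_totals = g["substrate_total_nM"].unique()
        if s_totals.size > 1:
            raise ParseError(
                f"{path}: conflicting substrate totals {sorted(s_totals)} "
                f"for {variant}/{condition}"
            )
        out.append(
            TimeCourse(
                variant=str(variant),
                condition=str(condition),
                substrate_total=float(s_totals[0]),
                time=g["time_min"].to_numpy(dtype=float),
                product=g["product_nM"].to_numpy(dtype=float),
                replicate=g["replicate"].astype(str).to_numpy(),
            )
        )
    return out


def write_time_course_csv(tcs: Sequence[TimeCourse], path: Union[str, Path]) -> None:
    frames = []
    for tc in tcs:
        frames.append(
            pd.DataFrame(
                {
                    "variant": tc.variant,
                    "condition": tc.condition,
                    "replicate": tc.replicate,
                    "time_min": tc.time,
                    "product_nM": tc.product,
                    "substrate_total_nM": tc.substrate_total,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[TIME_COURSE_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_melt_csv(path: Union[str, Path]) -> list:
    """Read a melt CSV into MeltCurve objects, one per variant × replicate,
    sorted by temperature; duplicate temperatures within a replicate are
    rejected."""
    df = pd.read_csv(path)
    _require_columns(df, MELT_COLUMNS, path)
    for i, row in df.iterrows():
        rowno = int(i) + 1
        try:
            t = float(row["temperature_C"])
            float(row["theta222"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {rowno}: non-numeric value") from exc
        if not (0 <= t <= 100):
            raise ParseError(
                f"{path}: row {rowno}: temperature {t} °C outside [0, 100]"
            )
    out = []
    for (variant, replicate), g in df.groupby(["variant", "replicate"], sort=True):
        g = g.sort_values("temperature_C")
        temps = g["temperature_C"].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(temps) == 0)[0]
        if dup.size:
            raise ParseError(
                f"{path}: duplicate temperature {temps[dup[0]]} °C in "
                f"{variant}/{replicate}"
            )
        out.append(
            MeltCurve(
                variant=str(variant),
                replicate=str(replicate),
                temperature=temps,
                theta222=g["theta222"].to_numpy(dtype=float),
            )
        )
    return out


def write_melt_csv(curves: Sequence[MeltCurve], path: Union[str, Path]) -> None:
    frames = [
        pd.DataFrame(
            {
                "variant": c.variant,
                "replicate": c.replicate,
                "temperature_C": c.temperature,
                "theta222": c.theta222,
            }
        )
        for c in curves
    ]
    df = pd.concat(frames, ignore_index=True)[MELT_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def burst_fit_to_dict(fit: BurstFit) -> dict:
    return {
        "variant": fit.variant,
        "condition": fit.condition,
        "model": fit.model,
        "A0_nM": fit.A0,
        "k1_per_min": fit.k1,
        "k2_nM_per_min": fit.k2,
        "se": fit.se,
        "bootstrap_se": fit.bootstrap_se,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "substrate_total_nM": fit.substrate_total,
        "converged": fit.converged,
        "message": fit.message,
    }


def melt_summary_to_dict(avg) -> dict:
    """Serialise a MeltAverage (or a single MeltFit) for the results JSON."""
    if hasattr(avg, "tm_values"):
        return {
            "variant": avg.variant,
            "Tm_C": avg.tm_mean,
            "Tm_sd_C": avg.tm_sd,
            "Tm_replicates_C": list(avg.tm_values),
            "dH_vH_kJ_per_mol": [f.dh_vh for f in avg.fits],
            "Tm_derivative_C": [f.tm_derivative for f in avg.fits],
        }
    return {
        "variant": avg.variant,
        "Tm_C": avg.tm,
        "Tm_se_C": avg.se_tm,
        "dH_vH_kJ_per_mol": avg.dh_vh,
        "Tm_derivative_C": avg.tm_derivative,
        "native_baseline": list(avg.native_baseline),
        "denatured_baseline": list(avg.denatured_baseline),
    }


def _fmt(v: Optional[float], prec: int = 3) -> str:
    return "--" if v is None else f"{v:.{prec}f}"


def write_results(
    fits: Sequence[BurstFit] = (),
    melts: Sequence = (),
    panel=None,
    outdir: Union[str, Path] = ".",
) -> dict:
    """Write results.json (full precision) and report.txt (summary tables).

    The text report mirrors the study's presentation: a kinetics table
    with columns A0 (nM), k1 (min⁻¹), k2 (nM·min⁻¹), a Tm table, and the
    thermolability panel when present. Returns the results dictionary.
    """
    if not fits and not melts and panel is None:
        raise ValueError("no results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if fits:
        results["kinetics"] = [burst_fit_to_dict(f) for f in fits]
    if melts:
        results["thermal"] = [melt_summary_to_dict(m) for m in melts]
    if panel is not None:
        results["thermolability"] = {
            "rows": panel.to_records(),
            "protection": [dataclasses.asdict(p) for p in panel.protection],
            "missing": [list(m) for m in panel.missing],
        }
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    lines = []
    if fits:
        lines.append("DNA glycosylase activity rate constants")
        lines.append(
            f"{'variant':<12}{'condition':<12}{'A0 (nM)':>12}"
            f"{'k1 (min^-1)':>14}{'k2 (nM/min)':>14}  model"
        )
        for f in fits:
            a0 = _fmt(f.A0, 2)
            k1 = _fmt(f.k1, 3)
            se_a0 = _fmt(f.se.get("A0"), 2) if f.A0 is not None else ""
            se_k1 = _fmt(f.se.get("k1"), 3) if f.k1 is not None else ""
            a0s = f"{a0} ± {se_a0}" if se_a0 else a0
            k1s = f"{k1} ± {se_k1}" if se_k1 else k1
            k2s = f"{f.k2:.3f} ± {_fmt(f.se.get('k2'), 3)}"
            lines.append(
                f"{f.variant:<12}{f.condition:<12}{a0s:>12}{k1s:>14}{k2s:>14}  {f.model}"
            )
        lines.append("")
    if melts:
        lines.append("Melting temperatures (CD, 222 nm)")
        lines.append(f"{'variant':<12}{'Tm (°C)':>10}{'SD/SE (°C)':>12}")
        for m in melts:
            d = melt_summary_to_dict(m)
            spread = d.get("Tm_sd_C", d.get("Tm_se_C"))
            lines.append(f"{d['variant']:<12}{d['Tm_C']:>10.2f}{_fmt(spread, 2):>12}")
        lines.append("")
    if panel is not None:
        lines.append(panel.render_text())
    else:
        lines.append("(no thermolability panel in this run)")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return results
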