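"""End-to-end study analysis and study-style output tables.

:func:`run_study_analysis` reproduces the analysis plan of a two-session,
multi-observer staging study:

* descriptives — session-1 stage counts and percentages per (method,
  tooth), I3M median and quartiles, NA counts;
* intra-observer — per observer and tooth, weighted Cohen's kappa between
  the two sessions (ordinal weights by default) for staging methods, and
  the two-way absolute-agreement ICC for the continuous I3M;
* inter-observer — session 1 only, Gwet's AC2 with ordinal weights over
  the observed-category alphabet for staging methods (overall, per jaw
  where both jaws are staged, per tooth) and ICC for I3M (overall and per
  tooth); NA responses are excluded observation-wise and the retained
  observation totals are reported;
* NA concordance — unweighted AC1 on the NA / not-NA binarization over
  all cells, with the 5% prevalence audit.

Benchmark labels follow Landis-Koch for kappa/AC and Portney-Watkins for
ICC.  :func:`format_tables` serializes the report deterministically to
CSV, JSON and/or pipe-table markdown with coefficients at 3 decimals and
percentages at 1 decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import cohen_kappa_weighted, gwet_ac
from .icc import icc_absolute, icc_intra
from .na import na_agreement
from .study import (
    MANDIBULAR,
    MAXILLARY,
    RatingTable,
    pivot_to_matrix,
    session_pairs,
)
from .weights import build_weights, weights_for_matrix

ASSUMPTIONS = (
    "inter-observer coefficients use session 1 only",
    "intra-observer weighted kappa uses ordinal weights (same kind as AC2)",
    "pooled coefficients treat each (subject, tooth) pair as one unit",
    "category exclusion applied per analyzed table",
)


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    intra_table: pd.DataFrame
    inter_tables: dict  # method -> DataFrame
    na_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _scopes(scheme):
    """Row layout of an inter-observer table for one method."""
    teeth = sorted(scheme.applicable_teeth)
    scopes = [("Overall", set(teeth))]
    if scheme.method_id in ("DEM", "GHK"):
        scopes.append(("Maxillary", set(MAXILLARY)))
        scopes.append(("Mandibular", set(MANDIBULAR)))
    for t in teeth:
        scopes.append((f"FDI {t}", {t}))
    return scopes


def _descriptives(table: RatingTable, session: int = 1) -> pd.DataFrame:
    rows = []
    for method in table.methods():
        scheme = table.schemes[method]
        for tooth in sorted(scheme.applicable_teeth):
            sub = table.df[
                (table.df["method"] == method)
                & (table.df["tooth"] == tooth)
                & (table.df["session"] == session)
            ]
            total = len(sub)
            if total == 0:
                continue
            values = sub["value"]
            n_na = int(values.isna().sum())
            if scheme.is_continuous:
                x = values.dropna().astype(float)
                rows.append(
                    {
                        "method": method, "tooth": tooth, "category": "median (Q1-Q3)",
                        "count": total - n_na, "percent": np.nan,
                        "median": round(float(x.median()), 2),
                        "q1": round(float(x.quantile(0.25)), 2),
                        "q3": round(float(x.quantile(0.75)), 2),
                    }
                )
            else:
                for cat in scheme.categories:
                    c = int((values == cat).sum())
                    rows.append(
                        {
                            "method": method, "tooth": tooth, "category": cat,
                            "count": c, "percent": round(100 * c / total, 1),
                            "median": np.nan, "q1": np.nan, "q3": np.nan,
                        }
                    )
            rows.append(
                {
                    "method": method, "tooth": tooth, "category": "NA",
                    "count": n_na, "percent": round(100 * n_na / total, 1),
                    "median": np.nan, "q1": np.nan, "q3": np.nan,
                }
            )
    return pd.DataFrame(rows)


def _intra(table: RatingTable, weight_kind: str) -> pd.DataFrame:
    rows = []
    for obs in table.observers():
        for method in table.methods():
            scheme = table.schemes[method]
            for tooth in sorted(scheme.applicable_teeth):
                pairs = session_pairs(table, obs, method, tooth)
                complete = [(a, b) for a, b, ok in pairs if ok]
                n_excluded = len(pairs) - len(complete)
                if scheme.is_continuous:
                    res = icc_intra(complete)
                    rows.append(
                        {
                            "observer": obs, "method": method, "tooth": tooth,
                            "statistic": "ICC(A,1)", "coefficient": res.icc,
                            "ci_low": res.ci_low, "ci_high": res.ci_high,
                            "n_pairs": res.n_subjects, "n_excluded": n_excluded,
                            "benchmark": res.benchmark() if np.isfinite(res.icc) else "",
                        }
                    )
                    continue
                used = sorted(
                    {v for p in complete for v in p}, key=scheme.categories.index
                )
                kind = weight_kind if len(used) > 1 else "identity"
                res = cohen_kappa_weighted(complete, build_weights(tuple(used), kind))
                rows.append(
                    {
                        "observer": obs, "method": method, "tooth": tooth,
                        "statistic": f"kappa_w[{kind}]", "coefficient": res.coefficient,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "n_pairs": res.n_units, "n_excluded": n_excluded,
                        "benchmark": res.benchmark("landis_koch"),
                    }
                )
    return pd.DataFrame(rows)


def _inter(table: RatingTable, weight_kind: str, session: int) -> dict:
    out = {}
    for method in table.methods():
        scheme = table.schemes[method]
        rows = []
        for scope_name, teeth in _scopes(scheme):
            pooling = "per_tooth" if len(teeth) == 1 else (
                "overall" if scope_name == "Overall" else "per_jaw"
            )
            matrix = pivot_to_matrix(table, method, teeth=teeth, session=session,
                                     pooling=pooling)
            if scheme.is_continuous:
                res = icc_absolute(matrix)
                rows.append(
                    {
                        "scope": scope_name, "statistic": "ICC(A,1)",
                        "coefficient": res.icc, "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n_observations": res.n_subjects * res.k_raters,
                        "p_value": res.p_value,
                        "benchmark": res.benchmark() if np.isfinite(res.icc) else "",
                    }
                )
                continue
            w = weights_for_matrix(matrix, weight_kind)
            res = gwet_ac(matrix, w)
            rows.append(
                {
                    "scope": scope_name,
                    "statistic": "AC1" if w.is_identity else f"AC2[{w.kind}]",
                    "coefficient": res.coefficient, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "n_observations": res.n_observations,
                    "p_value": res.p_value,
                    "benchmark": res.benchmark("landis_koch"),
                }
            )
        out[method] = pd.DataFrame(rows)
    return out


def _na(table: RatingTable, session: int) -> pd.DataFrame:
    rows = []
    for method in table.methods():
        scheme = table.schemes[method]
        scopes = [("Overall", set(scheme.applicable_teeth))]
        if scheme.method_id in ("DEM", "GHK"):
            scopes += [("Maxillary", set(MAXILLARY)), ("Mandibular", set(MANDIBULAR))]
        for scope_name, teeth in scopes:
            matrix = pivot_to_matrix(
                table, method, teeth=teeth, session=session,
                pooling="overall" if scope_name == "Overall" else "per_jaw",
            )
            rep = na_agreement(matrix)
            rows.append(
                {
                    "method": method, "scope": scope_name,
                    "coefficient": rep.ac1.coefficient,
                    "ci_low": rep.ac1.ci_low, "ci_high": rep.ac1.ci_high,
                    "n_observations": matrix.cells.size,
                    "p_value": rep.ac1.p_value,
                    "na_count": rep.na_count,
                    "na_proportion": rep.na_proportion,
                    "prevalence_flag": rep.prevalence_flag,
                    "benchmark": rep.ac1.benchmark("landis_koch"),
                }
            )
    return pd.DataFrame(rows)


def run_study_analysis(
    table: RatingTable,
    weight_kind: str = "ordinal",
    inter_session: int = 1,
    provenance: dict | None = None,
) -> StudyReport:
    """Full intra/inter/NA analysis of a validated two-session table."""
    report = StudyReport(
        descriptives=_descriptives(table, session=1),
        intra_table=_intra(table, weight_kind),
        inter_tables=_inter(table, weight_kind, inter_session),
        na_table=_na(table, inter_session),
    )
    report.provenance = {
        "software": f"agreedent {__version__}",
        "weight_kind": weight_kind,
        "inter_session": inter_session,
        "assumptions": list(ASSUMPTIONS),
        **(provenance or {}),
    }
    return report


# ---------------------------------------------------------------- rendering

_COEF_COLS = ("coefficient", "ci_low", "ci_high", "median", "q1", "q3",
              "na_proportion")


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if c in _COEF_COLS:
            out[c] = out[c].map(lambda v: round(v, 3) if pd.notna(v) else v)
        elif c == "percent":
            out[c] = out[c].map(lambda v: round(v, 1) if pd.notna(v) else v)
        elif c == "p_value":
            out[c] = out[c].map(
                lambda v: ("<0.001" if v < 0.001 else round(v, 3)) if pd.notna(v) else v
            )
    return out


def _to_markdown(df: pd.DataFrame) -> str:
    df = _rounded(df)
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if pd.isna(v):
                cells.append("NA")
            elif isinstance(v, float):
                cells.append(format(v, ".3f") if c in _COEF_COLS else format(v, "g"))
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def format_tables(report: StudyReport, formats=("csv", "json"), out_dir=".") -> list:
    """Write the report tables; returns the list of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    named = {
        "descriptives": report.descriptives,
        "intra_observer": report.intra_table,
        "na_concordance": report.na_table,
    }
    for method, df in report.inter_tables.items():
        named[f"inter_observer_{method}"] = df
    written = []
    for fmt in formats:
        if fmt == "csv":
            for name, df in named.items():
                path = out_dir / f"{name}.csv"
                _rounded(df).to_csv(path, index=False)
                written.append(path)
        elif fmt == "json":
            payload = {"provenance": report.provenance}
            for name, df in named.items():
                payload[name] = json.loads(_rounded(df).to_json(orient="records"))
            path = out_dir / "report.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            written.append(path)
        elif fmt == "markdown":
            parts = [f"# Reliability report\n\nSoftware: {report.provenance.get('software', '')}\n"]
            for name, df in named.items():
                parts.append(f"\n## {name.replace('_', ' ')}\n\n" + _to_markdown(df))
            path = out_dir / "report.md"
            path.write_text("".join(parts))
            written.append(path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return written
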