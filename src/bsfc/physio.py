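"""Physiological summary statistics per anesthetic state.

Reproduces the per-subject group summaries (burst-suppression ratio, heart
rate, end-tidal CO2, body temperature) and the BS-vs-SW significance tests of
the study's physiology table, which ships with the package as a plain-text
fixture.  Group comparisons use a pooled two-sample Student t-test, which
reproduces every printed p-value of the source table.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

VARIABLES = {
    "bsr": "bsr_pct",
    "heart_rate": "heart_rate_bpm",
    "etco2": "etco2_mmhg",
    "temperature": "temperature_c",
}
# variables tested between groups (BSR is zero by definition in SW runs)
TESTED_VARIABLES = ["heart_rate", "etco2", "temperature"]


def load_physiology_table(path=None) -> pd.DataFrame:
    """Load the per-run physiology table (packaged fixture by default)."""
    if path is None:
        ref = resources.files("bsfc") / "data" / "table1_physiology.tsv"
        with resources.as_file(ref) as f:
            table = pd.read_csv(f, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"subject", "group", *VARIABLES.values()}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"physiology table lacks columns: {sorted(missing)}")
    bad = set(table["group"]) - {"BS", "SW"}
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    if (table.loc[table["group"] == "SW", "bsr_pct"] != 0).any():
        raise ValueError("SW rows must have BSR = 0")
    return table


def round_half_away(x: float, ndigits: int) -> float:
    """Decimal round-half-away-from-zero (display convention of the table)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def group_summary(
    table: pd.DataFrame,
    subject: str,
    variable: str,
    group: str,
    ndigits: int | None = None,
) -> float:
    """Arithmetic group mean of one variable for one subject.

    ``ndigits`` applies half-away-from-zero display rounding (the summary
    cells of the source table carry different printed precisions, so callers
    choose the precision to compare at).
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; choose from {list(VARIABLES)}")
    sub = table[(table["subject"] == subject) & (table["group"] == group)]
    if sub.empty:
        raise ValueError(f"no rows for subject {subject!r}, group {group!r}")
    mean = float(sub[VARIABLES[variable]].mean())
    return mean if ndigits is None else round_half_away(mean, ndigits)


def pooled_t_test(x, y) -> tuple[float, int, float]:
    """Two-sample Student t with pooled variance; returns (t, df, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    df = len(x) + len(y) - 2
    s2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if s2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ValueError("degenerate: zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(s2 * (1 / len(x) + 1 / len(y)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def format_p(p: float) -> str:
    """Three-decimal p-value; values below 0.0005 render as '<0.000'."""
    if p < 0.0005:
        return "<0.000"
    return f"{round_half_away(p, 3):.3f}"


def physio_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject group means and BS-vs-SW p-values, mirroring the source
    table's summary and P-value rows.

    Returns a long-format frame with one row per (subject, statistic,
    variable) cell; formatted p strings use 3-decimal rounding with the
    '<0.000' convention for p < 0.0005.
    """
    rows = []
    for subject in sorted(table["subject"].unique()):
        sub = table[table["subject"] == subject]
        for grp in ("BS", "SW"):
            if sub[sub["group"] == grp].empty:
                raise ValueError(f"subject {subject!r} lacks group {grp}")
        for variable, col in VARIABLES.items():
            if sub[col].isna().any():
                raise ValueError(f"missing values in column {col}")
            for grp in ("BS", "SW"):
                if variable == "bsr" and grp == "SW":
                    continue
                mean = group_summary(table, subject, variable, grp)
                rows.append(
                    {
                        "subject": subject,
                        "statistic": f"{grp}_mean",
                        "variable": variable,
                        "value": mean,
                        "formatted": f"{round_half_away(mean, 4):g}",
                    }
                )
            if variable in TESTED_VARIABLES:
                x = sub.loc[sub["group"] == "BS", col].to_numpy()
                y = sub.loc[sub["group"] == "SW", col].to_numpy()
                t, _, p = pooled_t_test(x, y)
                rows.append(
                    {
                        "subject": subject,
                        "statistic": "p_value",
                        "variable": variable,
                        "value": p,
                        "formatted": format_p(p),
                    }
                )
    return pd.DataFrame(rows)
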