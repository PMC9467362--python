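"""Settlement statistics: fractions, the angular transform, ANOVA with Tukey
HSD contrasts, settlement-location geometry, and the settlement-vs-Q recast.

Settlement proportions are variance-stabilized with the arcsine-square-root
(angular) transform before significance testing; fixed-effects one- or
two-way ANOVA and post-hoc Tukey honestly-significant-difference contrasts
are computed with statsmodels at a significance level of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "settlement_fraction",
    "arcsine_transform",
    "anova_tukey",
    "ridge_distance_histogram",
    "settlement_q_table",
]


def settlement_fraction(data, group: Optional[str] = None,
                        settled_col: str = "settled", total_col: str = "total"):
    """Settlement percentage(s): 100 x settled / total.

    Accepts a ``SimulationResult`` (lattice-based percentages of settled /
    exited / unresolved agents), a DataFrame of counts with ``settled`` and
    ``total`` columns (optionally percent per ``group``), or a plain
    (settled, total) pair.
    """
    if hasattr(data, "records"):  # SimulationResult
        return data.fractions()
    if isinstance(data, pd.DataFrame):
        if (data[total_col] <= 0).any():
            raise ValueError("zero total in settlement table")
        pct = 100.0 * data[settled_col] / data[total_col]
        if group is not None:
            return pct.groupby(data[group]).mean()
        return pct
    settled, total = data
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * settled / total


def arcsine_transform(p):
    """Angular transform asin(sqrt(p)) [rad] for proportions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return out if out.ndim else float(out)


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA decomposition plus Tukey HSD contrasts.

    ``table`` holds F and p per effect (statsmodels anova_lm layout);
    ``tukey`` holds pairwise group differences with family-wise adjusted p.
    """

    table: pd.DataFrame
    tukey: pd.DataFrame
    residual_df: int
    alpha: float = 0.05

    def effect(self, name: str) -> dict:
        row = self.table.loc[name]
        return {"F": float(row["F"]), "p": float(row["PR(>F)"]),
                "df": float(row["df"])}

    def significant_pairs(self) -> pd.DataFrame:
        return self.tukey[self.tukey["reject"]]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "residual_df": self.residual_df,
            "effects": {
                str(i): {"df": float(r["df"]), "F": (None if np.isnan(r["F"]) else float(r["F"])),
                         "p": (None if np.isnan(r["PR(>F)"]) else float(r["PR(>F)"]))}
                for i, r in self.table.iterrows()},
            "tukey": self.tukey.to_dict(orient="records"),
        }


def anova_tukey(data: pd.DataFrame, value: str, factors: Sequence[str],
                alpha: float = 0.05, transform: bool = False) -> AnovaResult:
    """One- or two-way fixed-effects ANOVA with Tukey HSD contrasts.

    ``factors`` names one or two categorical columns of ``data``; with two
    factors the model includes their interaction, and the Tukey contrasts
    compare the factor-combination groups.  ``transform=True`` applies the
    angular transform to ``value`` (which must then hold proportions in
    [0, 1]) before testing.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors required")
    df = data[factors].copy()
    y = data[value].to_numpy(dtype=float)
    if transform:
        y = arcsine_transform(y)
    df["_y"] = y
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    groups = df.groupby(factors, observed=True)["_y"]
    if len(factors) == 2 and (groups.size() < 2).any():
        raise ValueError("two-factor ANOVA needs >= 2 replicates per cell")
    if np.allclose(groups.var(ddof=1).fillna(0.0), 0.0) and \
            np.allclose(df["_y"].var(ddof=1), 0.0):
        warnings.warn("degenerate data: zero variance everywhere", stacklevel=2)

    terms = " * ".join(f"C({f})" for f in factors)
    model = ols(f"_y ~ {terms}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=2)

    if len(factors) == 1:
        labels = df[factors[0]].astype(str)
    else:
        labels = df[factors[0]].astype(str) + ":" + df[factors[1]].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tk = pairwise_tukeyhsd(df["_y"].to_numpy(), labels.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey["reject"] = tukey["reject"].astype(bool)
    return AnovaResult(table=table, tukey=tukey,
                       residual_df=int(model.df_resid), alpha=alpha)


def ridge_distance_histogram(x_positions, substrate, within: float = 1.0):
    """Horizontal distance of each settler to the nearest ridge flank.

    Flanks sit at local x = 0 and x = ridge_width within each ridge period
    (floor level).  Returns (distances, fraction_within) where the fraction
    counts settlers within ``within`` mm of a flank.
    """
    if substrate.kind != "ridged":
        raise ValueError("ridge distances need a ridged substrate")
    x = np.asarray(x_positions, dtype=float)
    p, w = substrate.period, substrate.ridge_width
    xt = np.mod(x, p)
    d = np.minimum.reduce([np.abs(xt - 0.0), np.abs(xt - w), np.abs(xt - p)])
    frac = float(np.mean(d <= within)) if len(d) else np.nan
    return d, frac


def settlement_q_table(classified: pd.DataFrame, run_col: str = "run",
                       species_col: str = "species",
                       above_col: str = "above_q",
                       all_runs: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-run percentages of settlers above/below Q_thresh, per species.

    ``classified`` has one row per settler with its run id, species label and
    boolean Q classification (from ``flowstats.classify_points_by_q``).  Runs
    listed in ``all_runs`` but contributing no settlers are excluded with a
    warning (missing data, not zeros).
    The long-format output (run, species, q_class, percent) feeds the
    two-factor ANOVA (Q class x species).
    """
    for col in (run_col, species_col, above_col):
        if col not in classified.columns:
            raise ValueError(f"missing classification column {col!r}")
    if classified[above_col].isna().any():
        raise ValueError("missing Q classification for some settlers")
    rows = []
    for (run, sp), sub in classified.groupby([run_col, species_col], observed=True):
        n = len(sub)
        if n == 0:
            continue
        pct_above = 100.0 * sub[above_col].sum() / n
        rows.append((run, sp, "above", pct_above, n))
        rows.append((run, sp, "below", 100.0 - pct_above, n))
    if all_runs is not None:
        present = {r for r, _, _, _, _ in rows}
        for r in all_runs:
            if r not in present:
                warnings.warn(f"run {r!r} has no settlers; excluded", stacklevel=2)
    return pd.DataFrame(rows, columns=[run_col, species_col, "q_class",
                                       "percent", "n_settlers"])
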