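"""Effect-size statistics for reliability tables.

``repeated_anova`` covers balanced, fully crossed designs with up to two
within-unit (repeated) factors and at most one between-unit factor, one
observation per cell — the designs used when ICC values serve as
observations and construction choices (parcellation, resolution, metric
order, regional class) serve as factors.  Each within effect is tested
against its interaction with units; partial eta squared is
``SS_effect / (SS_effect + SS_error_effect)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["EffectTable", "repeated_anova", "paired_ttest", "PairedTResult"]

_SS_TOL = 1e-10  # clip tiny negative sums of squares from floating error


@dataclass
class EffectTable:
    """Per-effect decomposition: SS, df, F, p, partial eta squared."""

    effects: pd.DataFrame
    ss_total: float
    design: str

    def __getitem__(self, effect: str) -> pd.Series:
        return self.effects.set_index("effect").loc[effect]


def _clip_ss(x: float) -> float:
    if x < -_SS_TOL:
        raise AssertionError(f"negative sum of squares {x}")
    return max(0.0, x)


def _check_balanced(df: pd.DataFrame, unit: str, cols: list[str]) -> None:
    counts = df.groupby([unit] + cols, observed=True).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("design must be balanced with one observation per cell")
    per_unit = df.groupby(unit, observed=True).size()
    if per_unit.nunique() != 1:
        raise ValueError("design must be balanced across units")


def repeated_anova(
    table: pd.DataFrame,
    dv: str,
    unit: str,
    within: list[str] | None = None,
    between: str | None = None,
) -> EffectTable:
    """Classical SS decomposition for a balanced repeated-measures design.

    Parameters
    ----------
    table : tidy DataFrame with one row per observation.
    dv : name of the dependent-variable column.
    unit : name of the unit (subject / metric / region) id column.
    within : up to two repeated-measure factor columns.
    between : optional categorical factor column (units nested in it).
    """
    within = list(within or [])
    if len(within) > 2:
        raise ValueError("at most two within factors are supported")
    cols = within + ([between] if between else [])
    if not cols:
        raise ValueError("at least one factor is required")
    df = table[[unit, dv] + cols].copy()
    _check_balanced(df, unit, within)
    if between is not None:
        g_per_unit = df.groupby(unit, observed=True)[between].nunique()
        if (g_per_unit != 1).any():
            raise ValueError("each unit must belong to exactly one between-group")
        sizes = df.drop_duplicates(unit).groupby(between, observed=True).size()
        if sizes.nunique() != 1:
            raise ValueError("between-groups must have equal numbers of units")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    n_units = df[unit].nunique()
    levels = {f: sorted(df[f].unique(), key=str) for f in within}
    n_cells = int(np.prod([len(levels[f]) for f in within])) if within else 1
    n_groups = df[between].nunique() if between else 1

    def mean_by(*keys: str) -> pd.Series:
        return df.groupby(list(keys), observed=True)[dv].mean()

    rows = []

    # between-units stratum
    unit_means = mean_by(unit)
    ss_units = _clip_ss(float(n_cells * ((unit_means - grand) ** 2).sum()))
    if between:
        group_means = mean_by(between)
        units_per_group = n_units // n_groups
        ss_b = _clip_ss(
            float(n_cells * units_per_group * ((group_means - grand) ** 2).sum())
        )
        ss_units_within = _clip_ss(ss_units - ss_b)
        df_b, df_uw = n_groups - 1, n_units - n_groups
        rows.append((between, ss_b, df_b, ss_units_within, df_uw))
    else:
        ss_units_within = ss_units

    unit_group = (
        df.drop_duplicates(unit).set_index(unit)[between] if between else None
    )

    accounted = [ss_units]  # running total of decomposed SS

    def within_effect(factors: list[str]) -> None:
        """Add a within effect (1 or 2 factors), its between-interaction,
        and its unit-interaction error term.  The highest-order within
        term's error is the residual of the full decomposition, which is
        its unit interaction in a balanced one-observation-per-cell
        design and guarantees exact SS conservation."""
        a = int(np.prod([len(levels[f]) for f in factors]))
        mult = n_cells // a
        cell = mean_by(*factors)
        if len(factors) == 1:
            dev = cell - grand
            df_eff = a - 1
        else:
            f1, f2 = factors
            m1, m2 = mean_by(f1), mean_by(f2)
            dev = cell.copy()
            for (l1, l2) in dev.index:
                dev.loc[(l1, l2)] = (
                    cell.loc[(l1, l2)] - m1.loc[l1] - m2.loc[l2] + grand
                )
            df_eff = (len(levels[f1]) - 1) * (len(levels[f2]) - 1)
        ss_eff = _clip_ss(float(mult * n_units * (dev**2).sum()))

        # interaction with the between factor
        ss_int_b = 0.0
        df_int_b = 0
        if between:
            gcell = mean_by(between, *factors)
            gmean = mean_by(between)
            total = 0.0
            for idx, val in gcell.items():
                g, rest = idx[0], idx[1:]
                key = rest[0] if len(rest) == 1 else rest
                total += (val - gmean.loc[g] - cell.loc[key] + grand) ** 2
            ss_int_b = _clip_ss(float((mult * n_units // n_groups) * total))
            df_int_b = df_eff * (n_groups - 1)

        # error: interaction of the effect with units (within groups)
        if len(factors) == len(within):
            # highest-order within term: error is the residual
            ss_err = _clip_ss(ss_total - accounted[0] - ss_eff - ss_int_b)
        else:
            ucell = mean_by(unit, *factors)
            total = 0.0
            for idx, val in ucell.items():
                u, rest = idx[0], idx[1:]
                key = rest[0] if len(rest) == 1 else rest
                if between:
                    g = unit_group.loc[u]
                    gkey = (g, *rest) if len(rest) > 1 else (g, rest[0])
                    cond = mean_by(between, *factors).loc[gkey]
                    total += (
                        val - unit_means.loc[u] - cond + mean_by(between).loc[g]
                    ) ** 2
                else:
                    total += (val - unit_means.loc[u] - cell.loc[key] + grand) ** 2
            ss_err = _clip_ss(float(mult * total))
            accounted[0] += ss_err
        df_err = df_eff * (n_units - n_groups)
        accounted[0] += ss_eff + ss_int_b

        rows.append(("*".join(factors), ss_eff, df_eff, ss_err, df_err))
        if between:
            rows.append(
                ("*".join(factors) + f"*{between}", ss_int_b, df_int_b, ss_err, df_err)
            )

    for f in within:
        within_effect([f])
    if len(within) == 2:
        within_effect(within)

    out = []
    for name, ss_eff, df_eff, ss_err, df_err in rows:
        ms_eff = ss_eff / df_eff if df_eff else float("nan")
        ms_err = ss_err / df_err if df_err else float("nan")
        if df_eff and df_err and ms_err > 0:
            F = ms_eff / ms_err
            p = float(sps.f.sf(F, df_eff, df_err))
        elif df_eff and df_err and ms_err == 0 and ss_eff > 0:
            F, p = float("inf"), 0.0
        else:
            F, p = float("nan"), float("nan")
        pes = (
            ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else float("nan")
        )
        out.append(
            {
                "effect": name,
                "ss": ss_eff,
                "df": df_eff,
                "ss_error": ss_err,
                "df_error": df_err,
                "F": F,
                "p": p,
                "partial_eta_sq": pes,
            }
        )
    design = (
        f"within={within}" + (f", between={between}" if between else "")
    )
    return EffectTable(pd.DataFrame(out), ss_total=ss_total, design=design)


@dataclass
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    n: int
    zero_variance: bool


def paired_ttest(values_a: np.ndarray, values_b: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test on the per-item differences.

    Zero-variance differences are flagged: identical inputs report
    (t=0, p=1); a constant nonzero difference has an undefined statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs equal-length vectors, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return PairedTResult(0.0, 1.0, 0.0, a.size, True)
        return PairedTResult(float("nan"), float("nan"), float(d.mean()), a.size, True)
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), float(d.mean()), a.size, False)
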