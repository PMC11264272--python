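"""Summary statistics for solvation free-energy benchmark tables.

A benchmark table is a pandas DataFrame with one row per molecule:
``molecule_id``, the experimental value ``dG_exp``, one or more
calculated columns (``dG_calc_<label>``), corrections
(``dG_corr_<label>``) with uncertainties, an ``elements`` column and an
optional rotatable-bond count ``n_rot``.  All energies are kcal/mol.

The deviation convention is δΔG = ΔG_exp − ΔG_calc, so a calculated
value that is too positive (too hydrophobic) gives a negative δΔG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .worksets import ValidationError

__all__ = [
    "SummaryStats",
    "ImprovementResult",
    "deviation",
    "summary_stats",
    "kde_curve",
    "improvement_table",
    "select_worst_performers",
    "flexibility_boxes",
    "count_small_corrections",
]


def deviation(dG_exp, dG_calc):
    """δΔG = ΔG_exp − ΔG_calc (kcal/mol); negative when calc is too positive."""
    return np.asarray(dG_exp, dtype=float) - np.asarray(dG_calc, dtype=float)


@dataclass
class SummaryStats:
    """RMSE/MAE and rank statistics with percentile-bootstrap 95% CIs."""

    rmse: float
    rmse_ci: tuple[float, float]
    mae: float
    mae_ci: tuple[float, float]
    pearson: float | None
    pearson_ci: tuple[float, float] | None
    spearman: float | None
    spearman_ci: tuple[float, float] | None
    n: int
    diagnostic: str | None = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "rmse": self.rmse, "rmse_ci_low": self.rmse_ci[0],
            "rmse_ci_high": self.rmse_ci[1],
            "mae": self.mae, "mae_ci_low": self.mae_ci[0],
            "mae_ci_high": self.mae_ci[1],
        }
        for name, val, ci in (("pearson", self.pearson, self.pearson_ci),
                              ("spearman", self.spearman, self.spearman_ci)):
            d[name] = val
            d[f"{name}_ci_low"] = None if ci is None else ci[0]
            d[f"{name}_ci_high"] = None if ci is None else ci[1]
        if self.diagnostic:
            d["diagnostic"] = self.diagnostic
        return d


def _point_stats(exp: np.ndarray, calc: np.ndarray,
                 with_corr: bool) -> tuple[float, float, float | None, float | None]:
    d = exp - calc
    rmse = float(np.sqrt(np.mean(d ** 2)))
    mae = float(np.mean(np.abs(d)))
    if not with_corr:
        return rmse, mae, None, None
    pear = float(stats.pearsonr(exp, calc).statistic)
    spear = float(stats.spearmanr(exp, calc).statistic)
    return rmse, mae, pear, spear


def summary_stats(table: pd.DataFrame, calc_column: str,
                  exp_column: str = "dG_exp",
                  n_boot: int = 1000, seed: int | None = 0) -> SummaryStats:
    """RMSE, MAE, Pearson and Spearman of a calculated column vs experiment.

    95% confidence intervals come from a joint percentile bootstrap over
    rows (the same resample feeds all four statistics).  Constant
    columns make the correlations undefined; they are reported as None
    with a diagnostic, never as 0.
    """
    if len(table) < 3:
        raise ValidationError("summary statistics need at least 3 rows")
    exp = table[exp_column].to_numpy(dtype=float)
    calc = table[calc_column].to_numpy(dtype=float)
    if not (np.all(np.isfinite(exp)) and np.all(np.isfinite(calc))):
        raise ValidationError("summary statistics require finite columns")
    diag = None
    with_corr = True
    if np.ptp(exp) == 0.0 or np.ptp(calc) == 0.0:
        with_corr = False
        diag = "correlation undefined: a column is constant"
    rmse, mae, pear, spear = _point_stats(exp, calc, with_corr)
    rng = np.random.default_rng(seed)
    n = exp.size
    boots = np.full((n_boot, 4), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        e, c = exp[idx], calc[idx]
        resample_corr = with_corr and np.ptp(e) > 0 and np.ptp(c) > 0
        boots[b] = _point_stats_array(e, c, resample_corr)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return SummaryStats(
        rmse=rmse, rmse_ci=(float(lo[0]), float(hi[0])),
        mae=mae, mae_ci=(float(lo[1]), float(hi[1])),
        pearson=pear,
        pearson_ci=None if pear is None else (float(lo[2]), float(hi[2])),
        spearman=spear,
        spearman_ci=None if spear is None else (float(lo[3]), float(hi[3])),
        n=n, diagnostic=diag)


def _point_stats_array(e: np.ndarray, c: np.ndarray, with_corr: bool) -> list[float]:
    d = e - c
    rmse = float(np.sqrt(np.mean(d ** 2)))
    mae = float(np.mean(np.abs(d)))
    if not with_corr:
        return [rmse, mae, np.nan, np.nan]
    # fast in-loop versions: Pearson via corrcoef, Spearman via average ranks
    pear = float(np.corrcoef(e, c)[0, 1])
    re = stats.rankdata(e)
    rc = stats.rankdata(c)
    spear = float(np.corrcoef(re, rc)[0, 1])
    return [rmse, mae, pear, spear]


def kde_curve(deviations, bandwidth_rule: str | float = "scott",
              n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate of a deviation sample.

    The grid spans the data ± 3 bandwidths; the returned density
    integrates to 1 within 1e-3 (trapezoid rule).
    """
    d = np.asarray(deviations, dtype=float).ravel()
    if d.size < 2:
        raise ValidationError("KDE needs at least 2 points")
    if np.ptp(d) == 0.0:
        raise ValidationError("KDE undefined for a zero-variance sample")
    kde = stats.gaussian_kde(d, bw_method=bandwidth_rule)
    h = float(kde.factor * d.std(ddof=1))
    grid = np.linspace(d.min() - 3 * h, d.max() + 3 * h, n_grid)
    return grid, kde(grid)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ImprovementResult:
    """How often the high-level correction helps, overall and for large corrections."""

    n: int
    n_improving: int
    n_large_corr: int
    n_large_corr_improving: int
    pct_improving: float
    pct_large_corr: float
    pct_large_corr_improving: float | None

    @property
    def display(self) -> tuple[int, int, int | None]:
        """Integer percentages (half away from zero) for report tables."""
        c = self.pct_large_corr_improving
        return (_round_half_away(self.pct_improving),
                _round_half_away(self.pct_large_corr),
                None if c is None else _round_half_away(c))


def improvement_table(table: pd.DataFrame, mm_column: str, corr_column: str,
                      exp_column: str = "dG_exp",
                      threshold: float = 0.5) -> ImprovementResult:
    """Fractions of molecules whose corrected value agrees better with experiment.

    A correction "improves" when |δΔG| strictly decreases after adding
    it (ties count as non-improvement).  Also reported: the fraction of
    corrections larger in magnitude than ``threshold`` and, among those,
    the fraction improving.
    """
    if len(table) == 0:
        raise ValidationError("improvement statistics need a non-empty table")
    exp = table[exp_column].to_numpy(dtype=float)
    mm = table[mm_column].to_numpy(dtype=float)
    corr = table[corr_column].to_numpy(dtype=float)
    dev_mm = np.abs(exp - mm)
    dev_corrected = np.abs(exp - (mm + corr))
    improving = dev_corrected < dev_mm
    large = np.abs(corr) > threshold
    n = exp.size
    n_imp = int(improving.sum())
    n_large = int(large.sum())
    n_large_imp = int((improving & large).sum())
    return ImprovementResult(
        n=n, n_improving=n_imp, n_large_corr=n_large,
        n_large_corr_improving=n_large_imp,
        pct_improving=100.0 * n_imp / n,
        pct_large_corr=100.0 * n_large / n,
        pct_large_corr_improving=None if n_large == 0 else 100.0 * n_large_imp / n_large)


ANI2X_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "S", "Cl"})


def _element_set(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    return {tok for tok in str(value).replace(",", " ").split() if tok}


def select_worst_performers(tables: dict[str, pd.DataFrame], k: int = 100,
                            allowed_elements: frozenset[str] = ANI2X_ELEMENTS,
                            exp_column: str = "dG_exp",
                            calc_columns: dict[str, str] | None = None
                            ) -> pd.DataFrame:
    """Union of the k worst-agreeing molecules per force field.

    Each table is restricted to molecules whose element set is covered
    by ``allowed_elements``, ranked by |δΔG| descending (ties broken by
    molecule_id), and its top k taken.  The returned table is the union,
    labelled ``both`` or ``<label>_only`` in a ``selected_by`` column.
    """
    if len(tables) < 1:
        raise ValidationError("at least one table required")
    calc_columns = calc_columns or {lbl: f"dG_calc_{lbl}" for lbl in tables}
    top: dict[str, pd.DataFrame] = {}
    for label, df in tables.items():
        eligible = df[df["elements"].map(
            lambda v: _element_set(v) <= set(allowed_elements))].copy()
        if len(eligible) < k:
            raise ValidationError(
                f"table {label!r} has only {len(eligible)} eligible rows for k={k}")
        eligible["abs_dev"] = np.abs(
            deviation(eligible[exp_column], eligible[calc_columns[label]]))
        eligible = eligible.sort_values(
            ["abs_dev", "molecule_id"], ascending=[False, True], kind="mergesort")
        top[label] = eligible.head(k)
    labels = list(tables)
    ids = {label: set(t["molecule_id"]) for label, t in top.items()}
    union = pd.concat(top.values()).drop_duplicates("molecule_id") \
        .sort_values("molecule_id").reset_index(drop=True)

    def tag(mol: str) -> str:
        member = [lbl for lbl in labels if mol in ids[lbl]]
        return "both" if len(member) == len(labels) and len(labels) > 1 \
            else f"{member[0]}_only" if len(member) == 1 else "both"

    union["selected_by"] = union["molecule_id"].map(tag)
    return union.drop(columns=["abs_dev"])


def flexibility_boxes(table: pd.DataFrame, corr_column: str,
                      nrot_column: str = "n_rot") -> pd.DataFrame:
    """Tukey box statistics of corrections grouped by rotatable-bond count.

    Per n_rot group: quartiles, whiskers at the most extreme data point
    within 1.5×IQR of the box, and the outliers beyond the whiskers
    ranked by |correction| descending and numbered from 1.
    """
    if nrot_column not in table or table[nrot_column].isna().mean() > 0.5:
        raise ValidationError("rotatable-bond counts missing for most rows")
    rows = []
    valid = table.dropna(subset=[nrot_column])
    for n_rot, grp in valid.groupby(nrot_column):
        vals = grp[corr_column].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out_mask = (vals < lo_fence) | (vals > hi_fence)
        outliers = grp.loc[out_mask, ["molecule_id", corr_column]].copy()
        outliers = outliers.reindex(
            outliers[corr_column].abs().sort_values(ascending=False).index)
        rows.append({
            "n_rot": n_rot, "n": len(vals), "q1": q1, "median": med, "q3": q3,
            "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
            "outlier_ids": list(outliers["molecule_id"]),
            "outlier_values": [float(v) for v in outliers[corr_column]],
            "outlier_ranks": list(range(1, len(outliers) + 1)),
        })
    return pd.DataFrame(rows).sort_values("n_rot").reset_index(drop=True)


def count_small_corrections(table: pd.DataFrame, corr_column: str,
                            threshold: float = 0.5) -> int:
    """Number of molecules with |correction| strictly below the threshold."""
    corr = table[corr_column].to_numpy(dtype=float)
    return int(np.sum(np.abs(corr) < threshold))
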