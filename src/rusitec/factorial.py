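"""Treatment-level statistics for the 2 x 2 x 3 factorial Rusitec design.

The experiment crosses two osmolality conditions, two incubation
temperatures and three betaine doses, replicated over 6 runs (n = 6 per
cell, 72 fermenter units).  Responses are analysed with an ordinary
least-squares linear model containing the experimental run as an additive
block term plus the full factorial of fixed effects:

    y ~ run + osmolality * temperature * betaine

Run is treated as a fixed block rather than a REML random effect; for a
balanced design the two give identical point estimates of treatment means
and contrasts (they differ only in how variance components are partitioned).
Least-squares means per factor level are model predictions averaged with
equal weight over the levels of every other factor and over runs; for a
balanced design they coincide with arithmetic marginal means.  F tests use
type-III (marginal) sums of squares with sum-to-zero contrasts.

Daily repeated measures of a fermenter are averaged into a single value per
fermenter before fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

__all__ = [
    "FACTORS",
    "DesignTable",
    "EffectsResult",
    "make_design",
    "validate_design",
    "fit_factorial",
    "pearson_matrix",
]

FACTORS = ("osmolality", "temperature", "betaine")
_LEVELS = {
    "osmolality": ("normal", "hyper"),
    "temperature": ("39.5", "42"),
    "betaine": ("control", "low", "high"),
}
_FORMULA = (
    "value ~ C(run) + C(osmolality, Sum) * C(temperature, Sum) * C(betaine, Sum)"
)
_EFFECT_TERMS = {
    "osmolality": "C(osmolality, Sum)",
    "temperature": "C(temperature, Sum)",
    "betaine": "C(betaine, Sum)",
    "osmolality:temperature": "C(osmolality, Sum):C(temperature, Sum)",
    "osmolality:betaine": "C(osmolality, Sum):C(betaine, Sum)",
    "temperature:betaine": "C(temperature, Sum):C(betaine, Sum)",
    "osmolality:temperature:betaine":
        "C(osmolality, Sum):C(temperature, Sum):C(betaine, Sum)",
}


def _normalize_levels(series: pd.Series, factor: str) -> pd.Series:
    """Map values to canonical level strings (so 42.0 -> "42")."""
    by_float = {}
    for level in _LEVELS[factor]:
        try:
            by_float[float(level)] = level
        except ValueError:
            pass

    def norm(v) -> str:
        try:
            return by_float.get(float(v), str(v))
        except (TypeError, ValueError):
            return str(v)

    return series.map(norm)


class DesignTable:
    """Assignment of fermenter-runs to the 12 factorial treatment cells.

    Wraps a DataFrame with columns run, fermenter, osmolality, temperature,
    betaine.  Factor levels are normalised to strings ("normal"/"hyper",
    "39.5"/"42", "control"/"low"/"high").
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["run", "fermenter", *FACTORS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"design table is missing columns: {missing}")
        frame = frame.copy()
        for factor in FACTORS:
            frame[factor] = _normalize_levels(frame[factor], factor)
            bad = set(frame[factor]) - set(_LEVELS[factor])
            if bad:
                raise ValueError(f"unknown {factor} level(s): {sorted(bad)}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)


def make_design(n_runs: int = 6) -> DesignTable:
    """Balanced design: every treatment cell once per run."""
    rows = []
    for run in range(1, n_runs + 1):
        for i, (osmo, temp, bet) in enumerate(
            itertools.product(*(_LEVELS[f] for f in FACTORS))
        ):
            rows.append({
                "run": run,
                "fermenter": f"R{run}F{i + 1:02d}",
                "osmolality": osmo,
                "temperature": temp,
                "betaine": bet,
            })
    return DesignTable(pd.DataFrame(rows))


def validate_design(design: DesignTable) -> bool:
    """True if every cell appears equally often in every run; raises on
    missing cells."""
    counts = design.frame.groupby(["run", *FACTORS], observed=True).size()
    cells = design.frame.groupby(list(FACTORS), observed=True).size()
    if len(cells) < 12:
        present = set(cells.index)
        all_cells = set(itertools.product(*(_LEVELS[f] for f in FACTORS)))
        raise ValueError(
            f"missing treatment cell(s): {sorted(all_cells - present)}"
        )
    return counts.nunique() == 1 and len(counts) == design.frame["run"].nunique() * 12


@dataclass
class EffectsResult:
    """Fitted factorial model: LS means, SEs and effect P-values.

    ``ls_means`` is tidy: one row per (factor, level) with lsmean, se.
    ``effects`` is one row per model term with F, P and a label
    ("significant" at P <= 0.05, "tendency" at 0.05 < P <= 0.10).
    """

    ls_means: pd.DataFrame
    effects: pd.DataFrame
    n_units: int
    _fit: object | None = None
    _design_info: object | None = None
    _grid: pd.DataFrame | None = None

    def pvalue(self, term: str) -> float:
        return float(self.effects.loc[term, "pvalue"])

    def ls_mean(self, factor: str, level: str) -> float:
        sel = self.ls_means[(self.ls_means["factor"] == factor)
                            & (self.ls_means["level"] == str(level))]
        return float(sel["lsmean"].iloc[0])

    def _level_weights(self, factor: str, level: str) -> np.ndarray:
        """Design-matrix averaging vector for one factor level's LS mean."""
        grid = self._grid[self._grid[factor] == str(level)]
        (exog,) = build_design_matrices([self._design_info], grid)
        return np.asarray(exog).mean(axis=0)

    def contrast(self, factor: str, level_a: str, level_b: str,
                 alpha: float = 0.05) -> dict[str, float]:
        """LS-mean difference level_a − level_b with SE and CI.

        The t distribution uses the model's residual degrees of freedom.
        """
        a = self._level_weights(factor, level_a) - self._level_weights(factor, level_b)
        beta = np.asarray(self._fit.params)
        cov = np.asarray(self._fit.cov_params())
        est = float(a @ beta)
        se = float(np.sqrt(a @ cov @ a))
        df = float(self._fit.df_resid)
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, df)
        if se > 0:
            p = 2 * scipy.stats.t.sf(abs(est) / se, df)
        else:
            p = float("nan")
        return {
            "estimate": est, "se": se, "df": df, "pvalue": p,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
        }


def _label(p: float) -> str:
    if np.isnan(p):
        return "none"
    if p <= 0.05:
        return "significant"
    if p <= 0.10:
        return "tendency"
    return "none"


def fit_factorial(data: pd.DataFrame, design: DesignTable | None = None,
                  response: str = "value") -> EffectsResult:
    """Fit the block + full-factorial model to one response.

    ``data`` needs columns run, fermenter, osmolality, temperature, betaine
    and the response (or just run/fermenter plus the response if ``design``
    is given, in which case factors are joined on (run, fermenter)).
    Multiple rows per fermenter (daily records) are averaged before fitting.
    """
    df = data.copy()
    if design is not None:
        df = df.merge(design.frame, on=["run", "fermenter"], how="left",
                      suffixes=("", "_design"))
        for factor in FACTORS:
            if f"{factor}_design" in df.columns:
                df[factor] = df[f"{factor}_design"]
        if df[list(FACTORS)].isna().any().any():
            raise ValueError("some (run, fermenter) rows are absent from the design")
    for factor in FACTORS:
        df[factor] = _normalize_levels(df[factor], factor)
    df = (df.groupby(["run", "fermenter", *FACTORS], observed=True, as_index=False)
            [response].mean())
    df = df.rename(columns={response: "value"}).dropna(subset=["value"])

    dt = DesignTable(df)
    if not validate_design(dt):
        warnings.warn("design is unbalanced; LS means are model-based, "
                      "not arithmetic marginal means", stacklevel=2)

    fit = smf.ols(_FORMULA, data=df).fit()
    ssr = float(fit.ssr)
    centered_tss = float(fit.centered_tss)
    degenerate = ssr <= max(centered_tss, 1.0) * 1e-12

    if degenerate and centered_tss <= abs(float(df["value"].mean())) * 1e-12 + 1e-300:
        # constant response: every effect is exactly null
        effects = pd.DataFrame(
            {"F": 0.0, "pvalue": 1.0}, index=list(_EFFECT_TERMS)
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = sm.stats.anova_lm(fit, typ=3)
        rows = {}
        for name, term in _EFFECT_TERMS.items():
            f = float(anova.loc[term, "F"])
            p = float(anova.loc[term, "PR(>F)"])
            if degenerate and not np.isfinite(f):
                f, p = 0.0, 1.0
            rows[name] = {"F": f, "pvalue": p}
        effects = pd.DataFrame(rows).T
    effects["label"] = [_label(p) for p in effects["pvalue"]]
    effects.index.name = "term"

    design_info = fit.model.data.design_info
    runs = sorted(df["run"].unique())
    grid = pd.DataFrame(
        itertools.product(runs, *(map(list, (_LEVELS[f] for f in FACTORS)))),
        columns=["run", *FACTORS],
    )
    beta = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    ls_rows = []
    for factor in FACTORS:
        for level in _LEVELS[factor]:
            sub = grid[grid[factor] == level]
            (exog,) = build_design_matrices([design_info], sub)
            a = np.asarray(exog).mean(axis=0)
            ls_rows.append({
                "factor": factor, "level": level,
                "lsmean": float(a @ beta),
                "se": float(np.sqrt(max(a @ cov @ a, 0.0))),
            })
    ls_means = pd.DataFrame(ls_rows)

    return EffectsResult(
        ls_means=ls_means, effects=effects, n_units=len(df),
        _fit=fit, _design_info=design_info, _grid=grid,
    )


def pearson_matrix(x: pd.DataFrame, y: pd.DataFrame,
                   alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations between columns of x and of y.

    Rows of x and y are matched on index.  Returns {"r", "pvalue",
    "significant"}; entries with fewer than 3 complete pairs or with zero
    variance are NaN.  Significance follows the two-sided t test at
    ``alpha``.
    """
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("pearson_matrix needs at least 3 paired samples")
    x = x.loc[common]
    y = y.loc[common]
    r = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    p = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    for xc in x.columns:
        for yc in y.columns:
            pair = pd.concat([x[xc], y[yc]], axis=1).dropna()
            if len(pair) < 3:
                continue
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            res = scipy.stats.pearsonr(a, b)
            r.loc[xc, yc] = res.statistic
            p.loc[xc, yc] = res.pvalue
    return {"r": r, "pvalue": p, "significant": p < alpha}
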