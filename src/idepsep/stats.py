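"""Two-condition comparison of EKMr spectra.

The experiment asks whether the intensity pattern across EKMr levels differs
between two treatment conditions.  That is a two-way fixed-effects ANOVA —
factors *condition* (2 levels) and *EKMr level* (9 in the reference design,
one per gate triplet) with interaction — on per-replicate normalized
intensities.  Replicate counts may be unbalanced (3 untreated vs 4 treated
in the reference design, giving interaction df 8 and error df 45).

The interaction term is the scientifically interesting one (a condition ×
level interaction means the *shape* of the spectrum shifted); its F test is
invariant to the sum-of-squares type, which matters only for the main
effects under imbalance (reported from a Type III decomposition with
sum-to-zero contrasts).

Per-level follow-up uses two-sample comparisons of condition means with the
pooled ANOVA error variance, Bonferroni-corrected over the number of levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AnovaResult", "two_way_anova", "bonferroni_posthoc"]


@dataclass(frozen=True)
class AnovaResult:
    """Effect table plus the fitted data needed for post hoc comparisons.

    ``effects`` has one row per term (condition, ekmr_level,
    condition:ekmr_level, Residual) with sum_of_squares, df, F, p.
    """

    effects: pd.DataFrame
    observations: pd.DataFrame
    alpha: float = 0.05

    def _row(self, term: str) -> pd.Series:
        return self.effects.loc[self.effects["term"] == term].iloc[0]

    @property
    def interaction_F(self) -> float:
        return float(self._row("condition:ekmr_level")["F"])

    @property
    def interaction_p(self) -> float:
        return float(self._row("condition:ekmr_level")["p"])

    @property
    def interaction_df(self) -> int:
        return int(self._row("condition:ekmr_level")["df"])

    @property
    def error_df(self) -> int:
        return int(self._row("Residual")["df"])

    @property
    def ms_error(self) -> float:
        r = self._row("Residual")
        return float(r["sum_of_squares"] / r["df"])


def _validate(obs: pd.DataFrame) -> pd.DataFrame:
    required = {"condition", "ekmr_level", "replicate", "intensity"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = obs.copy()
    if obs["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    if obs["ekmr_level"].nunique() < 2:
        raise ValueError("need at least 2 EKMr levels")
    cells = obs.groupby(["condition", "ekmr_level"], observed=True).size()
    full = obs["condition"].nunique() * obs["ekmr_level"].nunique()
    if len(cells) < full:
        raise ValueError(
            "empty condition × level cells make the interaction inestimable"
        )
    if (cells < 2).all():
        raise ValueError("need at least 2 replicates in at least one cell")
    return obs


def two_way_anova(observations: pd.DataFrame, *, alpha: float = 0.05) -> AnovaResult:
    """Fit ``intensity ~ condition * ekmr_level`` and tabulate the ANOVA.

    ``observations`` needs columns ``condition, ekmr_level, replicate,
    intensity``; ``ekmr_level`` may be numeric (EKMr values) or labels —
    it is treated categorically either way.  Handles unbalanced replicate
    counts; empty cells raise.
    """
    obs = _validate(observations)
    data = obs.assign(
        condition=obs["condition"].astype(str),
        ekmr_level=obs["ekmr_level"].astype(str),
    )
    model = smf.ols(
        "intensity ~ C(condition, Sum) * C(ekmr_level, Sum)", data=data
    ).fit()
    if model.df_resid > 0 and np.allclose(model.resid, 0.0):
        # zero within-cell variance: F undefined; report SS with NaN F/p
        table = sm.stats.anova_lm(model, typ=2)
        table["F"] = np.nan
        table["PR(>F)"] = np.nan
    else:
        table = sm.stats.anova_lm(model, typ=3)
        table = table.drop(index="Intercept", errors="ignore")
    rename = {
        "C(condition, Sum)": "condition",
        "C(ekmr_level, Sum)": "ekmr_level",
        "C(condition, Sum):C(ekmr_level, Sum)": "condition:ekmr_level",
    }
    effects = (
        table.rename(index=rename)
        .rename(columns={"sum_sq": "sum_of_squares", "PR(>F)": "p"})
        .reset_index(names="term")
    )
    effects["df"] = effects["df"].astype(int)
    effects = effects[["term", "sum_of_squares", "df", "F", "p"]]
    return AnovaResult(effects=effects, observations=obs, alpha=alpha)


def bonferroni_posthoc(
    observations: pd.DataFrame | None = None,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """Per-EKMr-level condition comparison with Bonferroni correction.

    Each level gets a two-sample t statistic on the condition means using
    the pooled ANOVA mean-square error (error df from the full model); raw
    p values are multiplied by the number of levels and capped at 1.

    Returns columns ``ekmr_level, mean_diff, raw_p, bonferroni_p,
    significant`` (flag at the ANOVA's alpha).
    """
    if anova is None:
        if observations is None:
            raise ValueError("need observations or a fitted AnovaResult")
        anova = two_way_anova(observations)
    obs = anova.observations
    conditions = sorted(obs["condition"].astype(str).unique())
    if len(conditions) != 2:
        raise ValueError("post hoc comparison is defined for exactly 2 conditions")
    a, b = conditions
    mse, dfe = anova.ms_error, anova.error_df
    levels = sorted(obs["ekmr_level"].unique())
    n_comp = len(levels)
    rows = []
    for lev in levels:
        sub = obs[obs["ekmr_level"] == lev]
        xa = sub.loc[sub["condition"].astype(str) == a, "intensity"].to_numpy()
        xb = sub.loc[sub["condition"].astype(str) == b, "intensity"].to_numpy()
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"level {lev!r} lacks one of the conditions")
        diff = xa.mean() - xb.mean()
        se = np.sqrt(mse * (1.0 / xa.size + 1.0 / xb.size))
        if se == 0:
            raw = 1.0
        else:
            t = diff / se
            raw = float(2.0 * sps.t.sf(abs(t), dfe))
        rows.append(
            {
                "ekmr_level": lev,
                "mean_diff": float(diff),
                "raw_p": raw,
                "bonferroni_p": min(raw * n_comp, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["bonferroni_p"] < anova.alpha
    return out
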