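"""Survival machinery: Kaplan-Meier, log-rank, and Cox proportional hazards.

Thin, validated wrappers around lifelines that expose the quantities the
scoring pipeline needs: per-stratum product-limit survival curves with
Greenwood standard errors, the k-group log-rank chi-square test, and Cox
partial-likelihood fits with Wald confidence intervals (lifelines handles
ties by the Breslow approximation). Also provides the deterministic
score-stratification rules (median / tertile / custom quantile) used to turn
continuous sample scores into survival strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMStratum",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "stratify_scores",
]


def _validate(table: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValueError(f"survival table needs a {col!r} column")
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")


@dataclass
class KMStratum:
    """Product-limit estimate for one stratum.

    ``curve`` is indexed by event time with columns ``survival`` (the KM
    step function, starting at 1 and non-increasing) and ``greenwood_se``.
    """

    curve: pd.DataFrame
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        past = self.curve.index[self.curve.index <= t]
        if len(past) == 0:
            return 1.0
        return float(self.curve.loc[past[-1], "survival"])


def km_estimate(
    table: pd.DataFrame, group: str | None = None
) -> dict[str, KMStratum]:
    """Kaplan-Meier curves per stratum with Greenwood standard errors.

    ``table`` has columns ``time`` and ``event`` (1 = death, 0 = censored)
    and optionally a ``group`` column naming strata.
    """
    _validate(table)
    if table["event"].sum() == 0:
        # all censored: S == 1 everywhere, still a valid (degenerate) estimate
        pass
    strata = {"all": table} if group is None else {
        str(g): sub for g, sub in table.groupby(group)
    }
    out: dict[str, KMStratum] = {}
    for name, sub in strata.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        d, r = tab["observed"].to_numpy(float), tab["at_risk"].to_numpy(float)
        surv = np.cumprod(1.0 - np.divide(d, r, out=np.zeros_like(d), where=r > 0))
        # Greenwood: var(S) = S^2 * cumsum(d / (r (r - d)))
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where((r - d) > 0, d / (r * (r - d)), 0.0)
        se = surv * np.sqrt(np.cumsum(inc))
        curve = pd.DataFrame(
            {"survival": surv, "greenwood_se": se}, index=tab.index
        )
        curve = curve[tab["observed"] > 0]  # steps only at event times
        out[name] = KMStratum(
            curve=curve, n=len(sub), n_events=int(sub["event"].sum())
        )
    return out


def logrank_test(table: pd.DataFrame, group: str = "group") -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square, two-sided p)."""
    _validate(table)
    groups = table[group].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if table["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(table["time"], table[group], table["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    table: pd.DataFrame, covariates: list[str], max_iter: int = 100
) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit.

    Returns a per-covariate frame with the coefficient, hazard ratio,
    Wald 95% CI bounds, and two-sided Wald p-value. Categorical covariates
    are dummy-encoded against their first level.
    """
    _validate(table)
    if table["event"].sum() == 0:
        raise ValueError("Cox model needs at least one event")
    df = table[["time", "event"] + covariates].copy()
    cat = [c for c in covariates if not pd.api.types.is_numeric_dtype(df[c])]
    if cat:
        df = pd.get_dummies(df, columns=cat, drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            fit_options={"max_steps": max_iter},
        )
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "hr_ci_low": s["exp(coef) lower 95%"],
            "hr_ci_high": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
        }
    )


def stratify_scores(scores: pd.Series, rule: str = "median") -> pd.Series:
    """Deterministic grouping of sample scores.

    ``rule`` is ``"median"`` (labels ``low``/``high``), ``"tertile"``
    (``low``/``mid``/``high``) or ``"quantile:<q>"`` (``low``/``high`` at the
    q-th quantile). Ties at a cutoff go to the lower group.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    v = scores.to_numpy(dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("all scores equal: stratification undefined")
    if rule == "median":
        cuts, labels = [np.quantile(v, 0.5)], ["low", "high"]
    elif rule == "tertile":
        cuts, labels = list(np.quantile(v, [1 / 3, 2 / 3])), ["low", "mid", "high"]
    elif rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1])
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")
        cuts, labels = [np.quantile(v, q)], ["low", "high"]
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    idx = np.searchsorted(np.asarray(cuts), v, side="left")
    idx = np.minimum(idx, len(labels) - 1)
    # ties at a cutoff belong to the lower group
    for i, c in enumerate(cuts):
        idx[v == c] = i
    return pd.Series([labels[i] for i in idx], index=scores.index, name="stratum")
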