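"""Group statistics: mixed 2x2 ANOVA, post hocs, regressions, BIC Bayes.

The battery mirrors a standard within-between design: a mixed ANOVA with the
within-subject factor task (easy/hard) and the between-subjects factor group
(low/high adaptability), Bonferroni-corrected post hoc t-tests plus
Mann-Whitney U tests for the between-group contrasts, per-component ordinary
least-squares regressions of the adaptability score on amplitude, and a
BIC-based posterior probability of the alternative hypothesis,

    p_BIC(H1|D) = 1 / (1 + exp(dBIC / 2)),
    dBIC = BIC(H1) - BIC(H0) = n ln(SSE_1 / SSE_0) + k ln(n),

the unit-information-prior approximation for nested model comparison.
Greenhouse-Geisser correction is moot for two-level factors (epsilon = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaEffect", "AnovaResult", "RegressionResult", "BayesResult",
    "mixed_anova_2x2", "posthoc_tests", "regress_score",
    "p_bic", "p_bic_from_delta", "p_bic_from_anova", "bonferroni",
    "interpret_p_bic",
]


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F tests for the 2x2 mixed design."""
    task: AnovaEffect
    group: AnovaEffect
    interaction: AnovaEffect
    n_subjects: int

    def effects(self) -> dict[str, AnovaEffect]:
        return {"task": self.task, "group": self.group,
                "interaction": self.interaction}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    F: float
    df1: int
    df2: int
    p: float
    r_squared: float


@dataclass(frozen=True)
class BayesResult:
    delta_bic: float
    p_bic_h1: float
    label: str


def _long_table(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    req = {"subject", "task", "amplitude"}
    if not req <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(req)}")
    df = values.copy()
    df["group"] = df["subject"].map(groups)
    if df["group"].isna().any():
        raise ValueError("some subjects lack a group label")
    return df


def mixed_anova_2x2(values: pd.DataFrame, groups: pd.Series) -> AnovaResult:
    """Mixed ANOVA: within factor task, between factor group.

    ``values``: long table with columns subject, task, amplitude (one row per
    subject x task).  ``groups``: subject -> {"low", "high"}.
    """
    df = _long_table(values, groups)
    if df["task"].nunique() != 2:
        raise ValueError("expected exactly two tasks")
    if df["group"].nunique() != 2:
        raise ValueError("expected exactly two groups")
    counts = df.groupby(["subject"]).size()
    if (counts != 2).any():
        raise ValueError("every subject needs exactly one value per task")
    if df.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("each group needs at least 2 subjects")

    aov = pg.mixed_anova(data=df, dv="amplitude", within="task",
                         subject="subject", between="group", effsize="np2")
    aov = aov.set_index("Source")

    def eff(src: str) -> AnovaEffect:
        r = aov.loc[src]
        # pingouin reports the effect SS/MS; recover the error SS from F
        ss_eff = float(r["SS"])
        ms_err = float(r["MS"]) / float(r["F"]) if r["F"] > 0 else np.nan
        ss_err = ms_err * int(r["DF2"])
        return AnovaEffect(F=float(r["F"]), df1=int(r["DF1"]),
                           df2=int(r["DF2"]), p=float(r["p_unc"]),
                           partial_eta_sq=float(r["np2"]),
                           ss_effect=ss_eff, ss_error=ss_err)

    return AnovaResult(task=eff("task"), group=eff("group"),
                       interaction=eff("Interaction"),
                       n_subjects=int(df["subject"].nunique()))


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, float(p) * family_size)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples, otherwise
    the tie-corrected normal approximation."""
    exact = (min(len(x), len(y)) <= 10
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def posthoc_tests(values: pd.DataFrame, groups: pd.Series,
                  family_size: int | None = None) -> pd.DataFrame:
    """Post hoc contrasts for the 2x2 design.

    Five t contrasts: easy vs hard within each group (paired), low vs high
    per task (independent), and low vs high on the easy-hard differences
    (independent); the three between-group contrasts are repeated as
    Mann-Whitney U tests.  Bonferroni correction multiplies each raw p by the
    family size (default: the five t contrasts form one family, the three U
    tests another).
    """
    df = _long_table(values, groups)
    tasks = sorted(df["task"].unique())
    if len(tasks) != 2:
        raise ValueError("expected exactly two tasks")
    easy, hard = tasks if tasks[0] == "easy" else (tasks[1], tasks[0])
    wide = df.pivot_table(index="subject", columns="task",
                          values="amplitude", aggfunc="first")
    wide["group"] = df.groupby("subject")["group"].first()
    wide["diff"] = wide[easy] - wide[hard]

    rows = []

    def add(name, kind, stat, p, df_t=None):
        rows.append({"contrast": name, "test": kind, "statistic": float(stat),
                     "df": df_t, "p_raw": float(p)})

    for grp, d in wide.groupby("group"):
        diff = (d[easy] - d[hard]).to_numpy()
        if diff.std(ddof=1) == 0:
            # degenerate variance: identical samples give t = 0, p = 1; a
            # constant nonzero shift is an exact difference (p = 0)
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(d[easy], d[hard])
        add(f"{easy} vs {hard} ({grp})", "paired t", t, p, len(d) - 1)

    lo = wide[wide["group"] == "low"]
    hi = wide[wide["group"] == "high"]
    for col, label in [(easy, f"low vs high ({easy})"),
                       (hard, f"low vs high ({hard})"),
                       ("diff", "low vs high (easy-hard diff)")]:
        t, p = sps.ttest_ind(lo[col], hi[col])
        add(label, "independent t", t, p, len(lo) + len(hi) - 2)
    n_t = len(rows)
    for col, label in [(easy, f"low vs high ({easy})"),
                       (hard, f"low vs high ({hard})"),
                       ("diff", "low vs high (easy-hard diff)")]:
        u, p = _mannwhitney(lo[col].to_numpy(), hi[col].to_numpy())
        add(label, "mann-whitney u", u, p, None)

    out = pd.DataFrame(rows)
    fam_t = family_size if family_size is not None else n_t
    fam_u = family_size if family_size is not None else len(out) - n_t
    fams = [fam_t] * n_t + [fam_u] * (len(out) - n_t)
    out["p_bonferroni"] = [bonferroni(p, f) for p, f in zip(out["p_raw"], fams)]
    return out


def regress_score(amplitudes: pd.Series, scores: pd.Series) -> RegressionResult:
    """OLS of the adaptability score on component amplitude, F test of slope."""
    x = np.asarray(amplitudes, float)
    y = np.asarray(scores, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("zero amplitude variance")
    res = sps.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    df2 = n - 2
    F = r2 * df2 / (1 - r2) if r2 < 1 else np.inf
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept), F=float(F),
                            df1=1, df2=df2, p=float(res.pvalue),
                            r_squared=float(r2))


_BANDS = [(0.5, "favors null"), (0.75, "weak"), (0.95, "positive"),
          (0.99, "strong"), (np.inf, "very strong")]


def interpret_p_bic(p_h1: float) -> str:
    """Conventional evidence bands for p_BIC(H1|D): below 0.5 favors the
    null; 0.5-0.75 weak, 0.75-0.95 positive, 0.95-0.99 strong, above 0.99
    very strong evidence for the alternative."""
    for edge, label in _BANDS:
        if p_h1 < edge or edge is np.inf:
            return label
    return "very strong"


def p_bic_from_delta(delta_bic: float) -> BayesResult:
    """Posterior probability of H1 from a BIC difference (logistic map)."""
    p_h1 = 1.0 / (1.0 + np.exp(delta_bic / 2.0))
    return BayesResult(delta_bic=float(delta_bic), p_bic_h1=float(p_h1),
                       label=interpret_p_bic(float(p_h1)))


def p_bic(sse_h0: float, sse_h1: float, n: int, k_diff: int = 1) -> BayesResult:
    """Posterior probability of H1 from the BIC approximation."""
    if sse_h0 <= 0 or sse_h1 <= 0:
        raise ValueError("sums of squared errors must be positive")
    if not n > k_diff >= 1:
        raise ValueError("need n > k_diff >= 1")
    delta = n * np.log(sse_h1 / sse_h0) + k_diff * np.log(n)
    return p_bic_from_delta(delta)


def p_bic_from_anova(effect: AnovaEffect, n: int) -> BayesResult:
    """Bayes factor approximation for one ANOVA effect.

    H1 is the model containing the effect (error SS), H0 the model without it
    (error SS + effect SS); k_diff = df1 of the effect.
    """
    return p_bic(sse_h0=effect.ss_error + effect.ss_effect,
                 sse_h1=effect.ss_error, n=n, k_diff=effect.df1)
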