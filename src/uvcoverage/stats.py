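"""Statistical comparison plan for paired coverage studies.

Implements the analysis battery of a two-visit crossover design in which
each participant applies both formulations (sunscreen, SPF moisturiser):

* normality gating by Lilliefors-corrected Kolmogorov-Smirnov, with log
  and square-root rescue transforms before falling back to nonparametric;
* paired t-test (or the nonparametric fallback) and one-within-factor
  repeated-measures ANOVA for the formulation effect;
* subgroup one-way ANOVA with Sidak-adjusted pairwise contrasts;
* two-factor ANCOVA (sex x skin group, age covariate);
* the order-effect check between sunscreen-first and moisturiser-first
  groups;
* half-face dose-response regression of mean intensity on applied mass;
* binary tabulation of medial-canthus outcomes.

All tests use a 0.05 significance level.  Every result records which
assumption path (parametric / transformed / nonparametric) was taken, so
an analysis run is auditable after the fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestResult",
    "GateResult",
    "normality_gate",
    "paired_compare",
    "rm_anova",
    "subgroup_compare",
    "ancova_two_factor",
    "order_effect_check",
    "dose_response_regression",
    "tabulate_binary",
    "sidak_adjust",
    "sidak_alpha",
    "collapse_skin_type",
    "validate_study_table",
]

ALPHA = 0.05


@dataclass
class TestResult:
    """One hypothesis-test outcome with its audit trail."""

    test_name: str
    statistic: float
    df: float | tuple | None
    p_value: float
    direction: str | None = None
    assumption_path: str = "parametric"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class GateResult:
    """Outcome of the normality gate for one sample."""

    path: str                      # parametric | transformed | nonparametric
    transform: str | None = None   # log | sqrt
    shift: float = 0.0             # added before transforming, if needed
    p_values: dict = field(default_factory=dict)
    degenerate: bool = False

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform == "log":
            return np.log(x + self.shift)
        if self.transform == "sqrt":
            return np.sqrt(x + self.shift)
        return x


def _shift_for(x: np.ndarray, transform: str) -> float:
    m = float(np.min(x))
    if transform == "log":
        return 0.0 if m > 0 else 1.0 - m
    return 0.0 if m >= 0 else -m


def normality_gate(sample, alpha: float = ALPHA) -> GateResult:
    """Route a sample to a parametric, transformed or nonparametric path.

    Normality is tested with the Kolmogorov-Smirnov statistic using the
    Lilliefors correction (parameters estimated from the sample — the
    naive KS test with estimated parameters is badly anti-conservative).
    If normality is rejected, log and then square-root transforms are
    tried (shifting the sample positive first when needed); if both fail
    the nonparametric path is returned.  Constant samples are degenerate
    and routed nonparametric with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality gate requires at least 3 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: normality undefined, "
                      "routing nonparametric", stacklevel=2)
        return GateResult(path="nonparametric", degenerate=True)
    if x.size < 4:
        # below the Lilliefors table: normality cannot be assessed
        warnings.warn("n < 4: normality untestable, assuming parametric",
                      stacklevel=2)
        return GateResult(path="parametric")
    pvals: dict[str, float] = {}
    _, p = lilliefors(x, dist="norm")
    pvals["raw"] = float(p)
    if p >= alpha:
        return GateResult(path="parametric", p_values=pvals)
    for transform in ("log", "sqrt"):
        shift = _shift_for(x, transform)
        xt = np.log(x + shift) if transform == "log" else np.sqrt(x + shift)
        if np.ptp(xt) == 0:
            continue
        _, p = lilliefors(xt, dist="norm")
        pvals[transform] = float(p)
        if p >= alpha:
            return GateResult(path="transformed", transform=transform,
                              shift=shift, p_values=pvals)
    return GateResult(path="nonparametric", p_values=pvals)


def paired_compare(a, b, gate: GateResult | None = None,
                   nonparametric: str = "mannwhitney") -> TestResult:
    """Compare two paired samples of percent missed.

    The parametric (and transformed) path is a two-sided paired t-test;
    the nonparametric fallback is the Mann-Whitney U test on the two
    samples, with ``nonparametric="wilcoxon"`` switching to the paired
    signed-rank alternative.  When no gate is supplied, the within-pair
    differences are gated.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison requires at least 2 pairs")
    if gate is None:
        diffs = a - b
        gate = (normality_gate(diffs) if n >= 3 and np.ptp(diffs) > 0
                else GateResult(path="parametric"))
    if gate.path in ("parametric", "transformed"):
        at, bt = gate.apply(a), gate.apply(b)
        d = at - bt
        if np.ptp(d) == 0 and d[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(at, bt)
        direction = "a>b" if float(np.mean(d)) > 0 else "a<b" if np.mean(d) < 0 else "none"
        return TestResult("paired t-test", float(t), float(n - 1), float(p),
                          direction=direction, assumption_path=gate.path,
                          extras={"mean_difference": float(np.mean(a - b)),
                                  "transform": gate.transform})
    if nonparametric == "wilcoxon":
        d = a - b
        if np.all(d == 0):
            return TestResult("wilcoxon signed-rank", 0.0, None, 1.0,
                              direction="none", assumption_path="nonparametric")
        stat, p = sps.wilcoxon(a, b)
        name = "wilcoxon signed-rank"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney U"
    direction = ("a>b" if np.median(a) > np.median(b)
                 else "a<b" if np.median(a) < np.median(b) else "none")
    return TestResult(name, float(stat), None, float(p), direction=direction,
                      assumption_path="nonparametric",
                      extras={"mean_difference": float(np.mean(a - b))})


def rm_anova(table: pd.DataFrame, dv: str = "percent_missed",
             within: str = "formulation", subject: str = "participant",
             region: str | None = None) -> TestResult:
    """One-within-factor repeated-measures ANOVA for the formulation effect.

    Requires complete paired data (every subject observed at every level
    of the within factor).  For a two-level factor the F statistic equals
    the squared paired-t statistic.
    """
    df = table if region is None else table[table["region"] == region]
    wide = df.pivot_table(index=subject, columns=within, values=dv,
                          aggfunc="mean")
    missing = wide[wide.isna().any(axis=1)].index.tolist()
    if missing:
        raise ValueError(
            f"incomplete within-subject data for participants: {missing}"
        )
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 within levels")
    gm = y.mean()
    ss_subj = k * float(((y.mean(axis=1) - gm) ** 2).sum())
    ss_treat = n * float(((y.mean(axis=0) - gm) ** 2).sum())
    ss_total = float(((y - gm) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_treat
    df_treat = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ss_treat <= 0 or ms_err <= 0:
        f = 0.0 if ss_treat <= 1e-12 else np.inf
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = (ss_treat / df_treat) / ms_err
        p = float(sps.f.sf(f, df_treat, df_err))
    means = wide.mean(axis=0)
    direction = f"max at {means.idxmax()}"
    return TestResult("repeated-measures ANOVA", float(f),
                      (df_treat, df_err), float(p), direction=direction,
                      assumption_path="parametric",
                      extras={"level_means": means.to_dict()})


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m``, capped at 1."""
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def sidak_alpha(alpha: float, m: int) -> float:
    """Per-test level achieving family level ``alpha`` over m comparisons."""
    return float(1.0 - (1.0 - alpha) ** (1.0 / m))


def subgroup_compare(table: pd.DataFrame, group: str,
                     dv: str = "percent_missed", region: str | None = None,
                     by: str = "formulation") -> dict:
    """Subgroup analysis: one-way ANOVA over group x formulation cells,
    then Sidak-adjusted between-group contrasts within each formulation.

    Returns ``{"anova": TestResult, "contrasts": [TestResult, ...]}``;
    each contrast records both the raw and the Sidak-adjusted p-value
    (m = number of contrasts in the family).
    """
    df = table if region is None else table[table["region"] == region]
    levels = sorted(df[group].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels of {group!r}, found {levels}")
    cells = [sub[dv].to_numpy(dtype=float)
             for _, sub in df.groupby([group, by], observed=True)]
    if any(len(c) < 2 for c in cells):
        raise ValueError("every group x formulation cell needs n >= 2")
    f, p = sps.f_oneway(*cells)
    anova = TestResult("one-way ANOVA (cells)", float(f),
                       (len(cells) - 1, sum(len(c) for c in cells) - len(cells)),
                       float(p))
    pairs = []
    for form, sub in df.groupby(by, observed=True):
        ga = sub[sub[group] == levels[0]][dv].to_numpy(dtype=float)
        gb = sub[sub[group] == levels[1]][dv].to_numpy(dtype=float)
        t, praw = sps.ttest_ind(ga, gb)
        pairs.append((form, levels[0], levels[1], float(t),
                      float(len(ga) + len(gb) - 2), float(praw),
                      float(np.mean(ga) - np.mean(gb))))
    m = len(pairs)
    contrasts = [
        TestResult(
            f"{group} contrast ({form}): {la} vs {lb}", t, dof, praw,
            direction=f"{la}>{lb}" if delta > 0 else f"{la}<{lb}",
            extras={"p_adjusted": sidak_adjust(praw, m), "m": m,
                    "mean_difference": delta,
                    "per_test_alpha": sidak_alpha(ALPHA, m)},
        )
        for form, la, lb, t, dof, praw, delta in pairs
    ]
    return {"anova": anova, "contrasts": contrasts}


def ancova_two_factor(table: pd.DataFrame, dv: str = "percent_missed",
                      factors: tuple[str, str] = ("sex", "skin_group"),
                      covariate: str = "age", region: str | None = None,
                      formulation: str | None = None,
                      ss_type: int = 2) -> dict:
    """Two-factor ANCOVA with interaction and a continuous covariate.

    Fits ``dv ~ C(f1) * C(f2) + covariate`` by OLS and reports the ANOVA
    table (Type II sums of squares by default; Type III available via
    ``ss_type=3``).  Returns a dict of term -> TestResult plus the fitted
    covariate slope under ``"slopes"``.
    """
    df = table
    if region is not None:
        df = df[df["region"] == region]
    if formulation is not None:
        df = df[df["formulation"] == formulation]
    f1, f2 = factors
    formula = f"{dv} ~ C({f1}) * C({f2}) + {covariate}"
    model = ols(formula, data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < \
            model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient ANCOVA design for terms {f1}, {f2}, {covariate}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=ss_type)
    results: dict[str, TestResult] = {}
    for term, row in tab.iterrows():
        if term == "Residual":
            continue
        results[term] = TestResult(
            f"ANCOVA {term}", float(row["F"]),
            (float(row["df"]), float(tab.loc["Residual", "df"])),
            float(row["PR(>F)"]), assumption_path="parametric",
        )
    results["slopes"] = {covariate: float(model.params[covariate])}
    results["model"] = model
    return results


def order_effect_check(table: pd.DataFrame, dv: str = "percent_missed",
                       order_col: str = "order") -> pd.DataFrame:
    """Check for carry-over effects between first-formulation groups.

    For every (region, formulation) cell, participants who applied
    sunscreen first are compared with those who applied moisturiser
    first — an independent t-test when the normality gate allows it,
    Mann-Whitney U otherwise.  Returns a tidy frame with one row per
    cell plus a ``consistent`` flag (no cell significant at 0.05).
    """
    if order_col not in table.columns:
        raise ValueError(f"order column {order_col!r} missing")
    groups = sorted(table[order_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 order groups, found {groups}")
    rows = []
    for (region, form), sub in table.groupby(["region", "formulation"],
                                             observed=True):
        ga = sub[sub[order_col] == groups[0]][dv].to_numpy(dtype=float)
        gb = sub[sub[order_col] == groups[1]][dv].to_numpy(dtype=float)
        if len(ga) < 2 or len(gb) < 2:
            raise ValueError(
                f"order group with n < 2 in cell ({region}, {form})"
            )
        pooled = np.concatenate([ga - ga.mean(), gb - gb.mean()])
        gate = normality_gate(pooled)
        if gate.path in ("parametric", "transformed"):
            stat, p = sps.ttest_ind(ga, gb)
            test = "independent t-test"
        else:
            stat, p = sps.mannwhitneyu(ga, gb, alternative="two-sided")
            test = "mann-whitney U"
        rows.append({
            "region": region, "formulation": form, "test": test,
            "statistic": float(stat), "p_value": float(p),
            "n_first": len(ga), "n_second": len(gb),
            "assumption_path": gate.path,
        })
    out = pd.DataFrame(rows)
    out["consistent"] = bool((out["p_value"] > ALPHA).all())
    return out


def dose_response_regression(records: pd.DataFrame,
                             dv: str = "mean_intensity",
                             mass_col: str = "mass",
                             form_col: str = "formulation") -> dict:
    """Linear dose-response of half-face mean intensity on applied mass.

    Fits ``mean_intensity ~ mass * formulation`` and reports the
    per-formulation slopes (grey levels per mg; negative = darkening)
    and the joint F test for any formulation effect (intercept shift or
    slope difference) against the mass-only model.
    """
    forms = sorted(records[form_col].unique())
    if len(forms) < 2:
        raise ValueError(f"need records for >= 2 formulations, found {forms}")
    for form in forms:
        n_mass = records.loc[records[form_col] == form, mass_col].nunique()
        if n_mass < 2:
            raise ValueError(
                f"formulation {form!r} has {n_mass} mass level(s); need >= 2"
            )
    if (records[mass_col] <= 0).any():
        raise ValueError("applied mass must be positive")
    full = ols(f"{dv} ~ {mass_col} * C({form_col})", data=records).fit()
    reduced = ols(f"{dv} ~ {mass_col}", data=records).fit()
    if full.ssr < 1e-12:
        f_stat, p, df_num = 0.0, 1.0, float(2 * (len(forms) - 1))
    else:
        f_stat, p, df_num = full.compare_f_test(reduced)
    slopes = {}
    base = forms[0]
    cov_params = full.cov_params()
    for form in forms:
        slope = float(full.params[mass_col])
        key = f"{mass_col}:C({form_col})[T.{form}]"
        if form == base or key not in full.params:
            se = float(full.bse[mass_col])
        else:
            slope += float(full.params[key])
            var = (cov_params.loc[mass_col, mass_col]
                   + cov_params.loc[key, key]
                   + 2.0 * cov_params.loc[mass_col, key])
            se = float(np.sqrt(max(var, 0.0)))
        slopes[form] = {"slope": slope, "se": se,
                        "df_resid": float(full.df_resid)}
    result = TestResult(
        "dose-response formulation effect", float(f_stat),
        (float(df_num), float(full.df_resid)), float(p),
        assumption_path="parametric",
    )
    return {"formulation_effect": result, "slopes": slopes, "model": full}


def tabulate_binary(outcomes) -> dict:
    """Tabulate binary covered/missed outcomes.

    Returns missed and total counts, the exact percent missed, and the
    whole-number display percent.  Display truncates the fraction
    (66 of 84 reads as 78%), the convention used when such counts are
    reported; the exact value is retained alongside.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to tabulate")
    bad = {o for o in outcomes if o not in ("covered", "missed")}
    if bad:
        raise ValueError(f"unrecognized outcomes: {sorted(bad)}")
    n_missed = sum(o == "missed" for o in outcomes)
    n_total = len(outcomes)
    percent = 100.0 * n_missed / n_total
    return {
        "n_missed": n_missed,
        "n_total": n_total,
        "percent_missed": percent,
        "percent_display": int(percent),
    }


def collapse_skin_type(table: pd.DataFrame,
                       col: str = "skin_type") -> pd.DataFrame:
    """Derive the collapsed skin group {I+II, III+IV} from skin type I-IV."""
    mapping = {"I": "I+II", "II": "I+II", "III": "III+IV", "IV": "III+IV"}
    out = table.copy()
    unknown = set(out[col].unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown skin types: {sorted(unknown)}")
    out["skin_group"] = out[col].map(mapping)
    return out


def validate_study_table(table: pd.DataFrame,
                         require_paired: bool = True) -> list[str]:
    """Return participants lacking both formulations (paired design)."""
    counts = table.groupby("participant", observed=True)["formulation"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete and require_paired:
        raise ValueError(
            f"participants missing a formulation: {incomplete}"
        )
    return incomplete
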