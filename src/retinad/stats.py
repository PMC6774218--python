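"""Cohort statistics: ANOVA + Tukey HSD, ANCOVA slope equality, t-tests.

Mirrors the statistical battery of a two-genotype longitudinal design:

* within each genotype, one-way ANOVA across ages with Tukey's HSD
  post-hoc for all age pairs (age treated as a categorical factor);
* between genotypes, ANCOVA on the linear model ``value ~ age * group``
  (age numeric, months); the group x age interaction F-test is the
  slope-equality test and its p-value is the chance of drawing data
  with slopes this different if the true slopes coincide;
* at each age, an independent two-sample t-test between genotypes
  (equal-variance classic Student by default, Welch optional).

No correction is applied across parameters; each parameter's battery
stands alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import InvalidParameterError

#: Tukey significance tiers and the letters used to annotate them in the
#: summary tables; a shared letter between two cells marks a pairwise
#: difference significant at that tier.
SIGNIFICANCE_TIERS = ((0.0001, "d"), (0.001, "c"), (0.01, "b"), (0.05, "a"))


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj

    def tukey_p(self, g1, g2) -> float:
        t = self.tukey
        hit = t[((t.group1 == g1) & (t.group2 == g2)) |
                ((t.group1 == g2) & (t.group2 == g1))]
        if hit.empty:
            raise KeyError((g1, g2))
        return float(hit.p_adj.iloc[0])


@dataclass
class AncovaResult:
    slopes: dict[str, float]
    intercepts: dict[str, float]
    interaction_f: float
    p_value: float
    df: tuple[int, int]


@dataclass
class TTestResult:
    t_stat: float
    df: float
    p_value: float


@dataclass
class StatsReport:
    """Full result surface of one cohort analysis."""

    cell_summary: pd.DataFrame  # genotype, age, parameter, mean, sd, n, letters
    anova: pd.DataFrame  # genotype, parameter, F, df1, df2, p
    tukey: pd.DataFrame  # genotype, parameter, age pair, meandiff, p_adj
    ancova: pd.DataFrame  # parameter, slopes, interaction F, p
    ttests: pd.DataFrame  # parameter, age, t, df, p
    notes: list[str] = field(default_factory=list)


def anova_tukey(groups: dict[object, np.ndarray]) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD across the given groups.

    ``groups`` maps a label (e.g. age in months) to that group's values.
    """
    if len(groups) < 2:
        raise InvalidParameterError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidParameterError(f"group {k!r} has n < 2")
    f_stat, p = sstats.f_oneway(*arrays.values())
    n_total = sum(v.size for v in arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[str(k)] * v.size for k, v in arrays.items()])
    if np.ptp(values) == 0:
        # degenerate all-equal data: statsmodels' Tukey is undefined; report
        # no pairwise differences
        pairs = [(a, b) for i, a in enumerate(arrays) for b in list(arrays)[i + 1:]]
        tukey = pd.DataFrame(
            [(str(a), str(b), 0.0, 1.0) for a, b in pairs],
            columns=["group1", "group2", "meandiff", "p_adj"],
        )
        return AnovaResult(0.0, len(groups) - 1, n_total - len(groups), 1.0, tukey)
    res = pairwise_tukeyhsd(values, labels)
    uniq = list(res.groupsunique)
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    tukey = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": np.asarray(res.meandiffs, float),
            "p_adj": np.asarray(res.pvalues, float),
        }
    )
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        p_value=float(p),
        tukey=tukey,
    )


def ancova_slopes(
    values: np.ndarray,
    ages: np.ndarray,
    groups: np.ndarray,
) -> AncovaResult:
    """Slope-equality test between two groups via the age x group interaction.

    Fits ``value ~ age * C(group)`` with age numeric and reports each
    group's fitted slope plus the interaction F-test (for two groups a
    single-df test, F = t²).
    """
    df = pd.DataFrame({"value": values, "age": ages, "group": groups})
    levels = sorted(df.group.unique())
    if len(levels) != 2:
        raise InvalidParameterError("slope comparison requires exactly two groups")
    for lv in levels:
        if df[df.group == lv].age.nunique() < 2:
            raise InvalidParameterError(f"group {lv!r} needs >= 2 distinct ages")
    model = ols("value ~ age * C(group)", data=df).fit()
    inter = [c for c in model.params.index if c.startswith("age:")]
    if len(inter) != 1 or not np.isfinite(model.bse[inter[0]]):
        raise InvalidParameterError("singular design in slope comparison")
    term = inter[0]
    tval = float(model.tvalues[term])
    pval = float(model.pvalues[term])
    base, other = levels
    slope0 = float(model.params["age"])
    slope1 = slope0 + float(model.params[term])
    icpt0 = float(model.params["Intercept"])
    icpt_terms = [c for c in model.params.index if c.startswith("C(group)")]
    icpt1 = icpt0 + float(model.params[icpt_terms[0]])
    return AncovaResult(
        slopes={str(base): slope0, str(other): slope1},
        intercepts={str(base): icpt0, str(other): icpt1},
        interaction_f=tval**2,
        p_value=pval,
        df=(1, int(model.df_resid)),
    )


def ttest_by_age(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> TTestResult:
    """Independent two-sample t-test between the genotypes at one age."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("t-test needs n >= 2 per group")
    res = sstats.ttest_ind(x, y, equal_var=equal_var)
    df = (x.size + y.size - 2) if equal_var else float(res.df)
    return TTestResult(t_stat=float(res.statistic), df=float(df),
                       p_value=float(res.pvalue))


def _tier_letter(p: float) -> str | None:
    for thr, letter in SIGNIFICANCE_TIERS:
        if p < thr:
            return letter
    return None


def assign_letters(anova: AnovaResult) -> dict[str, str]:
    """Tukey-style significance letters per group.

    Each significant pair contributes the letter of the smallest tier
    its adjusted p passes to *both* its members, so a shared letter
    marks a significant pairwise difference at that tier.
    """
    letters: dict[str, set[str]] = {}
    for _, row in anova.tukey.iterrows():
        letter = _tier_letter(float(row.p_adj))
        if letter:
            letters.setdefault(str(row.group1), set()).add(letter)
            letters.setdefault(str(row.group2), set()).add(letter)
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def build_summary(cohort: pd.DataFrame) -> StatsReport:
    """Run the full battery over a long-format cohort table.

    ``cohort`` columns: ``animal_id, genotype, age_months, parameter,
    value``.  Returns per-cell mean ± SD with significance letters,
    per-genotype ANOVA/Tukey across ages, per-parameter ANCOVA slope
    tests and per-age between-genotype t-tests.  Parameters with
    missing cells are reported in ``notes`` and their tests skipped.
    """
    required = {"animal_id", "genotype", "age_months", "parameter", "value"}
    if not required.issubset(cohort.columns):
        raise InvalidParameterError(f"cohort table needs columns {sorted(required)}")
    notes: list[str] = []
    cells, anova_rows, tukey_rows, ancova_rows, ttest_rows = [], [], [], [], []
    genotypes = sorted(cohort.genotype.unique())
    for param, sub in cohort.groupby("parameter"):
        ages = sorted(sub.age_months.unique())
        for g in genotypes:
            gsub = sub[sub.genotype == g]
            groups = {a: gsub[gsub.age_months == a].value.to_numpy() for a in ages}
            missing = [a for a, v in groups.items() if v.size == 0]
            if missing:
                notes.append(f"{param}/{g}: missing ages {missing}; ANOVA skipped")
                groups = {a: v for a, v in groups.items() if v.size > 0}
            letters: dict[str, str] = {}
            if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
                res = anova_tukey(groups)
                anova_rows.append(
                    (g, param, res.f_stat, res.df_between, res.df_within, res.p_value)
                )
                for _, row in res.tukey.iterrows():
                    tukey_rows.append(
                        (g, param, row.group1, row.group2,
                         float(row.meandiff), float(row.p_adj))
                    )
                letters = assign_letters(res)
            else:
                notes.append(f"{param}/{g}: fewer than two usable ages; ANOVA skipped")
            for a, v in groups.items():
                cells.append(
                    (g, a, param, float(np.mean(v)),
                     float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
                     int(v.size), letters.get(str(a), ""))
                )
        # ANCOVA over the two genotypes
        if len(genotypes) == 2 and sub.groupby("genotype").age_months.nunique().min() >= 2:
            try:
                anc = ancova_slopes(
                    sub.value.to_numpy(),
                    sub.age_months.to_numpy(float),
                    sub.genotype.to_numpy(),
                )
                ancova_rows.append(
                    (param, anc.slopes[genotypes[0]], anc.slopes[genotypes[1]],
                     anc.interaction_f, anc.p_value)
                )
            except InvalidParameterError as exc:
                notes.append(f"{param}: ANCOVA skipped ({exc})")
        else:
            notes.append(f"{param}: ANCOVA skipped (needs 2 genotypes x >=2 ages)")
        # per-age t-tests
        if len(genotypes) == 2:
            for a in ages:
                x = sub[(sub.genotype == genotypes[0]) & (sub.age_months == a)].value
                y = sub[(sub.genotype == genotypes[1]) & (sub.age_months == a)].value
                if x.size >= 2 and y.size >= 2:
                    t = ttest_by_age(x.to_numpy(), y.to_numpy())
                    ttest_rows.append((param, a, t.t_stat, t.df, t.p_value))
    return StatsReport(
        cell_summary=pd.DataFrame(
            cells,
            columns=["genotype", "age_months", "parameter", "mean", "sd", "n", "letters"],
        ),
        anova=pd.DataFrame(
            anova_rows, columns=["genotype", "parameter", "F", "df1", "df2", "p"]
        ),
        tukey=pd.DataFrame(
            tukey_rows,
            columns=["genotype", "parameter", "age1", "age2", "meandiff", "p_adj"],
        ),
        ancova=pd.DataFrame(
            ancova_rows,
            columns=["parameter", "slope_group1", "slope_group2", "interaction_F", "p"],
        ),
        ttests=pd.DataFrame(
            ttest_rows, columns=["parameter", "age_months", "t", "df", "p"]
        ),
        notes=notes,
    )
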