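"""Group-comparison statistics: the normality-gated decision tree.

Every outcome is first gated by Shapiro-Wilk normality per group (all
groups must pass at alpha = 0.05). Normally distributed data go to a
one-way ANOVA (group effects) or a two-way repeated-measures ANOVA
(group, time, interaction) with Tukey's post-hoc test; non-normal data go
to the Wilcoxon rank-sum test (two groups), the Kruskal-Wallis test with
Dunn's corrected post-hoc (more than two groups), or the Friedman test
for repeated measures.

The named tests come from scipy / statsmodels / pingouin; this module
contributes the gate, the wiring between omnibus and post-hoc tests, a
hand-rolled Dunn's test (rank-sum z statistics with mid-rank tie
correction and Bonferroni adjustment over all pairs), and a uniform
result/report schema.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05

#: Sums-of-squares convention used for the mixed (two-way RM) ANOVA with
#: unequal group sizes; stated in every report header.
RM_ANOVA_SS_NOTE = ("mixed ANOVA (between = arm, within = timepoint) via "
                    "pingouin.mixed_anova, Type II sums of squares")


@dataclass
class StatResult:
    """One omnibus test with optional post-hoc pairs."""

    test_name: str
    symbol: str                     # F, H, Q, W, t or z
    statistic: float
    df: tuple | None
    p: float
    gate: str                       # "parametric" or "nonparametric"
    post_hoc: list[tuple[str, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    effects: dict[str, "StatResult"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0 <= self.p <= 1):
            raise ValueError("p outside [0, 1]")


def _as_groups(values_by_group: dict) -> dict[str, np.ndarray]:
    out = {}
    for k, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        out[str(k)] = arr
    return {k: v for k, v in out.items() if v.size > 0}


def normality_gate(values_by_group: dict, alpha: float = DEFAULT_ALPHA,
                   ) -> tuple[str, list[str]]:
    """Classify data as parametric iff every group passes Shapiro-Wilk.

    Groups with fewer than three values cannot be tested and force the
    nonparametric branch with a warning note. Returns (gate, notes).
    """
    groups = _as_groups(values_by_group)
    notes: list[str] = []
    for name, vals in groups.items():
        if vals.size < 3:
            notes.append(f"group {name} has n={vals.size} < 3: "
                         "normality untestable, using nonparametric branch")
            warnings.warn(notes[-1], stacklevel=2)
            return "nonparametric", notes
        if np.ptp(vals) == 0:
            notes.append(f"group {name} is constant: nonparametric branch")
            return "nonparametric", notes
        if sps.shapiro(vals).pvalue < alpha:
            return "nonparametric", notes
    return "parametric", notes


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> list[tuple[str, float]]:
    names = list(groups)
    res = sps.tukey_hsd(*(groups[g] for g in names))
    return [(f"{g1} vs {g2}", float(res.pvalue[i, j]))
            for (i, g1), (j, g2)
            in itertools.combinations(enumerate(names), 2)]


def dunn_posthoc(groups: dict[str, np.ndarray]) -> list[tuple[str, float]]:
    """Dunn's multiple-comparison test after Kruskal-Wallis.

    Pairwise z statistics on pooled mean ranks with mid-rank tie
    correction; two-sided p values Bonferroni-adjusted over all pairs
    (clipped at 1).
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)  # mid-ranks for ties
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()
                      / (12.0 * (n_total - 1))) if n_total > 1 else 0.0)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0:
            p = 1.0
        else:
            z = abs(mean_ranks[g1] - mean_ranks[g2]) / se
            p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        out.append((f"{g1} vs {g2}", float(p)))
    return out


def compare_groups(values_by_group: dict, gate: str | None = None,
                   alpha: float = DEFAULT_ALPHA,
                   post_hoc: bool = True) -> StatResult:
    """Independent-group comparison along the gated decision tree.

    parametric -> one-way ANOVA with Tukey post-hoc; nonparametric ->
    Wilcoxon rank-sum (two groups) or Kruskal-Wallis with Dunn post-hoc
    (more than two). ``gate=None`` runs :func:`normality_gate` first.
    ``post_hoc=False`` skips the pairwise tests (the omnibus result is
    unaffected); useful in simulation loops.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    notes: list[str] = []
    if gate is None:
        gate, notes = normality_gate(groups, alpha)

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        # no variance anywhere: no evidence of any group difference
        return StatResult("degenerate (no variance)", "H", 0.0, None, 1.0,
                          gate, notes=notes + ["all values identical"])

    if gate == "parametric":
        res = sps.f_oneway(*groups.values())
        k = len(groups)
        n = sum(v.size for v in groups.values())
        return StatResult("one-way ANOVA", "F", float(res.statistic),
                          (k - 1, n - k), float(res.pvalue), gate,
                          post_hoc=_tukey_posthoc(groups) if post_hoc else [],
                          notes=notes)
    if len(groups) == 2:
        a, b = groups.values()
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        if _has_ties(pooled):
            notes = notes + ["ties handled by mid-ranks"]
        return StatResult("Wilcoxon rank-sum", "W", float(res.statistic),
                          None, float(res.pvalue), "nonparametric",
                          notes=notes)
    res = sps.kruskal(*groups.values())
    if _has_ties(pooled):
        notes = notes + ["ties handled by mid-ranks"]
    return StatResult("Kruskal-Wallis", "H", float(res.statistic),
                      (len(groups) - 1,), float(res.pvalue), "nonparametric",
                      post_hoc=dunn_posthoc(groups) if post_hoc else [],
                      notes=notes)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def repeated_measures(table: pd.DataFrame, gate: str | None = None,
                      alpha: float = DEFAULT_ALPHA,
                      value: str = "value", subject: str = "animal_id",
                      within: str = "timepoint", between: str = "arm",
                      ) -> StatResult:
    """Repeated-measures comparison over ``subject`` x ``within`` cells.

    Parametric: two-way mixed ANOVA (between-group, within-time and their
    interaction; pingouin, Type II sums of squares) with Tukey post-hoc on
    the subject means per group. Nonparametric: Friedman test over the
    within-factor (subjects as blocks, pooled across groups). Subjects
    missing any timepoint are removed listwise and noted.
    """
    df = table[[subject, within, between, value]].dropna().copy()
    n_tp = df[within].nunique()
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == n_tp].index
    removed = sorted(set(df[subject]) - set(keep))
    notes = []
    if removed:
        notes.append(f"listwise removal of incomplete subjects: {removed}")
    df = df[df[subject].isin(keep)]
    if df.empty or df[subject].nunique() < 2:
        raise ValueError("need at least two complete subjects")

    if gate is None:
        # gate on the model residuals (value minus its group x time cell
        # mean): one Shapiro-Wilk on the pooled residuals, rather than
        # many low-powered tests on tiny cells
        resid = (df[value]
                 - df.groupby([between, within])[value].transform("mean"))
        if df.groupby(between)[subject].nunique().min() < 2 \
                or np.ptp(resid.to_numpy()) == 0:
            gate = "nonparametric"
            notes.append("groups too small or degenerate for residual "
                         "normality testing: nonparametric branch")
        else:
            gate = ("parametric"
                    if sps.shapiro(resid).pvalue >= alpha
                    else "nonparametric")
            notes.append(f"gate: Shapiro-Wilk on cell-mean residuals "
                         f"({gate})")

    if gate == "parametric":
        import pingouin as pg
        aov = pg.mixed_anova(data=df, dv=value, within=within,
                             subject=subject, between=between)
        effects: dict[str, StatResult] = {}
        for _, row in aov.iterrows():
            name = {between: "group", within: "time"}.get(
                row["Source"], "interaction")
            effects[name] = StatResult(
                "mixed ANOVA", "F", float(row["F"]),
                (float(row["DF1"]), float(row["DF2"])), float(row["p_unc"]),
                gate, notes=[RM_ANOVA_SS_NOTE])
        subj_means = df.groupby([subject, between])[value].mean().reset_index()
        groups = {a: g[value].to_numpy()
                  for a, g in subj_means.groupby(between)}
        post = _tukey_posthoc(groups) if len(groups) > 1 else []
        inter = effects.get("interaction", next(iter(effects.values())))
        return StatResult("two-way RM ANOVA", "F", inter.statistic, inter.df,
                          inter.p, gate, post_hoc=post,
                          notes=notes + [RM_ANOVA_SS_NOTE], effects=effects)

    # Friedman over timepoints, subjects as blocks
    wide = df.pivot_table(index=subject, columns=within, values=value)
    cols = [wide[c].to_numpy() for c in wide.columns]
    if len(cols) < 3:
        # two timepoints: Friedman degenerates to a sign-test ordering;
        # use the Wilcoxon signed-rank test, the standard two-level analog
        res = sps.wilcoxon(cols[0], cols[1])
        return StatResult("Wilcoxon signed-rank", "W", float(res.statistic),
                          None, float(res.pvalue), "nonparametric",
                          notes=notes + ["two timepoints: signed-rank used"])
    res = sps.friedmanchisquare(*cols)
    return StatResult("Friedman", "Q", float(res.statistic),
                      (len(cols) - 1,), float(res.pvalue), "nonparametric",
                      notes=notes)


def outcome_report(outcomes: dict[str, pd.DataFrame],
                   alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Run the decision tree on every outcome table and tabulate results.

    Each outcome table needs columns ``animal_id``, ``arm`` and ``value``
    (one row per animal); tables with a ``timepoint`` column of more than
    one level go through the repeated-measures branch. Returns one row per
    outcome with the gate, test, statistic, p, significance flag at
    ``alpha`` and the post-hoc pairs below ``alpha``.
    """
    rows = []
    for name, tab in outcomes.items():
        if tab is None or len(tab) == 0:
            warnings.warn(f"outcome {name!r} has no data; row omitted",
                          stacklevel=2)
            continue
        try:
            if "timepoint" in tab.columns and tab["timepoint"].nunique() > 1:
                rm = repeated_measures(tab, alpha=alpha)
                if "group" in rm.effects:
                    res = rm.effects["group"]
                    res = StatResult(rm.test_name + " (group effect)",
                                     res.symbol, res.statistic, res.df,
                                     res.p, rm.gate, post_hoc=rm.post_hoc,
                                     notes=rm.notes)
                else:
                    # nonparametric repeated measures: the Friedman test
                    # addresses time only, so the group question goes to a
                    # rank test on the per-subject means across timepoints
                    subj = tab.groupby(["animal_id", "arm"])["value"] \
                        .mean().reset_index()
                    groups = {a: g["value"].to_numpy()
                              for a, g in subj.groupby("arm")}
                    res = compare_groups(groups, gate="nonparametric",
                                         alpha=alpha)
                    res.notes = rm.notes + res.notes + [
                        "group effect via rank test on subject means; "
                        f"time effect: {rm.test_name} {rm.symbol}="
                        f"{rm.statistic:.3g}, p={rm.p:.4g}"]
                p_group = res.p
            else:
                groups = {a: g["value"].to_numpy()
                          for a, g in tab.groupby("arm")}
                res = compare_groups(groups, alpha=alpha)
                p_group = res.p
        except ValueError as err:
            warnings.warn(f"outcome {name!r} not testable: {err}",
                          stacklevel=2)
            continue
        sig_pairs = [f"{pair} (p={p:.4g})"
                     for pair, p in res.post_hoc if p < alpha]
        rows.append({
            "outcome": name, "gate": res.gate, "test": res.test_name,
            "symbol": res.symbol, "statistic": res.statistic,
            "df": "x".join(str(d) for d in res.df) if res.df else "",
            "p": p_group, "significant": bool(p_group < alpha),
            "posthoc_significant": "; ".join(sig_pairs),
            "notes": "; ".join(res.notes),
        })
    return pd.DataFrame(rows, columns=[
        "outcome", "gate", "test", "symbol", "statistic", "df", "p",
        "significant", "posthoc_significant", "notes"])
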