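"""Descriptive-sensory statistics: panel means, mixed ANOVA, Tukey letters.

A trained panel (10 assessors) scores a set of samples (storage time x
packaging) on unstructured 0-15 cm line scales, each sample four times in
separate sessions.  The analysis treats the sample effect as fixed and the
assessor and replicate effects as random.  For a balanced complete design
the classical expected-mean-squares rules give the sample F test its correct
denominator: the sample x assessor interaction mean square, not the residual.
Significant attributes are followed up with Tukey's HSD on the same error
term, summarised as a compact letter display (samples sharing no letter
differ at the chosen alpha).

Sums of squares are obtained from a sequential-ANOVA fit of
``value ~ sample + assessor + replicate + sample:assessor`` (orthogonal on a
balanced design, so the decomposition is unique); the replicate x sample
interaction is pooled into the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaTable",
    "summarize_attribute",
    "mixed_anova",
    "tukey_letters",
    "attribute_screen",
    "split_scores",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["assessor", "sample", "packaging", "weeks", "replicate", "attribute", "value"]

SCALE_RANGE = (0.0, 15.0)


def _check_balance(sub: pd.DataFrame, attribute: str):
    """A balanced complete design has exactly one observation per cell."""
    samples = sub["sample"].unique()
    assessors = sub["assessor"].unique()
    replicates = sub["replicate"].unique()
    counts = sub.groupby(["sample", "assessor", "replicate"]).size()
    expected = pd.MultiIndex.from_product(
        [samples, assessors, replicates], names=["sample", "assessor", "replicate"]
    )
    missing = expected.difference(counts.index)
    dupes = counts[counts > 1]
    if len(missing) or len(dupes):
        raise ValueError(
            f"attribute {attribute!r}: unbalanced design; "
            f"missing cells {list(missing)[:10]}, duplicated cells {list(dupes.index)[:10]}"
        )


def summarize_attribute(scores: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Per-sample panel means: replicate-level means, their mean and sd.

    For each sample, the panel mean over assessors is computed per replicate
    session; the reported sample mean is the mean of those replicate means
    and the sd is taken over exactly the replicate means (n = number of
    replicates, ddof=1).  Missing cells are rejected with their list.
    """
    sub = scores[scores["attribute"] == attribute]
    if sub.empty:
        raise ValueError(f"no scores for attribute {attribute!r}")
    _check_balance(sub, attribute)
    rep_means = (
        sub.groupby(["sample", "replicate"])["value"].mean().unstack("replicate")
    )
    out = pd.DataFrame(
        {
            "mean": rep_means.mean(axis=1),
            "sd": rep_means.std(axis=1, ddof=1),
        }
    )
    rep_means.columns = [f"rep_{r}" for r in rep_means.columns]
    out = pd.concat([rep_means, out], axis=1)
    out.index.name = "sample"
    return out


@dataclass
class AnovaTable:
    """Mixed-ANOVA decomposition for one attribute.

    ``table`` holds SS, df and MS for sample, assessor, replicate, the
    sample x assessor interaction and the residual.  ``f_sample`` tests the
    fixed sample effect against the interaction mean square.
    """

    attribute: str
    table: pd.DataFrame
    f_sample: float
    p_sample: float
    df_num: int
    df_den: int
    ms_error: float
    alpha: float = 0.05
    degenerate: bool = False
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(
            not self.degenerate and np.isfinite(self.p_sample) and self.p_sample < self.alpha
        )


def mixed_anova(scores: pd.DataFrame, attribute: str, alpha: float = 0.05) -> AnovaTable:
    """Balanced mixed ANOVA (sample fixed; assessor, replicate random).

    Requires a balanced complete design with at least two samples and two
    assessors.  The p value of the sample effect comes from
    ``F = MS_sample / MS_sample_x_assessor`` on (a-1, (a-1)(b-1)) degrees of
    freedom.  A zero interaction mean square (no variation) is flagged as
    degenerate rather than producing a 0/0 F ratio.
    """
    sub = scores[scores["attribute"] == attribute].copy()
    if sub.empty:
        raise ValueError(f"no scores for attribute {attribute!r}")
    if sub["sample"].nunique() < 2 or sub["assessor"].nunique() < 2:
        raise ValueError("mixed ANOVA needs at least 2 samples and 2 assessors")
    _check_balance(sub, attribute)
    fit = smf.ols(
        "value ~ C(sample) + C(assessor) + C(replicate) + C(sample):C(assessor)", data=sub
    ).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = anova_lm(fit, typ=1)
    rename = {
        "C(sample)": "sample",
        "C(assessor)": "assessor",
        "C(replicate)": "replicate",
        "C(sample):C(assessor)": "sample:assessor",
        "Residual": "residual",
    }
    table = aov.rename(index=rename)[["sum_sq", "df"]]
    table.columns = ["ss", "df"]
    table["ms"] = table["ss"] / table["df"]
    total = pd.DataFrame(
        {"ss": [table["ss"].sum()], "df": [table["df"].sum()], "ms": [np.nan]},
        index=["total"],
    )
    table = pd.concat([table, total])
    ms_s = table.loc["sample", "ms"]
    ms_sa = table.loc["sample:assessor", "ms"]
    df_num = int(table.loc["sample", "df"])
    df_den = int(table.loc["sample:assessor", "df"])
    scale = max(table.loc["total", "ss"], 1.0)
    degenerate = ms_sa <= 1e-12 * scale
    if degenerate:
        f_sample, p_sample = np.nan, np.nan
    else:
        f_sample = ms_s / ms_sa
        p_sample = float(st.f.sf(f_sample, df_num, df_den))
    return AnovaTable(
        attribute=attribute,
        table=table,
        f_sample=float(f_sample),
        p_sample=float(p_sample) if np.isfinite(f_sample) else np.nan,
        df_num=df_num,
        df_den=df_den,
        ms_error=float(ms_sa),
        alpha=alpha,
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Tukey HSD and compact letter display


def _insert_absorb(names, sig_pairs):
    """Compact letter display by insert-and-absorb.

    Start from one group holding every sample; for each significantly
    different pair, split every group containing both; absorb groups that
    became subsets of others.  Two samples then share a letter iff they were
    never declared different.
    """
    groups = [set(names)]
    for i, j in sig_pairs:
        new_groups = []
        for g in groups:
            if i in g and j in g:
                new_groups.extend([g - {i}, g - {j}])
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    # letter order follows the best (first-listed) member of each group
    pos = {n: k for k, n in enumerate(names)}
    groups.sort(key=lambda g: min(pos[n] for n in g))
    letters = {n: "" for n in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, g in zip(alphabet, groups):
        for n in g:
            letters[n] += letter
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def tukey_letters(
    anova: AnovaTable, scores: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD compact letter display for the sample means of one attribute.

    All pairwise sample-mean differences are compared with
    ``q(alpha, k, df) * sqrt(MS_error / n)`` where ``MS_error`` is the ANOVA
    error term of the sample test (the sample x assessor interaction), ``df``
    its degrees of freedom and ``n`` the number of observations per sample.
    Letters are produced even without a significant omnibus effect (then all
    samples share one letter unless a pair still exceeds the HSD).
    """
    sub = scores[scores["attribute"] == anova.attribute]
    means = sub.groupby("sample")["value"].agg(["mean", "size"])
    if means["size"].nunique() != 1:
        raise ValueError("unequal sample sizes; Tukey HSD requires a balanced design")
    n_per = int(means["size"].iloc[0])
    order = means.sort_values("mean", ascending=False).index.tolist()
    k = len(order)
    if anova.degenerate or not np.isfinite(anova.ms_error) or anova.ms_error <= 0:
        sig_pairs = []
        hsd = np.nan
    else:
        q_crit = st.studentized_range.ppf(1 - alpha, k, anova.df_den)
        hsd = q_crit * np.sqrt(anova.ms_error / n_per)
        sig_pairs = [
            (a, b)
            for ai, a in enumerate(order)
            for b in order[ai + 1 :]
            if abs(means.loc[a, "mean"] - means.loc[b, "mean"]) > hsd
        ]
    letters = _insert_absorb(order, sig_pairs)
    out = means.loc[order, ["mean"]].copy()
    out["letters"] = [letters[s] for s in order]
    out.attrs["hsd"] = float(hsd) if np.isfinite(hsd) else np.nan
    out.index.name = "sample"
    return out


def split_scores(scores: pd.DataFrame) -> dict:
    """The three analysis splits: plastic pouches, aluminium pouches, combined."""
    return {
        "plastic": scores[scores["packaging"] == "plastic"].copy(),
        "aluminium": scores[scores["packaging"] == "aluminium"].copy(),
        "combined": scores.copy(),
    }


def attribute_screen(scores_by_split: dict, alpha: float = 0.05) -> dict:
    """Attributes with a significant sample effect, per dataset split.

    ``scores_by_split`` maps split name -> long score table; the result maps
    split name -> list of attribute names whose mixed-ANOVA sample effect is
    significant at ``alpha``.  These attributes feed the PCA stage.
    """
    out = {}
    for split, table in scores_by_split.items():
        sig = []
        for attribute in pd.unique(table["attribute"]) if len(table) else []:
            res = mixed_anova(table, attribute, alpha=alpha)
            if res.significant:
                sig.append(attribute)
        out[split] = sig
    return out
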