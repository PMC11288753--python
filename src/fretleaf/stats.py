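"""Statistical comparisons for the pipeline outputs.

Implements the study-style comparison set: Welch/Student t tests, two-way
factorial ANOVA (type-II sums of squares) with Tukey or Sidak post-hoc,
Benjamini–Hochberg FDR q-values, the per-cell-type nucleus-count comparison,
and Pearson R². Welch (unequal-variance) is the default two-sample test; a
pooled-variance mode is available by flag.

Degenerate-input conventions: two samples with zero variance and equal means
give p = 1 (statistic 0) with a note; an effect whose sum of squares is zero
to numerical tolerance gets F = 0, p = 1 rather than a 0/0 NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "FactorialResult",
    "welch_t",
    "two_way_factorial",
    "bh_fdr",
    "count_comparison",
    "pearson_r2",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p: float
    effect: float  # mean(a) - mean(b)
    n_a: int
    n_b: int
    q: float | None = None
    note: str = ""


def welch_t(a, b, equal_var: bool = False, labels=("a", "b")) -> ComparisonResult:
    """Two-sided two-sample t test (Welch by default; Student with equal_var).

    Requires n >= 2 per sample. Two constant samples with equal means give
    p = 1 by convention; constant samples with different means give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    effect = float(a.mean() - b.mean())
    test = "student_t" if equal_var else "welch_t"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(effect, 0.0):
            logger.debug("both samples constant with equal means: p = 1 convention")
            return ComparisonResult(labels[0], labels[1], test, 0.0, 1.0,
                                    effect, a.size, b.size, note="zero_variance")
        return ComparisonResult(labels[0], labels[1], test,
                                float(np.sign(effect)) * np.inf, 0.0,
                                effect, a.size, b.size, note="zero_variance")
    import warnings

    with warnings.catch_warnings():
        # near-identical samples are legitimate here (discrete counts);
        # exact degeneracy is already handled by the conventions above
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(labels[0], labels[1], test,
                            float(res.statistic), float(res.pvalue),
                            effect, a.size, b.size)


@dataclass
class FactorialResult:
    anova: pd.DataFrame  # rows R, C, R:C, Residual; sum_sq/df/F/p/significant
    posthoc: pd.DataFrame | None
    alpha: float
    note: str = ""

    @property
    def interaction_significant(self) -> bool:
        return bool(self.anova.loc["R:C", "significant"])


def two_way_factorial(
    values,
    factor_r,
    factor_c,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> FactorialResult:
    """Two-way factorial ANOVA with type-II SS on a (near-)balanced design.

    Requires >= 2 levels per factor and >= 2 replicates per cell so the
    interaction is estimable; an empty design cell raises, naming the cell.
    The post-hoc table (Tukey HSD or Sidak-corrected pairwise Welch t over
    the R×C cells) is computed only when the interaction — or, failing that,
    a main effect — is significant, mirroring how such designs are reported.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if posthoc not in ("tukey", "sidak"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "fr": np.asarray(factor_r).astype(str),
        "fc": np.asarray(factor_c).astype(str),
    })
    r_levels = sorted(df["fr"].unique())
    c_levels = sorted(df["fc"].unique())
    if len(r_levels) < 2 or len(c_levels) < 2:
        raise ValueError("need >= 2 levels per factor")
    cell_n = df.groupby(["fr", "fc"], observed=True).size()
    for r in r_levels:
        for c in c_levels:
            n = cell_n.get((r, c), 0)
            if n == 0:
                raise ValueError(f"empty design cell (R={r!r}, C={c!r})")
            if n < 2:
                raise ValueError(
                    f"design cell (R={r!r}, C={c!r}) has {n} replicate; "
                    "the interaction needs >= 2"
                )

    note = ""
    total_var = df["value"].var(ddof=0)
    if total_var == 0:
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": [len(r_levels) - 1, len(c_levels) - 1,
                                   (len(r_levels) - 1) * (len(c_levels) - 1),
                                   len(df) - len(r_levels) * len(c_levels)],
             "F": 0.0, "p": 1.0},
            index=["R", "C", "R:C", "Residual"],
        )
        note = "all values identical: p = 1 convention"
    else:
        model = smf.ols("value ~ C(fr) * C(fc)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        tab = tab.rename(index={"C(fr)": "R", "C(fc)": "C", "C(fr):C(fc)": "R:C"})
        anova = pd.DataFrame({
            "sum_sq": tab["sum_sq"],
            "df": tab["df"],
            "F": tab.get("F"),
            "p": tab.get("PR(>F)"),
        })
        # zero-SS effects (e.g. exactly additive data) -> F = 0, p = 1
        scale = max(float(anova["sum_sq"].sum()), 1.0)
        for idx in ("R", "C", "R:C"):
            if anova.loc[idx, "sum_sq"] <= 1e-10 * scale or not np.isfinite(
                anova.loc[idx, "F"]
            ):
                zero = anova.loc[idx, "sum_sq"] <= 1e-10 * scale
                anova.loc[idx, "F"] = 0.0 if zero else anova.loc[idx, "F"]
                if zero:
                    anova.loc[idx, "p"] = 1.0
        anova.loc["Residual", ["F", "p"]] = np.nan
    anova["significant"] = anova["p"] < alpha

    post = None
    effects_sig = anova.loc[["R", "C", "R:C"], "significant"]
    residual_ss = float(anova.loc["Residual", "sum_sq"])
    if residual_ss <= 1e-12 * max(float(anova["sum_sq"].sum()), 1.0):
        # exact (noise-free) data: studentized ranges are undefined
        note = (note + "; " if note else "") + "zero residual variance: post-hoc skipped"
    elif effects_sig.any() and total_var > 0:
        cells = (df["fr"] + ":" + df["fc"]).to_numpy()
        if posthoc == "tukey":
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(df["value"].to_numpy(), cells, alpha=alpha)
            post = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        else:
            from statsmodels.stats.multitest import multipletests

            rows = []
            names = sorted(set(cells))
            for i, gi in enumerate(names):
                for gj in names[i + 1:]:
                    r = welch_t(df.loc[cells == gi, "value"],
                                df.loc[cells == gj, "value"], labels=(gi, gj))
                    rows.append({"group1": gi, "group2": gj,
                                 "meandiff": r.effect, "p_raw": r.p})
            post = pd.DataFrame(rows)
            if len(post):
                rej, p_adj, *_ = multipletests(post["p_raw"], alpha=alpha,
                                               method="sidak")
                post["p_adj"] = p_adj
                post["reject"] = rej
    return FactorialResult(anova=anova, posthoc=post, alpha=alpha, note=note)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j)·m/j over the sorted p-values, mapped back to
    the input order; elementwise q >= p and q is permutation-invariant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def count_comparison(
    count_table: pd.DataFrame,
    condition_col: str = "condition",
    control_label: str = "control",
    infested_label: str = "infested",
) -> pd.DataFrame:
    """Per-cell-type Welch t on per-image nucleus counts, BH-FDR corrected.

    ``count_table`` has one row per image: the condition column, an image
    identifier, one column per cell type, and (optionally) ``total`` —
    added from the class columns if absent. Requires >= 2 images per
    condition. Returns one row per class plus total with effect
    (infested − control mean count), t, p and q.
    """
    df = count_table.copy()
    class_cols = [c for c in df.columns
                  if c not in (condition_col, "image_id", "total")]
    if "total" not in df.columns:
        df["total"] = df[class_cols].sum(axis=1)
    ctl = df[df[condition_col] == control_label]
    inf = df[df[condition_col] == infested_label]
    if len(ctl) < 2 or len(inf) < 2:
        raise ValueError("need >= 2 images per condition")
    rows = []
    for col in [*class_cols, "total"]:
        r = welch_t(inf[col], ctl[col], labels=(infested_label, control_label))
        rows.append({
            "cell_type": col,
            "mean_control": float(ctl[col].mean()),
            "mean_infested": float(inf[col].mean()),
            "effect": r.effect,
            "statistic": r.statistic,
            "p": r.p,
            "note": r.note,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def pearson_r2(x, y) -> float:
    """Squared Pearson product-moment correlation, in [0, 1].

    Requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)
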