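"""Genotype-phenotype statistics: GLM association, FDR, group tests, survival.

Per-variant association uses a linear model phenotype ~ dosage + covariates
with Wald tests and Benjamini-Hochberg FDR control across all tested
variants. Group comparisons cover the unpaired t-test, the one-sample
t-test used for very rare carriers, and one-way ANOVA with Dunnett's
correction against a control group. Transfusion-free survival is compared
across haplogroups by Kaplan-Meier estimation and the log-rank test. A
burden score counts "beneficial" catalogued alleles per sample and tests
the phenotype trend over the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeRecord:
    """One sample's phenotypes: HbF (g/L), transfusion history, ferritin (ug/L)."""

    sample_id: str
    hbf: float
    age_first_transfusion: float  # years; censoring time when never transfused
    transfused: bool
    ferritin: float
    age: float = np.nan
    sex: int = 0

    def __post_init__(self) -> None:
        for name in ("hbf", "age_first_transfusion", "ferritin"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{self.sample_id}: {name} must be non-negative")


def load_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV (sample_id, hbf, age_first_transfusion, transfused, ferritin, age, sex)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "hbf", "age_first_transfusion", "transfused", "ferritin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min over j >= i of m * p_(j) / j for the sorted p-values,
    mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class AssocResult:
    variant: str
    n: int
    beta: float
    se: float
    p: float
    q: float
    maf: float


def gwas_glm(
    dosages: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    min_n: int = 10,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-variant linear-model association with BH-FDR over tested variants.

    ``dosages`` is samples x variants with values in {0, 1, 2}. Each variant
    is fit as phenotype ~ dosage (+ covariates) by OLS; the dosage Wald p
    feeds a single BH correction across all tested variants. Monomorphic
    variants, variants below the MAF floor, variants with fewer than
    ``min_n`` phenotyped samples and singular designs are skipped with a
    recorded reason.
    """
    import statsmodels.api as sm

    idx = phenotype.dropna().index.intersection(dosages.index)
    if covariates is not None:
        covariates = covariates.loc[idx].astype(float)
    y = phenotype.loc[idx].astype(float)
    skipped: dict[str, str] = {}
    rows = []
    for var in dosages.columns:
        d = dosages.loc[idx, var].astype(float)
        n = int(d.notna().sum())
        if n < min_n:
            skipped[var] = f"n={n} < {min_n}"
            continue
        maf = float(d.mean() / 2)
        maf = min(maf, 1 - maf)
        if d.nunique() < 2:
            skipped[var] = "monomorphic"
            continue
        if maf < maf_min:
            skipped[var] = f"maf={maf:.4g} below floor"
            continue
        X = pd.DataFrame({"dosage": d})
        if covariates is not None:
            X = pd.concat([X, covariates], axis=1)
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            skipped[var] = "singular design"
            continue
        fit = sm.OLS(y, X, missing="drop").fit()
        rows.append(
            AssocResult(
                var, n, float(fit.params["dosage"]), float(fit.bse["dosage"]),
                float(fit.pvalues["dosage"]), np.nan, maf,
            )
        )
    for var, why in skipped.items():
        logger.info("gwas_glm: skipped %s (%s)", var, why)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df, skipped


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    df: float | tuple
    per_comparison: pd.DataFrame | None = None  # Dunnett-adjusted p per group


def group_compare(
    values,
    groups=None,
    test: str = "unpaired_t",
    mu0: float | None = None,
    control: str | None = None,
) -> GroupComparison:
    """Standard group comparisons used for phenotype contrasts.

    ``unpaired_t``: two groups, two-sided Student t. ``one_sample_t``: all
    values against a reference mean ``mu0`` (the rare-carrier comparison).
    ``anova_dunnett``: one-way ANOVA over >= 3 groups plus Dunnett-adjusted
    per-group comparisons against ``control`` (default: first group label).
    """
    if test == "one_sample_t":
        if mu0 is None:
            raise ValueError("one_sample_t requires mu0")
        v = np.asarray(values, dtype=float)
        res = stats.ttest_1samp(v, popmean=mu0)
        return GroupComparison(test, float(res.statistic), float(res.pvalue), len(v) - 1)

    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(list(groups))
    by = {label: s[g.values == label].to_numpy() for label in pd.unique(g)}
    if len(by) < 2:
        raise ValueError("need >= 2 groups")
    if test == "unpaired_t":
        if len(by) != 2:
            raise ValueError("unpaired_t needs exactly 2 groups")
        a, b = by.values()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 values")
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison(test, float(res.statistic), float(res.pvalue), len(a) + len(b) - 2)
    if test == "anova_dunnett":
        labels = list(by)
        ctrl = control if control is not None else labels[0]
        if ctrl not in by:
            raise ValueError(f"control group {ctrl!r} not present")
        f = stats.f_oneway(*by.values())
        others = [l for l in labels if l != ctrl]
        dn = stats.dunnett(*[by[l] for l in others], control=by[ctrl])
        per = pd.DataFrame(
            {"group": others, "statistic": dn.statistic, "p_adjusted": dn.pvalue}
        )
        dfs = (len(by) - 1, sum(len(v) for v in by.values()) - len(by))
        return GroupComparison(test, float(f.statistic), float(f.pvalue), dfs, per)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class SurvivalResult:
    """KM curves per group plus the log-rank comparison."""

    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival)
    chi2: float
    p: float
    df: int


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier transfusion-free survival per group with a log-rank test.

    ``times`` are ages at first transfusion (or censoring), ``events`` the
    transfusion flags, ``groups`` the haplogroup labels. Requires >= 2
    groups and >= 1 event overall.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(list(groups))
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if e.sum() == 0:
        raise ValueError("no events")
    curves = {}
    for label in labels:
        kmf = KaplanMeierFitter()
        sel = g == label
        kmf.fit(t[sel], e[sel], label=str(label))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(label)] = sf
    res = multivariate_logrank_test(t, g, e)
    return SurvivalResult(curves, float(res.test_statistic), float(res.p_value), len(labels) - 1)


@dataclass
class BurdenResult:
    scores: pd.Series  # per-sample count of beneficial alleles
    beta: float
    se: float
    p: float
    missing: list[str] = field(default_factory=list)


def burden_score(
    sample_dosages: pd.DataFrame,
    beneficial_catalog: list[str],
    phenotype: pd.Series | None = None,
) -> BurdenResult:
    """Accumulated count of beneficial alleles per sample, with phenotype trend.

    The score sums the dosages of the catalogued beneficial variants; a
    catalog variant absent from the call set contributes 0 and is recorded.
    With a phenotype given, the trend is fit as phenotype ~ score by OLS.
    """
    import statsmodels.api as sm

    missing = [v for v in beneficial_catalog if v not in sample_dosages.columns]
    if missing:
        warnings.warn(f"burden_score: variants absent from call set: {missing}")
    present = [v for v in beneficial_catalog if v in sample_dosages.columns]
    scores = (
        sample_dosages[present].sum(axis=1)
        if present
        else pd.Series(0, index=sample_dosages.index)
    )
    beta = se = p = np.nan
    if phenotype is not None:
        idx = phenotype.dropna().index.intersection(scores.index)
        if scores.loc[idx].nunique() > 1:
            X = sm.add_constant(scores.loc[idx].astype(float).rename("score"))
            fit = sm.OLS(phenotype.loc[idx].astype(float), X).fit()
            beta, se, p = float(fit.params["score"]), float(fit.bse["score"]), float(fit.pvalues["score"])
    return BurdenResult(scores, beta, se, p, missing)
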