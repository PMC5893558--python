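"""Downstream expression statistics for candidate pleiotropy genes.

Four tests, all ordinary linear models fit with statsmodels:

* ``eqtl_ancova`` — additive-model ANCOVA eQTL test: expression regressed
  on genotype dosage (0/1/2 coded numerically) plus covariates; F test on
  the dosage term.
* ``group_de`` — case/control differential expression with brain region as
  a covariate when several regions are pooled.
* ``rm_anova_genotype_by_age`` — genotype effect across ages in transgenic
  mouse expression data. Because public mouse expression series are
  cross-sectional per age (different animals sacrificed at each time
  point), this is a two-way factorial ANOVA (genotype + age + interaction,
  Type II sums of squares) reporting the genotype main effect; with a
  single age level it degenerates to one-way ANOVA.
* ``marker_correlation`` — Pearson r^2 between two genes' expression with
  a two-sided p.

Expression values are assumed log-transformed upstream. Raw p-values are
reported by default; Benjamini–Hochberg adjustment is available as a flag
on the table-level driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression with per-sample covariates."""

    values: pd.DataFrame          # genes x samples
    covariates: pd.DataFrame      # samples x covariate columns
    log_scale: bool = True

    def __post_init__(self):
        if not self.values.columns.equals(self.covariates.index):
            self.covariates = self.covariates.loc[self.values.columns]
        if self.covariates.isna().any().any():
            raise ValueError("missing covariate values for modeled samples")

    def gene(self, name) -> np.ndarray:
        return self.values.loc[name].to_numpy(dtype=float)


def _fit_ols(y, frame, formula):
    model = ols(formula, data=frame.assign(_y=np.asarray(y, dtype=float))).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("singular design matrix: "
                         f"{formula} with {len(frame)} samples")
    return model


def eqtl_ancova(expr, dosage, covariates: pd.DataFrame | None = None):
    """Additive-model ANCOVA: F statistic and p for the dosage term.

    Dosage enters as a numeric 0/1/2 regressor (additive coding); an exact
    fit (residual variance ~ 0) is reported as (inf, 0.0).
    """
    expr = np.asarray(expr, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    frame = pd.DataFrame({"dosage": dosage})
    terms = ["dosage"]
    if covariates is not None:
        for c in covariates.columns:
            frame[c] = covariates[c].to_numpy()
            terms.append(f"C({c})" if covariates[c].dtype == object else c)
    if len(np.unique(dosage)) < 2:
        raise ValueError("dosage must take at least 2 distinct values")
    model = _fit_ols(expr, frame, "_y ~ " + " + ".join(terms))
    if model.ssr <= 1e-12 * max(model.centered_tss, 1.0):
        logger.warning("exact fit: residual variance ~ 0")
        return float("inf"), 0.0
    f = float(model.tvalues["dosage"] ** 2)
    return f, float(model.pvalues["dosage"])


def group_de(expr, diagnosis, region=None):
    """Case/control effect with optional brain-region covariate.

    Returns (effect on the model's expression scale, p for the diagnosis
    term). With a single region level the covariate is dropped and the
    test equals the pooled-variance two-sample t-test (t^2 = F).
    """
    expr = np.asarray(expr, dtype=float)
    diagnosis = pd.Categorical(diagnosis)
    if len(diagnosis.categories) != 2:
        raise ValueError("diagnosis must have exactly 2 levels")
    if min(pd.Series(diagnosis).value_counts()) == 0:
        raise ValueError("one diagnosis group is empty")
    frame = pd.DataFrame({"diagnosis": diagnosis})
    formula = "_y ~ C(diagnosis)"
    if region is not None and len(pd.unique(np.asarray(region))) > 1:
        frame["region"] = np.asarray(region)
        formula += " + C(region)"
    model = _fit_ols(expr, frame, formula)
    term = [t for t in model.params.index if t.startswith("C(diagnosis)")][0]
    return float(model.params[term]), float(model.pvalues[term])


def rm_anova_genotype_by_age(expr, genotype_group, age, subject=None):
    """Genotype main-effect F and p across age groups (factorial ANOVA).

    ``subject`` is accepted for interface compatibility with true
    repeated-measures layouts but unused: each animal contributes one
    sample in cross-sectional designs.
    """
    expr = np.asarray(expr, dtype=float)
    frame = pd.DataFrame({"genotype": np.asarray(genotype_group, dtype=object),
                          "age": np.asarray(age, dtype=object)})
    if frame.groupby("genotype").size().min() == 0 or frame["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotype levels with data")
    for g in frame["genotype"].unique():
        if frame.loc[frame["genotype"] == g].empty:
            raise ValueError(f"genotype level {g} absent at every age")
    if frame["age"].nunique() == 1:
        model = _fit_ols(expr, frame, "_y ~ C(genotype)")
        tab = anova_lm(model, typ=2)
    else:
        model = _fit_ols(expr, frame, "_y ~ C(genotype) * C(age)")
        tab = anova_lm(model, typ=2)
    row = tab.loc["C(genotype)"]
    return float(row["F"]), float(row["PR(>F)"])


def marker_correlation(x, y):
    """Pearson r^2 between two genes with the two-sided p of the r test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r**2), float(p)


def expression_report(matrix: ExpressionMatrix, test: str = "group_de",
                      bh_adjust: bool = False, **kwargs) -> pd.DataFrame:
    """Per-gene test driver producing a genes x statistics table.

    ``test`` selects group_de (needs covariates diagnosis [+ region]),
    eqtl_ancova (needs genotype_dosage) or rm_anova (needs genotype_group
    and age). With multiple probes per gene (duplicated index), the first
    probe in sorted numerical order is reported.
    """
    values = matrix.values
    if values.index.duplicated().any():
        values = values.sort_index(kind="mergesort")
        values = values[~values.index.duplicated(keep="first")]
    cov = matrix.covariates
    rows = []
    for gene in values.index:
        y = values.loc[gene].to_numpy(dtype=float)
        if test == "group_de":
            eff, p = group_de(y, cov["diagnosis"], cov.get("region"))
            rows.append({"gene": gene, "effect": eff, "p": p})
        elif test == "eqtl_ancova":
            extra = cov.drop(columns=[c for c in ("genotype_dosage",) if c in cov])
            f, p = eqtl_ancova(y, cov["genotype_dosage"],
                               extra if len(extra.columns) else None)
            rows.append({"gene": gene, "F": f, "p": p})
        elif test == "rm_anova":
            f, p = rm_anova_genotype_by_age(y, cov["genotype_group"], cov["age"])
            rows.append({"gene": gene, "F": f, "p": p})
        else:
            raise ValueError(f"unknown test {test!r}")
    out = pd.DataFrame(rows).set_index("gene")
    if bh_adjust:
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
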