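"""Per-gene differential expression and pathway-level enrichment.

Case/control status is modelled per gene by logistic regression —
status ~ expression + age + sex + centre — and the reported p-value is
the Wald test of the expression coefficient, i.e. whether that gene's
expression carries information about diagnosis after covariate
adjustment. Expression is standardised per gene before fitting; the Wald
p-value is invariant to this affine rescaling and the fit is better
conditioned.

At the pathway level, the count k of significant genes among the n
measured pathway genes is compared against a Binomial(n, p0) null with
p0 = 0.05 by an exact one-sided upper-tail test, P(X >= k), computed by
direct summation of the probability mass. A small p says more pathway
genes were dysregulated than chance alone would mark significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DIAGNOSES = ("AD", "MCI", "control")


@dataclass
class ExpressionStudy:
    """Expression matrix (genes x samples, log-scale) with sample metadata.

    ``samples`` is indexed by sample id and carries columns ``diagnosis``
    (AD / MCI / control), ``age``, ``sex`` and ``centre``. Samples with a
    missing covariate are dropped at construction and counted in
    ``n_dropped_samples``; a missing diagnosis is an error.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    n_dropped_samples: int = 0

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples.index):
            if set(self.expression.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample sheet disagree")
            self.samples = self.samples.loc[self.expression.columns]
        if self.samples["diagnosis"].isna().any():
            raise ValueError("missing diagnosis labels")
        unknown = set(self.samples["diagnosis"]) - set(DIAGNOSES)
        if unknown:
            raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
        covars = self.samples[["age", "sex", "centre"]]
        bad = covars.isna().any(axis=1)
        if bad.any():
            keep = self.samples.index[~bad]
            self.samples = self.samples.loc[keep]
            self.expression = self.expression[keep]
            self.n_dropped_samples += int(bad.sum())
            warnings.warn(
                f"dropped {int(bad.sum())} sample(s) with missing covariates",
                stacklevel=2,
            )

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def group_sizes(self) -> pd.Series:
        return self.samples["diagnosis"].value_counts()


@dataclass
class GeneGLMResult:
    """Wald test of the expression term for one gene."""

    gene: str
    coef: float
    se: float
    p_value: float
    comparison: str
    flag: str = ""  # "", "zero_variance", "separation", "non_converged"

    @property
    def ok(self) -> bool:
        return self.flag == ""


def per_gene_glm(
    study: ExpressionStudy,
    comparison: tuple[str, str] = ("AD", "control"),
    genes: Sequence[str] | None = None,
) -> list[GeneGLMResult]:
    """Fit the per-gene logistic model for one two-group comparison.

    ``comparison`` names (group1, group2); group1 is coded 1. Covariates
    are age (linear), sex and centre (categorical; centre omitted when the
    study is single-centre). Genes with zero expression variance, perfect
    separation or a non-converged fit are flagged with p = NaN rather than
    dropped.
    """
    g1, g2 = comparison
    label = f"{g1}-vs-{g2}"
    mask = study.samples["diagnosis"].isin([g1, g2])
    meta = study.samples[mask]
    if (meta["diagnosis"] == g1).sum() < 2 or (meta["diagnosis"] == g2).sum() < 2:
        raise ValueError(f"need >=2 samples per group for {label}")
    y = (meta["diagnosis"] == g1).to_numpy(dtype=float)

    covar_cols = [np.ones(len(meta)), meta["age"].to_numpy(dtype=float)]
    names = ["const", "age"]
    sex_levels = sorted(map(str, meta["sex"].unique()))
    for lvl in sex_levels[1:]:
        covar_cols.append((meta["sex"].astype(str) == lvl).to_numpy(dtype=float))
        names.append(f"sex[{lvl}]")
    centre_levels = sorted(map(str, meta["centre"].unique()))
    if len(centre_levels) > 1:
        for lvl in centre_levels[1:]:
            covar_cols.append(
                (meta["centre"].astype(str) == lvl).to_numpy(dtype=float)
            )
            names.append(f"centre[{lvl}]")
    base = np.column_stack(covar_cols)
    design = np.column_stack([np.zeros(len(meta)), base])  # slot 0: expression

    gene_list = list(genes) if genes is not None else list(study.genes)
    expr = study.expression.loc[gene_list, meta.index].to_numpy(dtype=float)

    results: list[GeneGLMResult] = []
    for row, gene in zip(expr, gene_list):
        sd = row.std()
        if sd == 0 or not np.isfinite(sd):
            results.append(
                GeneGLMResult(gene, np.nan, np.nan, np.nan, label, "zero_variance")
            )
            continue
        design[:, 0] = (row - row.mean()) / sd
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                results.append(
                    GeneGLMResult(gene, np.nan, np.nan, np.nan, label, "non_converged")
                )
                continue
            coef = float(fit.params[0])
            se = float(fit.bse[0])
            p = float(fit.pvalues[0])
            if not np.isfinite(p) or not np.isfinite(coef):
                results.append(
                    GeneGLMResult(gene, np.nan, np.nan, np.nan, label, "separation")
                )
                continue
            results.append(GeneGLMResult(gene, coef, se, p, label))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            results.append(
                GeneGLMResult(gene, np.nan, np.nan, np.nan, label, "separation")
            )
    return results


def results_to_frame(results: Iterable[GeneGLMResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "coef": [r.coef for r in results],
            "se": [r.se for r in results],
            "p": [r.p_value for r in results],
            "comparison": [r.comparison for r in results],
            "flag": [r.flag for r in results],
        }
    )


# ---------------------------------------------------------------------------
# pathway-level enrichment


def pathway_binomial_test(k: int, n: int, p0: float = 0.05) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= k), X~Bin(n, p0).

    Computed by direct summation of the binomial mass from k to n; no
    normal approximation is involved.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(stats.binom.pmf(np.arange(k, n + 1), n, p0).sum())


@dataclass
class PathwayEnrichmentResult:
    """Exact binomial enrichment of significant genes within a pathway."""

    pathway: str
    n_measured: int
    k_significant: int
    rule: str
    p0: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_significant <= self.n_measured:
            raise ValueError("k outside [0, n]")


def significance_rule(
    results: Iterable[GeneGLMResult],
    method: str = "raw",
    alpha: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Select significant genes by raw threshold, Bonferroni or BH-FDR.

    The correction family is the set of testable (unflagged) genes passed
    in. Returns the significant gene set plus a frame with adjusted
    p-values; flagged genes (p = NaN) are never significant.
    """
    res = list(results)
    frame = results_to_frame(res)
    ok = frame["p"].notna()
    p = frame.loc[ok, "p"].to_numpy()
    if method == "raw":
        adj = p
    elif method == "bonferroni":
        adj = np.minimum(1.0, p * len(p))
    elif method == "bh_fdr":
        adj = multipletests(p, method="fdr_bh")[1] if len(p) else p
    else:
        raise ValueError(f"unknown method {method!r}")
    frame["p_adj"] = np.nan
    frame.loc[ok, "p_adj"] = adj
    frame["significant"] = frame["p_adj"] < alpha
    frame["method"] = method
    sig = set(frame.loc[frame["significant"], "gene"])
    return sig, frame


def pathway_enrichment(
    results: Iterable[GeneGLMResult],
    pathway: str,
    method: str = "raw",
    alpha: float = 0.05,
    p0: float = 0.05,
) -> PathwayEnrichmentResult:
    """Binomial enrichment of a pathway's measured genes.

    ``results`` should already be restricted to the pathway's measured
    genes; k counts those significant under the chosen rule, and the
    binomial null proportion ``p0`` defaults to 0.05 independently of the
    rule.
    """
    res = list(results)
    sig, _ = significance_rule(res, method=method, alpha=alpha)
    n = len(res)
    k = len(sig)
    return PathwayEnrichmentResult(
        pathway, n, k, method, p0, pathway_binomial_test(k, n, p0)
    )


# ---------------------------------------------------------------------------
# cross-dataset operations


def cross_dataset_concordance(
    results_a: Iterable[GeneGLMResult],
    results_b: Iterable[GeneGLMResult],
) -> tuple[float, float, int]:
    """Spearman correlation of per-gene p-values across two studies.

    Computed over the intersection of genes with a valid p-value in both
    result sets; at least five shared genes are required. Returns
    (rho, p, n_shared).
    """
    pa = {r.gene: r.p_value for r in results_a if np.isfinite(r.p_value)}
    pb = {r.gene: r.p_value for r in results_b if np.isfinite(r.p_value)}
    shared = sorted(set(pa) & set(pb))
    if len(shared) < 5:
        raise ValueError(f"need >=5 shared genes, have {len(shared)}")
    rho, p = stats.spearmanr([pa[g] for g in shared], [pb[g] for g in shared])
    return float(rho), float(p), len(shared)


def merge_studies(
    studies: Sequence[ExpressionStudy],
    labels: Sequence[str] | None = None,
) -> ExpressionStudy:
    """Concatenate studies sample-wise on their gene intersection.

    The centre covariate of the merged study is prefixed with the study
    label so study-of-origin is absorbed by the centre term of the GLM.
    Sample ids are prefixed likewise to stay unique.
    """
    if not studies:
        raise ValueError("no studies to merge")
    if labels is None:
        labels = [f"S{i+1}" for i in range(len(studies))]
    genes = set(studies[0].genes)
    for s in studies[1:]:
        genes &= set(s.genes)
    if not genes:
        raise ValueError("empty gene intersection across studies")
    order = sorted(genes)
    expr_parts = []
    meta_parts = []
    for lab, s in zip(labels, studies):
        e = s.expression.loc[order].copy()
        e.columns = [f"{lab}:{c}" for c in e.columns]
        m = s.samples.copy()
        m.index = [f"{lab}:{c}" for c in m.index]
        m["centre"] = [f"{lab}:{c}" for c in m["centre"].astype(str)]
        expr_parts.append(e)
        meta_parts.append(m)
    return ExpressionStudy(
        pd.concat(expr_parts, axis=1), pd.concat(meta_parts, axis=0)
    )
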