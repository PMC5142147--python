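"""Downstream uses of gap calls in an association pipeline.

Three pieces: principal components computed from gap-probe betas (a
methylation-based surrogate for genotype PCs, usable for population-
stratification adjustment); a per-probe ordinary-least-squares scan of
methylation on a phenotype with covariates; and flag-don't-filter
reporting, where suggestive hits are annotated with gap / SNP flags
instead of being removed before analysis.

The scan is plain OLS with two-sided t-tests and Benjamini-Hochberg
q-values.  PCA centres probes but does not scale them: beta values
already share a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import BetaMatrix, GapCall, ValidationError

__all__ = ["gap_pcs", "EwasScan", "EwasResults", "flag_hits"]


def gap_pcs(
    beta: BetaMatrix,
    gap_ids: Sequence[str],
    k: int = 10,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples over the gap-probe submatrix.

    Returns ``(scores, explained_variance_ratio)`` with scores indexed by
    sample id, columns PC1..PCk.  Probes are mean-centred; missing betas
    are imputed with the probe mean before the decomposition.
    """
    gap_ids = list(gap_ids)
    if not gap_ids:
        raise ValidationError("gap_ids must be nonempty")
    k_max = min(beta.n_samples, len(gap_ids))
    if k > k_max:
        raise ValidationError(f"k={k} exceeds min(samples, gap probes)={k_max}")
    sub = beta.subset(gap_ids).data.to_numpy(dtype=float)
    # samples x probes
    X = sub.T
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X - col_mean
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, index=beta.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, pca.explained_variance_ratio_


class EwasScan:
    """Per-probe OLS of methylation on a phenotype with covariates.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    phenotype
        Numeric vector aligned with the beta matrix samples (or a Series
        indexed by sample id).
    covariates
        Optional samples x covariates matrix; an intercept is always
        added.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        phenotype,
        covariates: pd.DataFrame | np.ndarray | None = None,
    ):
        self.beta = beta
        n = beta.n_samples
        if isinstance(phenotype, pd.Series):
            phenotype = phenotype.reindex(beta.sample_ids).to_numpy()
        self.phenotype = np.asarray(phenotype, dtype=float)
        if self.phenotype.shape != (n,):
            raise ValidationError("phenotype length must match sample count")
        if np.isnan(self.phenotype).any():
            raise ValidationError("phenotype must be complete (no missing values)")
        if covariates is None:
            cov = np.empty((n, 0))
            cov_names: list[str] = []
        elif isinstance(covariates, pd.DataFrame):
            cov = covariates.reindex(beta.sample_ids).to_numpy(dtype=float)
            cov_names = list(covariates.columns)
        else:
            cov = np.asarray(covariates, dtype=float)
            cov_names = [f"x{i}" for i in range(cov.shape[1])]
        if cov.shape[0] != n:
            raise ValidationError("covariate rows must match sample count")
        X = np.column_stack([np.ones(n), self.phenotype, cov])
        self.exog_names = ["const", "phenotype", *cov_names]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name a collinear column: the first whose removal restores rank
            for j in range(X.shape[1]):
                keep = [c for c in range(X.shape[1]) if c != j]
                if np.linalg.matrix_rank(X[:, keep]) == rank:
                    raise ValidationError(
                        f"design matrix is rank deficient; column "
                        f"{self.exog_names[j]!r} is collinear"
                    )
            raise ValidationError("design matrix is rank deficient")
        self.design = X

    def fit(self) -> "EwasResults":
        """Fit all probes at once via the pseudoinverse of the shared design."""
        X = self.design
        n, p = X.shape
        Y = self.beta.values()  # probes x samples; NaN not supported in the scan
        if np.isnan(Y).any():
            raise ValidationError("ewas scan requires a complete beta matrix")
        pinv = np.linalg.pinv(X)
        coefs = Y @ pinv.T  # probes x p
        resid = Y - coefs @ X.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=1) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
        j = self.exog_names.index("phenotype")
        est, ses = coefs[:, j], se[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = est / ses
        pval = 2.0 * stats.t.sf(np.abs(tval), dof)
        pval = np.where(np.isnan(tval), 1.0, pval)
        qval = multipletests(pval, method="fdr_bh")[1]
        table = pd.DataFrame(
            {
                "estimate": est,
                "se": ses,
                "t": tval,
                "p": pval,
                "q": qval,
            },
            index=self.beta.probe_ids,
        )
        return EwasResults(self, table, dof)


@dataclass
class EwasResults:
    """Per-probe association estimates with flags attached on demand."""

    model: EwasScan
    table: pd.DataFrame
    dof: int
    flags: pd.DataFrame | None = field(default=None, repr=False)

    def attach_flags(
        self,
        gap_calls: Iterable[GapCall] = (),
        snp_annotated_ids: Iterable[str] = (),
    ) -> "EwasResults":
        calls = {c.probe_id: c for c in gap_calls}
        snp = set(snp_annotated_ids)
        idx = self.table.index
        self.flags = pd.DataFrame(
            {
                "is_gap": idx.isin(calls.keys()),
                "is_snp_annotated": idx.isin(snp),
                "is_outlier_driven": [
                    calls[p].outlier_driven if p in calls else False for p in idx
                ],
                "gap_group_sizes": [
                    ",".join(map(str, calls[p].group_sizes)) if p in calls else ""
                    for p in idx
                ],
            },
            index=idx,
        )
        return self

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p")
        lines = [
            "EWAS scan (OLS per probe)",
            "=========================",
            f"probes:    {len(t)}",
            f"samples:   {self.model.beta.n_samples}",
            f"covariates: {self.model.exog_names[2:] or 'none'}",
            f"residual dof: {self.dof}",
            "",
            t.head(top).to_string(float_format=lambda v: f"{v:.3e}"),
        ]
        return "\n".join(lines)


def flag_hits(
    result: EwasResults,
    p_cut: float = 1e-4,
    gap_calls: Iterable[GapCall] = (),
    snp_annotated_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Suggestive hits with gap / SNP flags attached — nothing removed.

    Returns every probe with p < ``p_cut`` (default 1e-4, the usual
    suggestive threshold), annotated with is_gap, is_snp_annotated,
    is_outlier_driven and the gap group sizes.
    """
    if not 0.0 < p_cut < 1.0:
        raise ValidationError(f"p_cut must be in (0, 1): {p_cut}")
    result.attach_flags(gap_calls, snp_annotated_ids)
    hits = result.table[result.table["p"] < p_cut].copy()
    out = hits.join(result.flags)
    return out.sort_values("p")
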