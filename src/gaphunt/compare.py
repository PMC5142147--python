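"""Baseline multimodality detectors and the benchmark harness.

Two generic alternatives to gap hunting are provided: a univariate
Gaussian mixture whose component count (1..k_max) is chosen by BIC, and
Hartigans' dip test of unimodality with a simulated null.  The benchmark
harness applies all methods to a synthetic dataset with known truth and
reports sensitivity, specificity, cluster-number accuracy, and the dip
AUC, optionally on the M-value scale as well.

The dip p-value is calibrated by Monte Carlo against ``b_null`` uniform
samples of the same size — the canonical null for the test (the uniform
is the least favourable unimodal distribution).  Tables are memoised per
(n, b_null, seed) because they depend on the data only through n.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._dip import dip_statistic
from .datatypes import BetaMatrix, ValidationError
from .gaphunter import GapHuntParams, beta_to_mvalues, gaphunter_matrix, mvalues_to_beta
from .simulate import SimTruth

__all__ = [
    "fit_gmm_1d",
    "dip_test",
    "roc_auc",
    "BenchmarkResult",
    "run_benchmark",
]


def fit_gmm_1d(
    values: np.ndarray,
    k_max: int = 6,
    n_init: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose a 1-D Gaussian mixture size by BIC.

    Fits unequal-variance mixtures with k = 1..k_max components and
    ``n_init`` seeded restarts each; returns ``(best_k, bic)`` where
    ``bic[k-1]`` is the BIC of the k-component fit (lower is better).
    A constant vector returns k = 1 by convention.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3 * k_max:
        raise ValidationError(f"need at least {3 * k_max} values for k_max={k_max}")
    if np.ptp(v) == 0.0:
        return 1, np.full(k_max, np.nan)
    X = v.reshape(-1, 1)
    bic = np.empty(k_max)
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
        ).fit(X)
        bic[k - 1] = gm.bic(X)
    return int(np.argmin(bic)) + 1, bic


@functools.lru_cache(maxsize=32)
def _null_dip_table(n: int, b_null: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(b_null)])


def dip_test(
    values: np.ndarray,
    b_null: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Hartigans' dip test of unimodality.

    Returns ``(dip, p_value)``; the p-value compares the observed dip to
    ``b_null`` dips of uniform samples of the same size, with the
    add-one correction ``(1 + #{null >= dip}) / (b_null + 1)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise ValidationError("dip_test needs at least 4 values")
    d = dip_statistic(v)
    null = _null_dip_table(int(v.size), int(b_null), int(seed))
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (b_null + 1.0)
    return float(d), float(p)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic,
    with ties contributing 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must contain both classes (0 and 1)")
    pos, neg = s[y == 1], s[y == 0]
    order = pd.Series(s).rank(method="average").to_numpy()
    r_pos = order[y == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class BenchmarkResult:
    """Detection metrics of each method on a labelled synthetic dataset."""

    scale: str  # "beta" or "mvalue"
    n_positive: int
    n_negative: int
    seed: int
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    cloud_calls: dict[str, int] = field(default_factory=dict)  # gap calls on clouds
    frame: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    def summary(self) -> str:
        lines = [
            f"Benchmark on {self.scale} scale "
            f"({self.n_positive} positives / {self.n_negative} negatives, seed {self.seed})",
            "-" * 72,
            f"{'method':<14}{'sensitivity':>12}{'specificity':>12}{'k accuracy':>12}{'AUC':>8}",
        ]
        for m, d in self.metrics.items():
            lines.append(
                f"{m:<14}"
                f"{d.get('sensitivity', float('nan')):>12.3f}"
                f"{d.get('specificity', float('nan')):>12.3f}"
                f"{d.get('cluster_accuracy', float('nan')):>12.3f}"
                f"{d.get('auc', float('nan')):>8.3f}"
            )
        if self.cloud_calls:
            lines.append(f"gap calls on cloud probes: {self.cloud_calls}")
        return "\n".join(lines)


def _subsample(ids: np.ndarray, limit: int | None, rng) -> np.ndarray:
    if limit is None or len(ids) <= limit:
        return ids
    return rng.choice(ids, size=limit, replace=False)


def run_benchmark(
    beta: BetaMatrix,
    truth: SimTruth,
    methods: tuple[str, ...] = ("gaphunter", "gmm", "dip"),
    params: GapHuntParams | None = None,
    scale: str = "beta",
    seed: int = 0,
    b_null: int = 500,
    max_probes_per_class: int | None = None,
) -> BenchmarkResult:
    """Benchmark detectors against ground truth.

    Positives are the true gap probes, negatives the flat probes; cloud
    and outlier probes are scored separately.  ``max_probes_per_class``
    subsamples positives/negatives for the per-probe methods (GMM, dip),
    which are orders of magnitude slower than gap hunting.

    On ``scale="mvalue"`` the GMM and dip run on logit2-transformed
    values (gap hunting itself stays on the beta scale by design).
    """
    if not methods:
        raise ValidationError("empty method set")
    params = params or GapHuntParams()
    rng = np.random.default_rng(seed)
    table = truth.table
    pos_ids = table.loc[table["probe_class"] == "gap", "probe_id"].to_numpy()
    neg_ids = table.loc[table["probe_class"] == "flat", "probe_id"].to_numpy()
    cloud_ids = set(table.loc[table["probe_class"] == "cloud", "probe_id"])
    result = BenchmarkResult(
        scale=scale, n_positive=len(pos_ids), n_negative=len(neg_ids), seed=seed
    )
    rows = []

    if "gaphunter" in methods:
        calls = {c.probe_id: c for c in gaphunter_matrix(beta, params)}
        sens = float(np.mean([pid in calls for pid in pos_ids])) if len(pos_ids) else np.nan
        spec = float(np.mean([pid not in calls for pid in neg_ids])) if len(neg_ids) else np.nan
        # cluster-number accuracy on true multi-cluster probes
        multi = table.loc[
            (table["probe_class"] == "gap") & (table["true_n_groups"] > 1), "probe_id"
        ]
        k_ok = [
            calls[pid].n_groups == int(table.loc[pid, "true_n_groups"])
            for pid in multi
            if pid in calls
        ]
        acc = float(np.mean(k_ok)) if k_ok else np.nan
        # per-sample group agreement over detected positives
        agree, total = 0, 0
        for pid in pos_ids:
            if pid not in calls or pid not in truth.sample_groups:
                continue
            lab = calls[pid].sample_groups
            tru = truth.sample_groups[pid]
            ok = ~np.isnan(lab)
            agree += int((lab[ok] == tru[ok]).sum())
            total += int(ok.sum())
        result.metrics["gaphunter"] = {
            "sensitivity": sens,
            "specificity": spec,
            "cluster_accuracy": acc,
            "group_agreement": agree / total if total else np.nan,
        }
        result.cloud_calls["gaphunter"] = sum(pid in calls for pid in cloud_ids)
        rows += [
            {"probe_id": pid, "method": "gaphunter", "called": pid in calls}
            for pid in np.concatenate([pos_ids, neg_ids])
        ]

    pos_sub = _subsample(pos_ids, max_probes_per_class, rng)
    neg_sub = _subsample(neg_ids, max_probes_per_class, rng)
    sub_ids = np.concatenate([pos_sub, neg_sub])
    sub_y = np.concatenate([np.ones(len(pos_sub)), np.zeros(len(neg_sub))]).astype(int)
    vals = beta.data.loc[sub_ids].to_numpy(dtype=float)
    if scale == "mvalue":
        vals = beta_to_mvalues(vals)
    elif scale != "beta":
        raise ValidationError(f"unknown scale: {scale!r}")

    if "gmm" in methods:
        best_k = np.array(
            [fit_gmm_1d(row, seed=seed)[0] for row in vals]
        )
        called = best_k > 1
        sens = float(called[sub_y == 1].mean()) if (sub_y == 1).any() else np.nan
        spec = float((~called[sub_y == 0]).mean()) if (sub_y == 0).any() else np.nan
        true_k = table.loc[sub_ids, "true_n_groups"].to_numpy(dtype=int)
        multi = (sub_y == 1) & (true_k > 1) & called
        acc = float((best_k[multi] == true_k[multi]).mean()) if multi.any() else np.nan
        result.metrics["gmm"] = {
            "sensitivity": sens,
            "specificity": spec,
            "cluster_accuracy": acc,
        }
        rows += [
            {"probe_id": pid, "method": "gmm", "best_k": int(k)}
            for pid, k in zip(sub_ids, best_k)
        ]

    if "dip" in methods:
        stats = np.array([dip_test(row, b_null=b_null, seed=seed) for row in vals])
        dips, pvals = stats[:, 0], stats[:, 1]
        auc = roc_auc(-np.log10(pvals), sub_y)
        result.metrics["dip"] = {"auc": auc}
        rows += [
            {"probe_id": pid, "method": "dip", "dip": float(d), "p": float(p)}
            for pid, (d, p) in zip(sub_ids, stats)
        ]

    result.frame = pd.DataFrame(rows)
    return result
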