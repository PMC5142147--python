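"""Gap hunting: detection of discretely clustered beta-value distributions.

The procedure, per probe: sort the beta values, take consecutive pairwise
differences, and declare a gap wherever a difference strictly exceeds a
width ``threshold`` (default 0.05 on the beta scale).  A probe with one or
more gaps is a *gap signal* with ``n_groups = n_gaps + 1``; gap locations
classify samples into groups, numbered in ascending beta order.  Gap
signals whose non-largest groups together hold no more than a fraction
``out_cutoff`` of the samples (default 0.01) are *outlier-driven* and are
dropped from the output unless explicitly retained.

The scan runs on the beta scale by design: a gap width in beta units maps
directly onto biological intuition about methylation differences, which an
M-value threshold does not.

Boundary conventions (deliberate, covered by tests): a consecutive
difference exactly equal to ``threshold`` is NOT a gap; the outlier rule
uses a non-strict comparison ("does not exceed"), so a non-largest mass
exactly equal to ``out_cutoff * n`` is outlier-driven.  When several groups
tie for largest, the largest count is subtracted once.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, GapCall, ValidationError
from . import io as _io

__all__ = [
    "GapHuntParams",
    "find_gaps",
    "assign_groups",
    "is_outlier_driven",
    "gaphunter_matrix",
    "mvalues_to_beta",
    "beta_to_mvalues",
    "GapHunter",
    "GapHuntResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GapHuntParams:
    """Tuning parameters of the gap-hunting scan.

    threshold
        Minimum empty interval width (beta units) that counts as a gap.
    out_cutoff
        Fraction of the per-probe sample size at or below which the
        non-largest groups mark a call as outlier-driven.
    keep_outlier_driven
        Retain outlier-driven calls (flagged) instead of dropping them.
    min_samples
        Minimum number of non-missing beta values required to scan a probe.
    """

    threshold: float = 0.05
    out_cutoff: float = 0.01
    keep_outlier_driven: bool = False
    min_samples: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold must be in (0, 1): {self.threshold}")
        if not 0.0 < self.out_cutoff < 1.0:
            raise ValidationError(f"out_cutoff must be in (0, 1): {self.out_cutoff}")
        if self.min_samples < 2:
            raise ValidationError("min_samples must be >= 2")


def find_gaps(
    values: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Locate gaps in a vector of beta values.

    Returns ``(gap_indices, cutpoints)`` where index ``i`` means a gap
    between sorted values ``i`` and ``i + 1`` (0-based) and each cutpoint
    is the midpoint of the two flanking values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("find_gaps needs a 1-D vector of length >= 2")
    if np.isnan(v).any():
        raise ValidationError("find_gaps requires non-missing values")
    s = np.sort(v)
    diffs = np.diff(s)
    idx = np.flatnonzero(diffs > threshold)
    cutpoints = (s[idx] + s[idx + 1]) / 2.0
    return idx, cutpoints


def assign_groups(
    values: np.ndarray, threshold: float, min_samples: int = 10
) -> tuple[np.ndarray, tuple[int, ...], tuple[float, ...]]:
    """Classify samples into gap-delimited groups.

    Returns ``(labels, group_sizes, cutpoints)``; labels run 1..k in
    ascending beta order, missing inputs get NaN labels and are excluded
    from the sizes.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if obs.sum() < min_samples:
        raise ValidationError(
            f"fewer than min_samples={min_samples} non-missing values ({obs.sum()})"
        )
    _, cutpoints = find_gaps(v[obs], threshold)
    labels = np.full(v.shape, np.nan)
    # searchsorted over cutpoints: values below the first cutpoint -> group 1
    labels[obs] = np.searchsorted(cutpoints, v[obs]) + 1.0
    k = len(cutpoints) + 1
    sizes = tuple(int((labels == g).sum()) for g in range(1, k + 1))
    return labels, sizes, tuple(float(c) for c in cutpoints)


def is_outlier_driven(
    group_sizes: tuple[int, ...] | list[int], out_cutoff: float, n: int | None = None
) -> bool:
    """True when all groups except the (single) largest together contain no
    more than ``out_cutoff * n`` samples."""
    sizes = list(group_sizes)
    if not sizes:
        raise ValidationError("group_sizes must be nonempty")
    if n is None:
        n = sum(sizes)
    rest = sum(sizes) - max(sizes)  # largest group subtracted once
    return rest <= out_cutoff * n


def gaphunter_matrix(
    beta: BetaMatrix, params: GapHuntParams | None = None
) -> list[GapCall]:
    """Run the gap-hunting scan over every probe of a beta matrix.

    Returns one :class:`GapCall` per probe with at least one gap.
    Outlier-driven calls are dropped unless ``params.keep_outlier_driven``,
    in which case they are retained with the flag set.  Probes with fewer
    than ``params.min_samples`` non-missing values are skipped with a
    logged reason.
    """
    params = params or GapHuntParams()
    if beta.n_probes == 0:
        logger.warning("gap hunting on an empty beta matrix")
        return []
    calls: list[GapCall] = []
    skipped = 0
    vals = beta.values()
    for i, probe_id in enumerate(beta.probe_ids):
        row = vals[i]
        obs = ~np.isnan(row)
        n_obs = int(obs.sum())
        if n_obs < params.min_samples:
            logger.info("probe %s skipped: %d non-missing values", probe_id, n_obs)
            skipped += 1
            continue
        labels, sizes, cutpoints = assign_groups(
            row, params.threshold, params.min_samples
        )
        if len(sizes) == 1:
            continue  # non-gap signal
        outlier = is_outlier_driven(sizes, params.out_cutoff, n_obs)
        if outlier and not params.keep_outlier_driven:
            continue
        calls.append(
            GapCall(
                probe_id=probe_id,
                n_groups=len(sizes),
                group_sizes=sizes,
                cutpoints=cutpoints,
                sample_groups=labels,
                outlier_driven=outlier,
            )
        )
    by_groups = Counter(c.n_groups for c in calls)
    logger.info(
        "gap hunting: %d/%d probes called (%d skipped); groups: %s",
        len(calls),
        beta.n_probes,
        skipped,
        dict(sorted(by_groups.items())),
    )
    return calls


def mvalues_to_beta(m) -> np.ndarray | BetaMatrix:
    """Convert M-values to the beta scale: beta = 2^m / (2^m + 1).

    Accepts an array (returns an array strictly inside (0, 1)) or a
    probes x samples DataFrame (returns a :class:`BetaMatrix`).
    """
    is_frame = isinstance(m, pd.DataFrame)
    arr = m.to_numpy(dtype=float) if is_frame else np.asarray(m, dtype=float)
    if not np.isfinite(arr[~np.isnan(arr)]).all():
        raise ValidationError("M-values must be finite")
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-arr))  # = 2^m / (2^m + 1), overflow-safe
    if is_frame:
        return BetaMatrix(pd.DataFrame(beta, index=m.index, columns=m.columns))
    return beta


def beta_to_mvalues(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """logit2 transform with beta clamped to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


class GapHunter:
    """Gap-hunting scan of a beta matrix, in model / results form.

    Parameters
    ----------
    beta
        Validated :class:`~gaphunt.datatypes.BetaMatrix`.

    Examples
    --------
    >>> res = GapHunter(beta).fit(threshold=0.05, out_cutoff=0.01)
    >>> res.gap_ids
    """

    def __init__(self, beta: BetaMatrix):
        self.beta = beta

    @classmethod
    def from_tsv(cls, path, missing_token: str = "NA") -> "GapHunter":
        return cls(_io.read_beta_matrix(path, missing_token))

    @classmethod
    def from_mvalues(cls, m: pd.DataFrame) -> "GapHunter":
        return cls(mvalues_to_beta(m))

    def fit(self, params: GapHuntParams | None = None, **kwargs) -> "GapHuntResults":
        """Run the scan; keyword arguments override :class:`GapHuntParams`
        fields (threshold, out_cutoff, keep_outlier_driven, min_samples)."""
        if params is None:
            params = GapHuntParams(**kwargs)
        elif kwargs:
            raise ValidationError("pass either params or keyword overrides, not both")
        calls = gaphunter_matrix(self.beta, params)
        return GapHuntResults(self, params, calls)


@dataclass
class GapHuntResults:
    """Results of a gap-hunting scan."""

    model: GapHunter
    params: GapHuntParams
    calls: list[GapCall] = field(repr=False)

    @property
    def gap_ids(self) -> list[str]:
        return [c.probe_id for c in self.calls]

    @property
    def n_gap_probes(self) -> int:
        return len(self.calls)

    def call_for(self, probe_id: str) -> GapCall:
        for c in self.calls:
            if c.probe_id == probe_id:
                return c
        raise KeyError(probe_id)

    def group_counts(self) -> pd.Series:
        """Number of gap probes by group count."""
        counts = Counter(c.n_groups for c in self.calls)
        return pd.Series(dict(sorted(counts.items())), dtype=int, name="n_probes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [c.probe_id for c in self.calls],
                "n_groups": [c.n_groups for c in self.calls],
                "group_sizes": [",".join(map(str, c.group_sizes)) for c in self.calls],
                "cutpoints": [
                    ",".join(f"{x:.6f}" for x in c.cutpoints) for c in self.calls
                ],
                "outlier_driven": [int(c.outlier_driven) for c in self.calls],
            }
        )

    def sample_group_frame(self) -> pd.DataFrame:
        """Gap probes x samples matrix of group labels (NaN = missing beta)."""
        return pd.DataFrame(
            {c.probe_id: c.sample_groups for c in self.calls},
            index=self.model.beta.sample_ids,
        ).T

    def save(self, path, labels_path=None) -> str:
        return _io.write_gap_calls(
            self.calls, path, sample_ids=list(self.model.beta.sample_ids),
            labels_path=labels_path,
        )

    def summary(self) -> str:
        lines = [
            "Gap hunting results",
            "===================",
            f"probes scanned:      {self.model.beta.n_probes}",
            f"samples:             {self.model.beta.n_samples}",
            f"threshold:           {self.params.threshold}",
            f"out_cutoff:          {self.params.out_cutoff}",
            f"keep_outlier_driven: {self.params.keep_outlier_driven}",
            f"gap probes:          {self.n_gap_probes}",
            "",
            "groups  probes",
        ]
        for k, v in self.group_counts().items():
            lines.append(f"{k:>6}  {v}")
        n_out = sum(c.outlier_driven for c in self.calls)
        if self.params.keep_outlier_driven:
            lines.append(f"\noutlier-driven (retained): {n_out}")
        return "\n".join(lines)

    def plot_probe(self, probe_id: str, ax=None):
        """Strip plot of one probe's beta values coloured by group."""
        import matplotlib.pyplot as plt

        call = self.call_for(probe_id)
        vals = self.model.beta.data.loc[probe_id].to_numpy(dtype=float)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        rng = np.random.default_rng(0)
        jitter = rng.uniform(-0.2, 0.2, size=len(vals))
        ax.scatter(jitter, vals, c=call.sample_groups, cmap="viridis", s=12)
        for cp in call.cutpoints:
            ax.axhline(cp, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("beta")
        ax.set_xticks([])
        ax.set_title(f"{probe_id}: {call.n_groups} groups")
        return ax
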