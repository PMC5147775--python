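"""Reusable statistics for the non-4C quantifications.

Three small tools: a two-sample t-test computed from printed group
summaries (mean, sd, n) rather than raw data, a Mann-Whitney U test for
per-cell spot counts with an exact enumeration mode, and the delta-delta-Ct
fold change for relative qPCR quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError, InputError

EXACT_CAP = 16  # combined sample size cap for exact Mann-Whitney enumeration


@dataclass(frozen=True)
class GroupSummary:
    """Printed group statistics: mean +/- sd with sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputError("sd must be >= 0")
        if self.n < 2:
            raise InputError("group size must be >= 2")


@dataclass(frozen=True)
class SpotCountSample:
    """Per-cell nonnegative integer spot counts for one condition."""

    label: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise InputError("empty spot-count sample")
        if any(c < 0 for c in self.counts):
            raise InputError("spot counts must be >= 0")


@dataclass(frozen=True)
class CtQuartet:
    """Ct replicate lists for target/reference genes in treated/control cells."""

    target_treated: tuple[float, ...]
    reference_treated: tuple[float, ...]
    target_control: tuple[float, ...]
    reference_control: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in (
            "target_treated",
            "reference_treated",
            "target_control",
            "reference_control",
        ):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise InputError(f"missing Ct replicates for {name}")
            if any(v <= 0 for v in vals):
                raise InputError(f"Ct values must be positive ({name})")


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled", tails: int = 2
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, p).

    ``variant="pooled"`` uses the pooled-variance statistic with
    ``df = n_a + n_b - 2``; ``"welch"`` uses the Welch-Satterthwaite
    approximation.  One-tailed p is for the observed direction.
    """
    if variant not in ("pooled", "welch"):
        raise InputError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if tails not in (1, 2):
        raise InputError("tails must be 1 or 2")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    if tails == 1:
        p = p / 2.0
    return float(t), float(df), float(p)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    a: SpotCountSample, b: SpotCountSample, mode: str = "normal"
) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p; returns (U of sample a, p).

    ``mode="exact"`` enumerates every assignment of the pooled values to
    the two groups (allowed up to combined n of 16; ties handled through
    midranks) and reports ``2 * min(tail probabilities)`` capped at 1.
    ``mode="normal"`` uses the tie-corrected normal approximation with a
    continuity correction clamped at the mean, so identical samples give
    p = 1 exactly.
    """
    if mode not in ("exact", "normal"):
        raise InputError(f"mode must be 'exact' or 'normal', got {mode!r}")
    x = np.asarray(a.counts, dtype=float)
    y = np.asarray(b.counts, dtype=float)
    n_a, n_b = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a)

    if mode == "exact":
        n_total = n_a + n_b
        if n_total > EXACT_CAP:
            raise CapacityError(
                f"exact mode limited to combined n <= {EXACT_CAP}, got {n_total}"
            )
        us = np.array(
            [
                _u_statistic(ranks[list(pick)], n_a)
                for pick in combinations(range(n_total), n_a)
            ]
        )
        eps = 1e-9
        p_low = np.mean(us <= u_obs + eps)
        p_high = np.mean(us >= u_obs - eps)
        return u_obs, float(min(1.0, 2.0 * min(p_low, p_high)))

    mu = n_a * n_b / 2.0
    n_total = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n_total * (n_total - 1))
    sigma2 = n_a * n_b / 12.0 * ((n_total + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    # continuity correction toward the mean; exact at U = mu (p = 1)
    z = max(0.0, abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return u_obs, float(min(1.0, 2.0 * stats.norm.sf(z)))


def ddct_fold_change(q: CtQuartet) -> float:
    """Relative qPCR quantification: fold change 2 ** (-ddCt).

    Replicate Cts are averaged first; ddCt is the treated target-minus-
    reference delta minus the control delta.
    """
    d_treated = float(np.mean(q.target_treated)) - float(np.mean(q.reference_treated))
    d_control = float(np.mean(q.target_control)) - float(np.mean(q.reference_control))
    return float(2.0 ** (-(d_treated - d_control)))


# -- CSV interfaces ------------------------------------------------------


def read_group_summaries(path) -> dict[str, GroupSummary]:
    """CSV with columns label, mean, sd, n."""
    df = pd.read_csv(path)
    return {
        str(r.label): GroupSummary(str(r.label), float(r.mean), float(r.sd), int(r.n))
        for r in df.itertuples(index=False)
    }


def read_spot_counts(path) -> dict[str, SpotCountSample]:
    """CSV with columns condition, count: one row per cell."""
    df = pd.read_csv(path)
    return {
        str(label): SpotCountSample(str(label), tuple(int(c) for c in grp["count"]))
        for label, grp in df.groupby("condition", sort=True)
    }


def read_ct_table(path, treated: str, control: str) -> CtQuartet:
    """CSV with columns condition, gene_class (target/reference), ct."""
    df = pd.read_csv(path)

    def pick(cond, cls):
        sel = df[(df["condition"] == cond) & (df["gene_class"] == cls)]["ct"]
        return tuple(float(v) for v in sel)

    return CtQuartet(
        target_treated=pick(treated, "target"),
        reference_treated=pick(treated, "reference"),
        target_control=pick(control, "target"),
        reference_control=pick(control, "reference"),
    )
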