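"""Window-level differential contact analysis between two conditions.

Coverage normalization scales one library's per-fragment counts so both
totals match; window means are plain arithmetic means of (normalized)
counts over a window's fragments.  Significance is a Pearson chi-square on
the 2x2 table of raw in-window vs out-of-window unique ligation totals,
which embodies the same total-coverage normalization through its margins
without breaking countness.  The out-of-window complement is the analyzed
cis region minus the window and the bait exclusion zone (exclusion-zone
fragments carry zero counts, so the complement is simply ``N - in``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, InputError
from .fragment_map import FragmentMap
from .ligation import ContactProfile


@dataclass(frozen=True)
class WindowSpec:
    """A named analysis window: anchor coordinate plus width in fragments."""

    name: str
    anchor: int
    width: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise InputError(f"window {self.name!r}: width must be >= 1")

    def resolve(self, fmap: FragmentMap) -> tuple[int, int]:
        """Half-open fragment-index range of this window on ``fmap``."""
        try:
            return fmap.window_around(self.anchor, self.width)
        except (InputError, ConfigError) as exc:
            raise ConfigError(f"window {self.name!r} unresolvable: {exc}") from exc


@dataclass
class NormalizedPair:
    """Two profiles brought to a common total; raw counts retained."""

    a: np.ndarray
    b: np.ndarray
    profile_a: ContactProfile
    profile_b: ContactProfile


@dataclass
class DifferentialResult:
    window: WindowSpec
    condition_a: str
    condition_b: str
    raw_in_a: int
    raw_out_a: int
    raw_in_b: int
    raw_out_b: int
    mean_a: float
    mean_b: float
    chi2: float
    dof: int
    pvalue: float
    percent_change: float
    tier: str
    low_count: bool = False


def _check_pair(profile_a: ContactProfile, profile_b: ContactProfile) -> None:
    if profile_a.fmap != profile_b.fmap:
        raise InputError("profiles are on different fragment maps")


def normalize_totals(profile_a: ContactProfile, profile_b: ContactProfile) -> NormalizedPair:
    """Scale profile B's counts by ``N_A / N_B`` so both totals equal ``N_A``."""
    _check_pair(profile_a, profile_b)
    if profile_a.n == 0 or profile_b.n == 0:
        raise InputError("cannot normalize a zero-total profile")
    scale = profile_a.n / profile_b.n
    return NormalizedPair(
        a=profile_a.counts.astype(float),
        b=profile_b.counts.astype(float) * scale,
        profile_a=profile_a,
        profile_b=profile_b,
    )


def window_mean(counts, window: WindowSpec, fmap: FragmentMap) -> float:
    """Arithmetic mean of counts per fragment over the window."""
    if isinstance(counts, ContactProfile):
        fmap = counts.fmap
        counts = counts.counts
    lo, hi = window.resolve(fmap)
    return float(np.mean(np.asarray(counts, dtype=float)[lo:hi]))


def percent_change(
    profile_a: ContactProfile, profile_b: ContactProfile, window: WindowSpec
) -> float:
    """100 * (mean_A - mean_B) / mean_B on coverage-normalized window means."""
    pair = normalize_totals(profile_a, profile_b)
    mean_a = window_mean(pair.a, window, profile_a.fmap)
    mean_b = window_mean(pair.b, window, profile_a.fmap)
    if mean_b == 0:
        raise InputError(f"window {window.name!r}: zero reference mean, change undefined")
    return 100.0 * (mean_a - mean_b) / mean_b


def _tier(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def chisq_window_test(
    profile_a: ContactProfile,
    profile_b: ContactProfile,
    window: WindowSpec,
    yates: bool = False,
) -> DifferentialResult:
    """Pearson chi-square (df = 1) on raw in-window vs out-of-window totals.

    Yates continuity correction is off by default: window totals here are
    in the thousands, where the correction is negligible and the
    uncorrected statistic matches the hand formula sum((O - E)^2 / E).
    """
    _check_pair(profile_a, profile_b)
    fmap = profile_a.fmap
    lo, hi = window.resolve(fmap)
    in_a = int(profile_a.counts[lo:hi].sum())
    in_b = int(profile_b.counts[lo:hi].sum())
    out_a = profile_a.n - in_a
    out_b = profile_b.n - in_b
    table = np.array([[in_a, out_a], [in_b, out_b]], dtype=np.int64)

    low_count = False
    if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
        low_count = True
    else:
        res = stats.chi2_contingency(table, correction=yates)
        chi2, p = float(res.statistic), float(res.pvalue)
        low_count = bool((res.expected_freq < 1).any())
        if chi2 == 0.0:
            p = 1.0

    pair = normalize_totals(profile_a, profile_b)
    mean_a = window_mean(pair.a, window, fmap)
    mean_b = window_mean(pair.b, window, fmap)
    pct = 100.0 * (mean_a - mean_b) / mean_b if mean_b > 0 else float("nan")
    return DifferentialResult(
        window=window,
        condition_a=profile_a.condition,
        condition_b=profile_b.condition,
        raw_in_a=in_a,
        raw_out_a=out_a,
        raw_in_b=in_b,
        raw_out_b=out_b,
        mean_a=mean_a,
        mean_b=mean_b,
        chi2=chi2,
        dof=1,
        pvalue=p,
        percent_change=pct,
        tier=_tier(p),
        low_count=low_count,
    )


def pairwise_panel(
    profiles: dict[str, ContactProfile],
    windows: dict[str, WindowSpec],
    plan: list[tuple[str, str, list[str]]],
    yates: bool = False,
) -> list[DifferentialResult]:
    """Run one chi-square comparison per (condition pair, window) in the plan.

    ``plan`` entries are ``(condition_a, condition_b, [window names])``.
    All profiles must share a fragment map and viewpoint.
    """
    results = []
    for cond_a, cond_b, window_names in plan:
        for cond in (cond_a, cond_b):
            if cond not in profiles:
                raise ConfigError(f"unknown condition {cond!r} in comparison plan")
        for wname in window_names:
            if wname not in windows:
                raise ConfigError(f"unknown window {wname!r} in comparison plan")
            results.append(
                chisq_window_test(
                    profiles[cond_a], profiles[cond_b], windows[wname], yates=yates
                )
            )
    return results


def panel_to_frame(results: list[DifferentialResult]):
    """Tabulate panel results (one row per comparison) for TSV/JSON export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "window": r.window.name,
                "condition_a": r.condition_a,
                "condition_b": r.condition_b,
                "raw_in_a": r.raw_in_a,
                "raw_out_a": r.raw_out_a,
                "raw_in_b": r.raw_in_b,
                "raw_out_b": r.raw_out_b,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "chi2": r.chi2,
                "dof": r.dof,
                "pvalue": r.pvalue,
                "percent_change": r.percent_change,
                "tier": r.tier,
                "low_count": r.low_count,
            }
            for r in results
        ]
    )
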