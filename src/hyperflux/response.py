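"""Treatment-response statistics over fitted cohorts.

Per-group mean ± s.d. summaries, percent and fold changes versus the
untreated group, exact Mann–Whitney rank-sum comparisons (full enumeration
at the small group sizes typical of these experiments), and the linear
necrosis–k_F correlation.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortSample, gate_events
from .model import PeakSeries, TwoSiteExchangeModel, normalise_series

__all__ = [
    "GroupSummary",
    "RankSumResult",
    "percent_change",
    "fold_change",
    "rank_sum_test",
    "linear_r2",
    "fit_cohort",
    "build_report",
    "CohortReport",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    values: tuple[float, ...]

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = tuple(float(x) for x in values)
        arr = np.asarray(v)
        return cls(
            label=label,
            n=len(v),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(v) > 1 else 0.0,
            values=v,
        )


def percent_change(baseline: float, followup: float) -> float:
    """Percent decrease from baseline: 100·(baseline − followup)/baseline.

    Positive for a decrease; round to the nearest integer for reporting.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (baseline - followup) / baseline


def fold_change(baseline: float, followup: float) -> float:
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return followup / baseline


@dataclass(frozen=True)
class RankSumResult:
    u: float
    p_value: float
    significant: bool
    method: str


def _values(group) -> np.ndarray:
    if isinstance(group, GroupSummary):
        return np.asarray(group.values, dtype=float)
    return np.asarray(list(group), dtype=float)


def rank_sum_test(a, b, exact_limit: int = 12) -> RankSumResult:
    """Two-sided Mann–Whitney U test.

    For ``n_a + n_b <= exact_limit`` the permutation distribution of U is
    enumerated in full over all C(n, n_a) group assignments of the pooled
    mid-ranks, so ties are handled exactly; the two-sided p-value uses the
    symmetry of that distribution about n_a·n_b/2.  Larger samples fall
    back to the normal approximation with tie correction and continuity
    correction.  All-tied input gives p = 1.
    """
    x, y = _values(a), _values(b)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    offset = na * (na + 1) / 2.0
    u_obs = float(ranks[:na].sum() - offset)
    m = na * nb
    if na + nb <= exact_limit:
        u_all = np.array(
            [
                sum(ranks[i] for i in combo) - offset
                for combo in itertools.combinations(range(na + nb), na)
            ]
        )
        lo = min(u_obs, m - u_obs)
        hi = max(u_obs, m - u_obs)
        eps = 1e-9
        p = float(np.mean((u_all <= lo + eps) | (u_all >= hi - eps)))
        method = "exact"
    else:
        # normal approximation, tie-corrected variance, continuity correction
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        if var == 0:
            return RankSumResult(u=u_obs, p_value=1.0, significant=False, method="normal")
        z = (abs(u_obs - m / 2.0) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "normal"
    return RankSumResult(u=u_obs, p_value=p, significant=p < ALPHA, method=method)


def linear_r2(x, y) -> float:
    """Squared Pearson correlation."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


# -- cohort-level analysis -------------------------------------------------

_PAIR_METRIC = {"pyruvate_lactate": "k_P", "fumarate_malate": "k_F"}


def fit_cohort(
    samples: list[CohortSample],
    mode: str = "unidirectional",
    normalise: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every sample's trajectories; one row per (sample, substrate pair)."""
    rows = []
    for s in samples:
        for pair, traj in s.trajectories.items():
            series = PeakSeries.from_trajectory(traj)
            if normalise:
                series = normalise_series(series, s.cell_count)
            res = TwoSiteExchangeModel(series, s.scheme, mode=mode).fit(**fit_kwargs)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "timepoint_h": s.timepoint_h,
                    "metric": _PAIR_METRIC.get(pair, pair),
                    "k": res.k,
                    "k_se": res.k_se,
                    "residual_norm": res.residual_norm,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CohortReport:
    """Machine- and human-readable cohort comparison report."""

    groups: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    missing: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "comparisons": self.comparisons,
            "missing": self.missing,
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"{'group':<16}{'metric':<16}{'n':>3}{'mean':>13}{'sd':>13}",
            "-" * 61,
        ]
        for g in self.groups:
            lines.append(
                f"{g['label']:<16}{g['metric']:<16}{g['n']:>3}"
                f"{g['mean']:>13.4g}{g['sd']:>13.4g}"
            )
        lines.append("")
        lines.append(
            f"{'comparison':<28}{'metric':<16}{'%change':>9}{'fold':>8}{'p':>9}"
        )
        lines.append("-" * 70)
        for c in self.comparisons:
            pc = c["percent_change_rounded"]
            pc_s = f"{pc:d}" if pc is not None else "--"
            fold = c["fold_change"]
            fold_s = f"{fold:.2g}" if fold is not None else "--"
            lines.append(
                f"{c['label']:<28}{c['metric']:<16}{pc_s:>9}{fold_s:>8}"
                f"{c['p_value']:>9.3g}{' *' if c['significant'] else ''}"
            )
        if self.missing:
            lines.append("")
            lines.append("missing / not computable:")
            for m in self.missing:
                lines.append(f"  - {m['label']} {m['metric']}: {m['reason']}")
        return "\n".join(lines)


def _group_label(group: str, timepoint_h: float) -> str:
    return "untreated" if group == "untreated" else f"treated_{timepoint_h:g}h"


def build_report(
    samples: list[CohortSample],
    fits: pd.DataFrame | None = None,
    mode: str = "unidirectional",
) -> CohortReport:
    """Summarise fitted rate constants, gated fractions and NADH per group,
    with percent/fold changes and rank-sum p-values versus untreated.

    Metrics whose baseline is zero (e.g. k_F before necrosis appears) are
    listed under ``missing`` rather than silently dropped.
    """
    if fits is None:
        fits = fit_cohort(samples, mode=mode)
    groups = sorted(
        {(s.group, s.timepoint_h) for s in samples}, key=lambda g: (g[0] != "untreated", g[1])
    )
    if len(groups) < 2:
        raise ValueError("need at least two groups (untreated + treated)")
    if ("untreated",) not in {(g,) for g, _ in groups} and all(
        g != "untreated" for g, _ in groups
    ):
        raise ValueError("cohort has no untreated group to compare against")

    # collect per-sample metric values for each group
    metric_values: dict[tuple[str, float], dict[str, list[float]]] = {}
    for grp in groups:
        metric_values[grp] = {}
    for _, row in fits.iterrows():
        key = (row["group"], row["timepoint_h"])
        metric_values[key].setdefault(row["metric"], []).append(float(row["k"]))
    for s in samples:
        key = (s.group, s.timepoint_h)
        if s.events is not None:
            g = gate_events(s.events)
            for name, value in (
                ("viable_frac", g.viable),
                ("apoptotic_frac", g.apoptotic),
                ("necrotic_frac", g.necrotic),
            ):
                metric_values[key].setdefault(name, []).append(value)
            metric_values[key].setdefault("nadh_mean", []).append(
                float(s.events["nadh"].mean())
            )

    report = CohortReport()
    summaries: dict[tuple[str, float], dict[str, GroupSummary]] = {}
    for grp in groups:
        label = _group_label(*grp)
        summaries[grp] = {}
        for metric, values in sorted(metric_values[grp].items()):
            gs = GroupSummary.from_values(label, values)
            summaries[grp][metric] = gs
            report.groups.append(
                {
                    "label": label,
                    "metric": metric,
                    "n": gs.n,
                    "mean": gs.mean,
                    "sd": gs.sd,
                    "values": list(gs.values),
                }
            )

    baseline_grp = next(g for g in groups if g[0] == "untreated")
    for grp in groups:
        if grp == baseline_grp:
            continue
        label = _group_label(*grp)
        for metric, gs in sorted(summaries[grp].items()):
            base = summaries[baseline_grp].get(metric)
            if base is None:
                report.missing.append(
                    {"label": label, "metric": metric, "reason": "no untreated values"}
                )
                continue
            if base.mean <= 0:
                report.missing.append(
                    {
                        "label": label,
                        "metric": metric,
                        "reason": "untreated mean is zero; percent/fold change undefined",
                    }
                )
                continue
            pc = percent_change(base.mean, gs.mean)
            fc = fold_change(base.mean, gs.mean)
            try:
                rs = rank_sum_test(base, gs)
                p, sig = rs.p_value, rs.significant
            except ValueError:
                p, sig = float("nan"), False
            report.comparisons.append(
                {
                    "label": f"{label} vs untreated",
                    "metric": metric,
                    "percent_change": pc,
                    "percent_change_rounded": int(round(pc)),
                    "fold_change": fc,
                    "p_value": p,
                    "significant": sig,
                }
            )
    return report
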