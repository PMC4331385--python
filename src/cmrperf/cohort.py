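"""Territory aggregation, reduced-flow classification and comparison stats.

Per-segment flow estimates from the standardized 16-segment heart model are
pooled into the three coronary vessel territories (LAD, LCX, RCA). A
territory with mean hyperaemic flow below 2.5 mL/min/mL of tissue (strict
inequality) is classified as having reduced myocardial blood flow, the
threshold used in quantitative stress-perfusion studies. Detection counts
are tallied against angiographic groups: 1 = no/minor disease, 2 =
non-obstructive stenosis, 3 = obstructive stenosis; groups 2 and 3 together
are the stenotic vessels.

The statistical helpers wrap the classical tests used for method
comparison — paired t, Welch two-sample t, Fisher's variance-ratio F,
one-sample t (all two-sided) — plus Bland-Altman bias and limits of
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "SegmentRecord",
    "TerritorySummary",
    "StatsReport",
    "AHA16_TERRITORIES",
    "REDUCED_FLOW_THRESHOLD",
    "segment_territory_map",
    "territory_summary",
    "classify_reduced_flow",
    "detection_counts",
    "mpr",
    "paired_t",
    "welch_t",
    "f_variance",
    "one_sample_t",
    "bland_altman",
]

#: Default threshold for reduced hyperaemic flow, mL/min/mL of tissue.
REDUCED_FLOW_THRESHOLD = 2.5

#: AHA convention mapping the 16-segment model onto coronary territories.
AHA16_TERRITORIES: Dict[str, Tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "LCX": (5, 6, 11, 12, 16),
    "RCA": (3, 4, 9, 10, 15),
}


def segment_territory_map(
    territories: Optional[Mapping[str, Iterable[int]]] = None,
) -> Dict[int, str]:
    """Invert a territory->segments mapping into segment->territory."""
    territories = territories or AHA16_TERRITORIES
    out: Dict[int, str] = {}
    for name, segs in territories.items():
        for s in segs:
            if s in out:
                raise ValueError(f"segment {s} assigned to two territories")
            out[int(s)] = name
    missing = set(range(1, 17)) - set(out)
    if missing:
        raise ValueError(f"mapping does not cover segments {sorted(missing)}")
    return out


@dataclass(frozen=True)
class SegmentRecord:
    subject: str
    segment: int  # 1..16
    state: str  # "stress" | "rest"
    model: str  # "fermi" | "dp"
    bolus: str  # "single" | "dual"
    mbf: float  # mL/min/mL
    converged: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.segment <= 16):
            raise ValueError(f"segment must be in 1..16, got {self.segment}")
        if self.state not in ("stress", "rest"):
            raise ValueError(f"state must be stress|rest, got {self.state!r}")
        if self.converged and not self.mbf > 0:
            raise ValueError("converged record requires mbf > 0")


@dataclass
class TerritorySummary:
    territory: str  # LAD | LCX | RCA
    mean_mbf_stress: float
    sd_mbf_stress: float
    mean_mbf_rest: Optional[float] = None
    sd_mbf_rest: Optional[float] = None
    mpr_mean: Optional[float] = None
    mpr_sd: Optional[float] = None
    n_segments: int = 0
    group: Optional[int] = None  # angiographic group 1|2|3
    reduced_flow: bool = False
    subject: Optional[str] = None


@dataclass
class StatsReport:
    test: str
    statistic: float
    p_value: float
    n: int
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def classify_reduced_flow(
    mean_stress_mbf: float, threshold: float = REDUCED_FLOW_THRESHOLD
) -> bool:
    """True when mean hyperaemic flow is strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return mean_stress_mbf < threshold


def mpr(stress_mbf: float, rest_mbf: float) -> float:
    """Myocardial perfusion reserve: stress flow divided by rest flow."""
    if rest_mbf <= 0:
        raise ValueError(f"rest_mbf must be > 0, got {rest_mbf}")
    return stress_mbf / rest_mbf


def territory_summary(
    records: Sequence[SegmentRecord],
    mapping: Optional[Mapping[int, str]] = None,
    threshold: float = REDUCED_FLOW_THRESHOLD,
) -> List[TerritorySummary]:
    """Pool converged segment flows into per-subject coronary territories.

    Non-convergent segments are dropped before averaging. A territory left
    with no converged stress segment is excluded (with a warning via the
    return side: it simply does not appear). MPR statistics use per-segment
    stress/rest ratios where both states converged.
    """
    mapping = mapping or segment_territory_map()
    subjects = sorted({r.subject for r in records})
    out: List[TerritorySummary] = []
    for subj in subjects:
        for terr in ("LAD", "LCX", "RCA"):
            segs = [s for s, t in mapping.items() if t == terr]
            stress = [
                r.mbf for r in records
                if r.subject == subj and r.segment in segs
                and r.state == "stress" and r.converged
            ]
            rest = {
                r.segment: r.mbf for r in records
                if r.subject == subj and r.segment in segs
                and r.state == "rest" and r.converged
            }
            stress_by_seg = {
                r.segment: r.mbf for r in records
                if r.subject == subj and r.segment in segs
                and r.state == "stress" and r.converged
            }
            if not stress:
                continue
            ratios = [
                stress_by_seg[s] / rest[s]
                for s in stress_by_seg
                if s in rest and rest[s] > 0
            ]
            mean_stress = float(np.mean(stress))
            out.append(
                TerritorySummary(
                    territory=terr,
                    subject=subj,
                    mean_mbf_stress=mean_stress,
                    sd_mbf_stress=float(np.std(stress, ddof=1)) if len(stress) > 1 else 0.0,
                    mean_mbf_rest=float(np.mean(list(rest.values()))) if rest else None,
                    sd_mbf_rest=(
                        float(np.std(list(rest.values()), ddof=1)) if len(rest) > 1 else None
                    ),
                    mpr_mean=float(np.mean(ratios)) if ratios else None,
                    mpr_sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else None,
                    n_segments=len(stress),
                    reduced_flow=classify_reduced_flow(mean_stress, threshold),
                )
            )
    return out


def detection_counts(summaries: Sequence[TerritorySummary]) -> Dict[str, int]:
    """Reduced-flow detection counts per angiographic group.

    Requires ``group`` assigned on every summary. "stenotic" pools groups 2
    and 3 (all vessels with a stenosis on angiography).
    """
    if any(s.group is None for s in summaries):
        raise ValueError("every territory summary needs an angiographic group")
    by_group = {g: [s for s in summaries if s.group == g] for g in (1, 2, 3)}
    counts = {
        "n_group1": len(by_group[1]),
        "n_group2": len(by_group[2]),
        "n_group3": len(by_group[3]),
        "flagged_group1": sum(s.reduced_flow for s in by_group[1]),
        "flagged_group2": sum(s.reduced_flow for s in by_group[2]),
        "flagged_group3": sum(s.reduced_flow for s in by_group[3]),
    }
    counts["n_stenotic"] = counts["n_group2"] + counts["n_group3"]
    counts["flagged_stenotic"] = counts["flagged_group2"] + counts["flagged_group3"]
    return counts


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def _check_pairs(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need n >= 2")
    return a, b


def paired_t(a, b) -> StatsReport:
    """Two-sided paired t-test on matched samples."""
    a, b = _check_pairs(a, b)
    if np.allclose(a, b):
        return StatsReport("paired_t", 0.0, 1.0, a.size)
    t, p = sps.ttest_rel(a, b)
    return StatsReport("paired_t", float(t), float(p), a.size)


def welch_t(a, b) -> StatsReport:
    """Two-sided Welch two-sample t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatsReport("welch_t", float(t), float(p), a.size + b.size)


def f_variance(a, b) -> StatsReport:
    """Two-sided Fisher F-test for homogeneity of two variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in the denominator sample")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return StatsReport("f_variance", float(f), float(min(p, 1.0)), a.size + b.size)


def one_sample_t(a, mu0: float) -> StatsReport:
    """Two-sided one-sample t-test of mean(a) against ``mu0``."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need n >= 2")
    if a.std(ddof=1) == 0:
        raise ValueError("zero variance: one-sample t undefined")
    t, p = sps.ttest_1samp(a, mu0)
    return StatsReport("one_sample_t", float(t), float(p), a.size)


def bland_altman(a, b) -> StatsReport:
    """Bland-Altman agreement: bias = mean(a-b), limits = bias +/- 1.96 SD.

    The 95% confidence interval of the bias uses the t distribution with
    n-1 degrees of freedom.
    """
    a, b = _check_pairs(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return StatsReport(
        "bland_altman",
        statistic=bias,
        p_value=1.0 if sd == 0 else float(sps.ttest_1samp(d, 0.0).pvalue),
        n=n,
        extra={
            "bias": bias,
            "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd,
            "bias_ci_low": bias - tcrit * sd / np.sqrt(n),
            "bias_ci_high": bias + tcrit * sd / np.sqrt(n),
            "sd_diff": sd,
        },
    )
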