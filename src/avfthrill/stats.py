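"""Group comparison of SNR_thr(N_opt) between normal and stenosis cohorts.

Normality of each cohort is screened with the Shapiro-Wilk test; regardless
of its outcome the cohorts are compared with a two-sided Mann-Whitney U test
(the distribution of SNR ratios is right-skewed, so the nonparametric test is
the primary analysis). Descriptive summaries use linear-interpolation
(type-7) quantiles.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupSummary",
    "TestReport",
    "summarize",
    "shapiro_wilk",
    "mann_whitney_u",
    "compare_cohorts",
    "report_to_json",
    "report_to_text",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    q25: float
    median: float
    q75: float
    iqr: float


@dataclass
class TestReport:
    shapiro: dict[str, tuple[float, float]]  # label -> (W, p)
    mw_u: float
    mw_p: float
    method: str  # "exact" or "normal-approximation"


def summarize(values, label: str = "") -> GroupSummary:
    """Type-7 (linear interpolation) quartile summary of one cohort."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("cannot summarize an empty cohort")
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    return GroupSummary(
        label=label,
        n=int(values.size),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        iqr=float(q75) - float(q25),
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston AS R94, via scipy)."""
    values = np.asarray(values, dtype=float)
    if not (3 <= values.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={values.size}")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = sstats.shapiro(values)
    return float(w), float(p)


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float, str]:
    """Mann-Whitney U (first sample's U) with explicit method selection.

    Exact p by enumeration when n1*n2 <= 64 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(U, p, method)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= 64 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative=alternative, method=method)
    label = "exact" if method == "exact" else "normal-approximation"
    return float(res.statistic), float(res.pvalue), label


def compare_cohorts(
    normal_values,
    stenosis_values,
    labels: tuple[str, str] = ("normal", "stenosis"),
    pooled_shapiro: bool = False,
) -> tuple[GroupSummary, GroupSummary, TestReport]:
    """Full two-cohort comparison of SNR values.

    Shapiro-Wilk is run per cohort by default (``pooled_shapiro=True`` tests
    the pooled sample instead); the Mann-Whitney U test is reported in either
    case.
    """
    normal_values = np.asarray(normal_values, dtype=float)
    stenosis_values = np.asarray(stenosis_values, dtype=float)
    s_nor = summarize(normal_values, labels[0])
    s_ste = summarize(stenosis_values, labels[1])
    def _shapiro_or_nan(values) -> tuple[float, float]:
        # n outside [3, 5000] (tiny toy cohorts) cannot be screened
        if not (3 <= len(values) <= 5000) or np.ptp(values) == 0:
            return (float("nan"), float("nan"))
        return shapiro_wilk(values)

    if pooled_shapiro:
        pooled = np.concatenate([normal_values, stenosis_values])
        shapiro = {"pooled": _shapiro_or_nan(pooled)}
    else:
        shapiro = {
            labels[0]: _shapiro_or_nan(normal_values),
            labels[1]: _shapiro_or_nan(stenosis_values),
        }
    u, p, method = mann_whitney_u(normal_values, stenosis_values)
    return s_nor, s_ste, TestReport(shapiro=shapiro, mw_u=u, mw_p=p, method=method)


def report_to_json(
    summaries: tuple[GroupSummary, GroupSummary],
    report: TestReport,
    path: str | Path,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    payload = {
        "groups": [asdict(s) for s in summaries],
        "shapiro": {k: list(v) for k, v in report.shapiro.items()},
        "mann_whitney": {"u": report.mw_u, "p": report.mw_p, "method": report.method},
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path


def report_to_text(
    summaries: tuple[GroupSummary, GroupSummary], report: TestReport
) -> str:
    lines = ["Cohort comparison of SNR_thr(N_opt)", "=" * 36]
    for s in summaries:
        lines.append(
            f"{s.label:>10s}: n={s.n:3d}  q25={s.q25:.4f}  median={s.median:.4f}  "
            f"q75={s.q75:.4f}  IQR={s.iqr:.4f}"
        )
    for label, (w, p) in report.shapiro.items():
        lines.append(f"Shapiro-Wilk [{label}]: W={w:.4f}, p={p:.4g}")
    lines.append(
        f"Mann-Whitney U={report.mw_u:.1f}, two-sided p={report.mw_p:.4g} ({report.method})"
    )
    return "\n".join(lines)
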