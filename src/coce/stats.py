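"""Method-agreement and summary statistics.

The morphometric validation compares cancer-area percentages measured on
elastographic stiffness maps against a reference segmentation: Pearson
correlation for association, Bland-Altman bias and 95% limits of agreement
for interchangeability, a one-tailed two-sample Student's t-test for group
comparisons, and the "mean +/- SD [min; max]" summary format.

Conventions: Student's pooled-variance t (Welch behind a flag), the 1.96
large-sample multiplier for the 95% limits (exact-t multiplier behind a
flag), and summaries printed as "[min; max]" -- the consistent form of
every printed instance, despite the label sometimes reading the other way
round.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AgreementStats:
    """Bland-Altman agreement between a measured and a reference method."""

    bias: float          # mean(measured - reference)
    sd_diff: float       # sample SD (n-1) of the differences
    loa_low: float       # bias - multiplier * sd_diff
    loa_high: float      # bias + multiplier * sd_diff
    n: int
    means: np.ndarray    # (measured + reference) / 2, for plotting
    diffs: np.ndarray


@dataclass
class SummaryStat:
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"
        return (f"{fmt(self.mean)} ± {fmt(self.sd)} "
                f"[{fmt(self.min)}; {fmt(self.max)}]")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value
    (from t = r*sqrt((n-2)/(1-r^2)) on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(measured: Sequence[float], reference: Sequence[float],
                 *, exact_t_multiplier: bool = False) -> AgreementStats:
    """Bias and 95% limits of agreement of measured vs reference."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("measured and reference must be equal-length 1-D")
    n = len(m)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mult = (float(sps.t.ppf(0.975, n - 1)) if exact_t_multiplier else 1.96)
    return AgreementStats(bias=bias, sd_diff=sd,
                          loa_low=bias - mult * sd, loa_high=bias + mult * sd,
                          n=n, means=(m + r) / 2.0, diffs=d)


def t_test_one_tailed(a: Sequence[float], b: Sequence[float],
                      direction: Literal["greater", "less"] = "greater",
                      *, welch: bool = False) -> float:
    """One-tailed two-sample Student's t-test.

    `direction` states the alternative for group a relative to group b
    ("greater": mean(a) > mean(b)).  Pooled-variance by default; Welch's
    unequal-variance form behind the flag.  Degenerate zero-variance input
    with equal means returns p = 0.5 by the no-evidence convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.5
        better = a.mean() > b.mean()
        return 0.0 if better == (direction == "greater") else 1.0
    res = sps.ttest_ind(a, b, equal_var=not welch, alternative=direction)
    return float(res.pvalue)


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean +/- sample SD with the observed range, print-ready."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return SummaryStat(mean=float(v.mean()), sd=sd, min=float(v.min()),
                       max=float(v.max()), n=int(v.size))


@dataclass
class AgreementReport:
    table: pd.DataFrame
    r: float
    p: float
    agreement: AgreementStats


def run_agreement_experiment(
    measured_percent: Sequence[float],
    truth_percent: Sequence[float],
    *,
    sample_ids: Sequence[str] | None = None,
    min_samples: int = 3,
    out_dir: str | Path | None = None,
) -> AgreementReport:
    """Morphometric agreement of elastographic vs reference cancer areas.

    Builds the per-sample table, computes Pearson r (with p) and the
    Bland-Altman statistics, and optionally writes the table (CSV), the
    statistics (JSON) and scatter / Bland-Altman plots under `out_dir`.
    """
    m = np.asarray(measured_percent, dtype=float)
    t = np.asarray(truth_percent, dtype=float)
    if m.shape != t.shape or m.ndim != 1:
        raise ValueError("measured and truth percentages must pair up")
    if len(m) < min_samples:
        raise ValueError(f"need at least {min_samples} paired samples")
    ids = (list(sample_ids) if sample_ids is not None
           else [f"sample_{i:03d}" for i in range(len(m))])
    if len(ids) != len(m):
        raise ValueError("sample_ids length mismatch")

    table = pd.DataFrame({"sample_id": ids, "truth_percent": t,
                          "coce_percent": m, "diff_percent": m - t})
    r, p = pearson(m, t)
    agreement = bland_altman(m, t)
    report = AgreementReport(table=table, r=r, p=p, agreement=agreement)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "agreement_table.csv", index=False)
        stats_json = {
            "pearson_r": r, "pearson_p": p, "bias_percent": agreement.bias,
            "sd_diff_percent": agreement.sd_diff,
            "loa_low_percent": agreement.loa_low,
            "loa_high_percent": agreement.loa_high, "n": agreement.n,
        }
        import json
        (out / "agreement_stats.json").write_text(
            json.dumps(stats_json, indent=2))
        _plot_agreement(report, out)
    return report


def _plot_agreement(report: AgreementReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(report.table["truth_percent"], report.table["coce_percent"],
               s=18, color="tab:blue")
    lim = max(1.0, report.table[["truth_percent", "coce_percent"]]
              .to_numpy().max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("reference cancer area (%)")
    ax.set_ylabel("C-OCE cancer area (%)")
    ax.set_title(f"r = {report.r:.3f}")
    fig.tight_layout()
    fig.savefig(out / "scatter.png", dpi=150)
    plt.close(fig)

    a = report.agreement
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(a.means, a.diffs, s=18, color="tab:blue")
    for y, style in ((a.bias, "-"), (a.loa_low, "--"), (a.loa_high, "--")):
        ax.axhline(y, color="tab:blue", ls=style, lw=0.8)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("C-OCE - reference (%)")
    ax.set_title(f"bias {a.bias:+.2f}%, LoA [{a.loa_low:.2f}; "
                 f"{a.loa_high:.2f}]%")
    fig.tight_layout()
    fig.savefig(out / "bland_altman.png", dpi=150)
    plt.close(fig)
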