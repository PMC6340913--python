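"""Method-comparison statistics: Bland–Altman, Pearson, ICC, cohort reports.

Differences are defined as estimated minus reference, so a positive bias
means the PPG method overestimates. Limits of agreement use the standard
1.96 multiplier. The intraclass correlation is the two-way random-effects,
absolute-agreement, average-measures form ICC(2,k).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .estimator import estimate_record
from .types import AgreementReport, PairedRR, ReferenceRR

LOA_Z = 1.96


def aggregate_reference(
    counts: Sequence[ReferenceRR], allow_fewer: bool = False
) -> float:
    """Mean of (at least three) consecutive reference counts."""
    if len(counts) < 3 and not allow_fewer:
        raise ValueError(
            f"need at least 3 consecutive reference counts, got {len(counts)} "
            "(pass allow_fewer=True to override)"
        )
    if len(counts) == 0:
        raise ValueError("no reference counts supplied")
    return float(np.mean([c.rr for c in counts]))


def bland_altman(
    pairs: Sequence[PairedRR],
) -> tuple[float, float, float, float]:
    """(bias, sd of differences, lower LoA, upper LoA), estimated - reference."""
    if len(pairs) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = np.array([p.rr_estimated - p.rr_reference for p in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - LOA_Z * sd, bias + LOA_Z * sd


def pearson(pairs: Sequence[PairedRR]) -> float:
    """Product-moment correlation between estimated and reference rates."""
    if len(pairs) < 3:
        raise ValueError("Pearson correlation requires at least 3 pairs")
    ref = np.array([p.rr_reference for p in pairs])
    est = np.array([p.rr_estimated for p in pairs])
    for name, v in (("reference", ref), ("estimated", est)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} values have zero variance")
    return float(stats.pearsonr(ref, est).statistic)


def icc_avg(ratings: np.ndarray) -> float:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``ratings`` is an n-subjects x k-methods matrix with no missing cells.
    Computed from the two-way ANOVA mean squares:
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x methods matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError(f"ICC requires >= 5 subjects and >= 2 methods, got {n}x{k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings contain missing cells")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom == 0:
        return 1.0
    return (msr - mse) / denom


def agreement_report(
    pairs: Sequence[PairedRR], availability_pct: float = 100.0
) -> AgreementReport:
    bias, sd, lo, hi = bland_altman(pairs)
    r = pearson(pairs)
    m = np.column_stack(
        [
            [p.rr_reference for p in pairs],
            [p.rr_estimated for p in pairs],
        ]
    )
    return AgreementReport(
        n=len(pairs),
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        pearson_r=r,
        icc_avg=icc_avg(m),
        availability_pct=availability_pct,
    )


def validate_cohort(
    records_with_truth: Sequence[tuple],
    config: PipelineConfig | None = None,
    plot_dir: Optional[str | Path] = None,
) -> AgreementReport:
    """Estimate every record, pair record means against truth, summarise.

    ``records_with_truth`` holds ``(PPGRecord, reference_rr)`` tuples where
    the reference is either a simulation ground truth or an aggregated
    clinical reference in breaths/min. Records for which no window fused
    count against availability and are excluded from the pairing.
    """
    cfg = config or PipelineConfig()
    if len(records_with_truth) < 2:
        raise ValueError("cohort validation requires at least 2 records")
    pairs = []
    n_available = 0
    for rec, ref in records_with_truth:
        ref_rr = ref.rr_bpm if hasattr(ref, "rr_bpm") else float(ref)
        _, _, mean_rr = estimate_record(rec, cfg)
        if mean_rr is not None:
            n_available += 1
            pairs.append(
                PairedRR(
                    subject_id=rec.subject_id,
                    rr_reference=ref_rr,
                    rr_estimated=mean_rr,
                )
            )
    if len(pairs) < 2:
        raise ValueError("fewer than 2 records produced an estimate")
    report = agreement_report(
        pairs, availability_pct=100.0 * n_available / len(records_with_truth)
    )
    if plot_dir is not None:
        _write_plots(pairs, report, Path(plot_dir))
    return report


def _write_plots(
    pairs: Sequence[PairedRR], report: AgreementReport, outdir: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    ref = np.array([p.rr_reference for p in pairs])
    est = np.array([p.rr_estimated for p in pairs])

    fig, ax = plt.subplots(figsize=(5, 5))
    lims = [min(ref.min(), est.min()) - 2, max(ref.max(), est.max()) + 2]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.plot(ref, est, "o", ms=4, alpha=0.7)
    ax.set_xlabel("Reference RR (b/min)")
    ax.set_ylabel("PPG-estimated RR (b/min)")
    ax.set_title(f"r = {report.pearson_r:.3f}, n = {report.n}")
    fig.tight_layout()
    fig.savefig(outdir / "scatter.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    mean = (ref + est) / 2
    diff = est - ref
    ax.plot(mean, diff, "o", ms=4, alpha=0.7)
    for y, style in (
        (report.bias, "-"),
        (report.loa_lower, "--"),
        (report.loa_upper, "--"),
    ):
        ax.axhline(y, color="k", ls=style, lw=0.8)
    ax.set_xlabel("Mean of methods (b/min)")
    ax.set_ylabel("Estimated - reference (b/min)")
    ax.set_title(
        f"bias {report.bias:.2f}, LoA [{report.loa_lower:.2f}, {report.loa_upper:.2f}]"
    )
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.svg")
    plt.close(fig)
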