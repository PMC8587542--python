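"""Agreement metrics: RMSE, relative RMSE, peak extraction and ICC.

RMSE between a reference ``x1`` and prediction ``x2`` is the discrete
root-mean-square of their difference; the relative RMSE normalizes by the
peak absolute value of the reference and is reported in percent.  Peak
agreement across trials is quantified by the intraclass correlation
coefficient in its two-way random-effects, absolute-agreement,
single-measure form ICC(2,1), with the categorical reading
poor (<= 0.5), moderate (<= 0.75), good (<= 0.9), excellent (> 0.9);
boundary values fall into the lower category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["rmse", "rrmse", "icc", "icc_category", "extract_peaks",
           "AgreementReport"]


def rmse(x1: np.ndarray, x2: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"length mismatch: {x1.shape} vs {x2.shape}")
    return float(np.sqrt(np.mean((x1 - x2) ** 2)))


def rrmse(x1: np.ndarray, x2: np.ndarray) -> float:
    """Relative RMSE in percent: 100 * RMSE / max |x1|.

    Note the asymmetry: the normalizer is the reference ``x1``.
    """
    x1 = np.asarray(x1, dtype=float)
    peak = float(np.max(np.abs(x1)))
    if peak == 0.0:
        raise ZeroDivisionError("rRMSE undefined for an identically-zero reference")
    return 100.0 * rmse(x1, x2) / peak


def icc_category(value: float) -> str:
    """Categorical reading of an ICC value (boundaries to the lower class)."""
    if value <= 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def icc(peaks_ref, peaks_cand) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2 table of
    paired peaks.  Requires at least 3 pairs and non-degenerate variance.
    """
    x = np.column_stack([np.asarray(peaks_ref, dtype=float),
                         np.asarray(peaks_cand, dtype=float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired peaks")
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst < 1e-300:
        raise ValueError("degenerate input: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(value), icc_category(float(value))


def extract_peaks(series: np.ndarray, window: tuple[int, int] | None = None) -> float:
    """Signed extremum of largest magnitude within a frame window."""
    x = np.asarray(series, dtype=float)
    if window is not None:
        x = x[window[0]:window[1]]
    if x.size == 0:
        raise ValueError("empty task window")
    return float(x[np.argmax(np.abs(x))])


@dataclass
class AgreementReport:
    """Agreement summary between a reference and a candidate signal set."""

    rmse: dict[str, float] = field(default_factory=dict)
    rrmse: dict[str, float] = field(default_factory=dict)
    icc: float | None = None
    icc_category: str | None = None
    icc_form: str = "ICC(2,1) absolute agreement, single measure"
    peaks_reference: list[float] = field(default_factory=list)
    peaks_candidate: list[float] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "rmse": self.rmse, "rrmse_percent": self.rrmse,
            "icc": self.icc, "icc_category": self.icc_category,
            "icc_form": self.icc_form,
            "peaks_reference": self.peaks_reference,
            "peaks_candidate": self.peaks_candidate,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def table(self) -> str:
        lines = [f"{'signal':<24}{'RMSE':>12}{'rRMSE %':>12}"]
        for key in self.rmse:
            rr = self.rrmse.get(key)
            rr_s = f"{rr:12.2f}" if rr is not None else " " * 12
            lines.append(f"{key:<24}{self.rmse[key]:12.4g}{rr_s}")
        if self.icc is not None:
            lines.append(f"peak ICC(2,1) = {self.icc:.3f} ({self.icc_category})")
        return "\n".join(lines)
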