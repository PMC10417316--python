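"""Error metrics, device-validation grading, and Bland-Altman agreement.

Metrics follow the conventions of blood-pressure device validation:

* MAD (mean absolute difference, aka MAE): mean of |prediction - reference|.
* ME (mean error): mean of (reference - prediction) — note the sign
  convention, reference minus prediction.
* SD: sample standard deviation of the signed errors (n - 1 denominator).
* CP_k: percentage of predictions with absolute error <= k mmHg (k = 5, 10,
  15).

Three published standards are graded:

* IEEE (1708-2014 style MAD bands): A if MAD <= 5 mmHg, B if 5 < MAD <= 6,
  C if 6 < MAD <= 7, D otherwise.
* BHS: A requires CP5 >= 60, CP10 >= 85, CP15 >= 95 (%); B requires
  (50, 75, 90); C requires (40, 65, 85); below C is D.
* AAMI: pass iff |ME| <= 5 mmHg and SD <= 8 mmHg.

Bland-Altman agreement is summarized by the mean difference and the
d-bar +/- 1.96 * SD limits of agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "EvalReport",
    "mad",
    "mean_error",
    "sd_of_errors",
    "cumulative_percentage",
    "grade_ieee",
    "grade_bhs",
    "grade_aami",
    "bland_altman",
    "evaluation_report",
    "plot_bland_altman",
    "plot_error_histogram",
]

BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}
AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


def _pair(predictions, references):
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("predictions and references must be equal-length 1-D and nonempty")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise InvalidArgumentError("inputs must be finite")
    return p, r


def mad(predictions, references) -> float:
    """Mean absolute difference in mmHg."""
    p, r = _pair(predictions, references)
    return float(np.mean(np.abs(p - r)))


def mean_error(predictions, references) -> float:
    """Mean signed error, reference minus prediction, in mmHg."""
    p, r = _pair(predictions, references)
    return float(np.mean(r - p))


def sd_of_errors(differences) -> float:
    """Sample standard deviation (n - 1) of the signed differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InvalidArgumentError("need at least two differences")
    return float(np.std(d, ddof=1))


def cumulative_percentage(differences, threshold: float) -> float:
    """Percentage of differences with |d| <= threshold mmHg."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise InvalidArgumentError("empty differences")
    return float(100.0 * np.mean(np.abs(d) <= threshold))


def grade_ieee(mad_value: float) -> str:
    """IEEE MAD bands: A <= 5 < B <= 6 < C <= 7 < D."""
    if mad_value <= 5:
        return "A"
    if mad_value <= 6:
        return "B"
    if mad_value <= 7:
        return "C"
    return "D"


def grade_bhs(cp5: float, cp10: float, cp15: float) -> str:
    """BHS cumulative-percentage grade; D when below every band."""
    for grade, (t5, t10, t15) in BHS_THRESHOLDS.items():
        if cp5 >= t5 and cp10 >= t10 and cp15 >= t15:
            return grade
    return "D"


def grade_aami(me: float, sd: float) -> bool:
    """AAMI: pass iff |ME| <= 5 mmHg and SD <= 8 mmHg (inclusive)."""
    return bool(abs(me) <= AAMI_ME_LIMIT and sd <= AAMI_SD_LIMIT)


def bland_altman(predictions, references) -> tuple[float, float, float]:
    """(mean difference, lower, upper) limits of agreement, d-bar +/- 1.96 SD.

    Differences follow the mean-error sign convention (reference minus
    prediction).  With fewer than two pairs or zero spread the limits equal
    the mean difference.
    """
    p, r = _pair(predictions, references)
    d = r - p
    center = float(np.mean(d))
    spread = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return center, center - 1.96 * spread, center + 1.96 * spread


@dataclass
class EvalReport:
    """Consolidated evaluation of one prediction set against references."""

    mad: float
    me: float
    sd: float
    cp5: float
    cp10: float
    cp15: float
    ieee_grade: str
    bhs_grade: str
    aami_pass: bool
    bland_altman_mean: float
    bland_altman_lower: float
    bland_altman_upper: float
    n: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            f"n segments        : {self.n}",
            f"MAD               : {self.mad:.3f} mmHg",
            f"ME                : {self.me:.3f} mmHg",
            f"SD of errors      : {self.sd:.3f} mmHg",
            f"CP5 / CP10 / CP15 : {self.cp5:.2f}% / {self.cp10:.2f}% / {self.cp15:.2f}%",
            f"IEEE grade        : {self.ieee_grade}",
            f"BHS grade         : {self.bhs_grade}",
            f"AAMI              : {'pass' if self.aami_pass else 'fail'}",
            (
                "Bland-Altman      : "
                f"{self.bland_altman_mean:.3f} mmHg "
                f"[{self.bland_altman_lower:.3f}, {self.bland_altman_upper:.3f}]"
            ),
        ]
        return "\n".join(lines)


def plot_bland_altman(predictions, references, path) -> None:
    """Bland-Altman scatter (mean vs difference) with the limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p, r = _pair(predictions, references)
    d = r - p
    center, lower, upper = bland_altman(p, r)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((p + r) / 2, d, s=6, alpha=0.4)
    for yv, style in ((center, "-"), (lower, "--"), (upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of reference and prediction (mmHg)")
    ax.set_ylabel("reference - prediction (mmHg)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=100)
    plt.close(fig)


def plot_error_histogram(predictions, references, path, bins: int = 40) -> None:
    """Histogram of the signed prediction errors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p, r = _pair(predictions, references)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(r - p, bins=bins)
    ax.set_xlabel("reference - prediction (mmHg)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(str(path), dpi=100)
    plt.close(fig)


def evaluation_report(predictions, references) -> EvalReport:
    """Full report: metrics, the three standards' outcomes, and agreement limits."""
    p, r = _pair(predictions, references)
    d = r - p
    mad_v = mad(p, r)
    me_v = mean_error(p, r)
    sd_v = sd_of_errors(d) if d.size > 1 else 0.0
    cp5 = cumulative_percentage(d, 5)
    cp10 = cumulative_percentage(d, 10)
    cp15 = cumulative_percentage(d, 15)
    ba = bland_altman(p, r)
    return EvalReport(
        mad=mad_v,
        me=me_v,
        sd=sd_v,
        cp5=cp5,
        cp10=cp10,
        cp15=cp15,
        ieee_grade=grade_ieee(mad_v),
        bhs_grade=grade_bhs(cp5, cp10, cp15),
        aami_pass=grade_aami(me_v, sd_v),
        bland_altman_mean=ba[0],
        bland_altman_lower=ba[1],
        bland_altman_upper=ba[2],
        n=int(p.size),
    )
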