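"""Performance quantification: unweighted average recall, empirical chance
levels from the inverse binomial CDF, and one-tailed significance over the
cross-validation's evaluation sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

ALPHA_DEFAULT = 0.05
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def uar(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted average recall, in percent.

    Mean over classes of (correct in class / total in class); classes absent
    from the truth are excluded from the mean.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("uar of empty label sequences is undefined")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    recalls = [
        np.mean(y_pred[y_true == cls] == cls) for cls in np.unique(y_true)
    ]
    return float(np.mean(recalls) * 100.0)


def empirical_chance(n_test: int, n_classes: int, alpha: float = ALPHA_DEFAULT) -> float:
    """Percent-correct threshold above which decoding beats chance.

    The smallest k with ``BinomialCDF(k; n_test, 1/n_classes) >= 1 - alpha``
    (exact binomial, no normal approximation), returned as ``100 k / n``.
    Non-increasing in n and strictly above 100/n_classes for finite n.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    p = 1.0 / n_classes
    k = int(binom.ppf(1.0 - alpha, n_test, p))
    while binom.cdf(k, n_test, p) < 1.0 - alpha:  # guard against ppf rounding
        k += 1
    while k > 0 and binom.cdf(k - 1, n_test, p) >= 1.0 - alpha:
        k -= 1
    return 100.0 * k / n_test


def chance_band(n_test: int, n_classes: int, alpha: float = ALPHA_DEFAULT) -> tuple[float, float]:
    """Symmetric band (about the theoretical level) inside which an accuracy
    is indistinguishable from chance: (200/c - threshold, threshold)."""
    hi = empirical_chance(n_test, n_classes, alpha)
    theoretical = 100.0 / n_classes
    return (2 * theoretical - hi, hi)


def significance(
    uars: Sequence[float], chance: float
) -> tuple[float, int, float, str]:
    """One-sample one-tailed t-test of UARs against chance (H1: mean > chance).

    Returns (t, df, p, stars).  Zero variance resolves by convention:
    p = 0 if the common value exceeds chance, else p = 1.
    """
    uars = np.asarray(uars, dtype=float)
    if uars.size < 2:
        raise ValueError("need at least 2 UAR values")
    df = uars.size - 1
    sd = uars.std(ddof=1)
    if sd == 0:
        p = 0.0 if uars.mean() > chance else 1.0
        t = np.inf if uars.mean() > chance else (-np.inf if uars.mean() < chance else 0.0)
    else:
        from scipy.stats import ttest_1samp

        res = ttest_1samp(uars, popmean=chance, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    stars = ""
    for level, sym in STAR_LEVELS:
        if p < level:
            stars = sym
            break
    return float(t), int(df), float(p), stars


@dataclass
class EvalReport:
    """Per-configuration performance over the 30 test evaluations."""

    uars: list[float]
    n_test: dict[int, int]
    n_classes: int
    alpha: float = ALPHA_DEFAULT
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(0.0 <= u <= 100.0 for u in self.uars):
            raise ValueError("UAR values must lie in [0, 100]")

    @property
    def mean_uar(self) -> float:
        return float(np.mean(self.uars))

    @property
    def sd_uar(self) -> float:
        return float(np.std(self.uars, ddof=1))

    @property
    def empirical_chance_per_fold(self) -> dict[int, float]:
        return {
            f: empirical_chance(n, self.n_classes, self.alpha)
            for f, n in self.n_test.items()
        }

    @property
    def empirical_chance_level(self) -> float:
        """Headline chance level: per-fold thresholds averaged across folds."""
        per_fold = self.empirical_chance_per_fold
        return float(np.mean(list(per_fold.values())))

    @property
    def empirical_chance_pooled(self) -> float:
        """Alternative convention: one threshold from the pooled test size."""
        return empirical_chance(sum(self.n_test.values()), self.n_classes, self.alpha)

    @property
    def diff_uar(self) -> float:
        return self.mean_uar - self.empirical_chance_level

    def ttest(self) -> tuple[float, int, float, str]:
        return significance(self.uars, self.empirical_chance_level)

    def to_dict(self) -> dict:
        t, df, p, stars = self.ttest()
        return {
            "uars": [float(u) for u in self.uars],
            "mean_uar": self.mean_uar,
            "sd_uar": self.sd_uar,
            "n_test": {str(k): int(v) for k, v in self.n_test.items()},
            "n_classes": self.n_classes,
            "alpha": self.alpha,
            "empirical_chance": self.empirical_chance_level,
            "empirical_chance_per_fold": {
                str(k): v for k, v in self.empirical_chance_per_fold.items()
            },
            "empirical_chance_pooled": self.empirical_chance_pooled,
            "diff_uar": self.diff_uar,
            "t": t,
            "df": df,
            "p": p,
            "stars": stars,
            "config": self.config,
        }


def summary_table(reports: Sequence[EvalReport]):
    """One row per configuration (check x T x channel count): mean +/- sd UAR,
    empirical chance, diffUAR, significance stars."""
    import pandas as pd

    rows = []
    for rep in reports:
        _, _, p, stars = rep.ttest()
        rows.append(
            {
                "check": rep.config.get("check", ""),
                "n_averaged": rep.config.get("n_averaged", ""),
                "n_channels": len(rep.config.get("channels", [])),
                "mean_uar": rep.mean_uar,
                "sd_uar": rep.sd_uar,
                "chance": rep.empirical_chance_level,
                "diff_uar": rep.diff_uar,
                "p": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows)


def evaluate(result, alpha: float = ALPHA_DEFAULT, config: dict | None = None) -> EvalReport:
    """Build an EvalReport from a decode.SicvResult."""
    return EvalReport(
        uars=[float(u) for u in result.uars],
        n_test=dict(result.n_test),
        n_classes=len(result.classes),
        alpha=alpha,
        config=config or {},
    )
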