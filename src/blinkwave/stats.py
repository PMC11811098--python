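"""Method-agreement and group-comparison statistics.

Reusable wrappers around the agreement statistics used to validate blink
metrics against a reference device: Bland-Altman limits of agreement (on
percent-of-pair-mean differences by default), the intraclass correlation
coefficient ICC(2,1) (two-way random effects, absolute agreement, single
measurement), Cohen's kappa for categorical labels, Spearman rank
correlation, and a normality-screened two-group comparison (Student's t when
both groups pass Shapiro-Wilk, Mann-Whitney U otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "bland_altman",
    "icc_absolute",
    "cohen_kappa",
    "spearman_corr",
    "compare_groups",
    "agreement_report",
]


@dataclass
class AgreementReport:
    """Bland-Altman summary (optionally with the paired-measurement ICC)."""

    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_used: int
    icc: float | None = None


def bland_altman(a, b, mode: str = "percent") -> AgreementReport:
    """Bland-Altman agreement between paired measurements.

    ``percent`` mode expresses each difference as a percentage of the pair
    mean, d_i = (a_i − b_i) / mean(a_i, b_i) · 100 (pairs with zero mean are
    excluded); ``raw`` mode uses plain differences.  The 95% limits of
    agreement are mean(d) ± 1.96·sd(d) with the sample standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if mode == "percent":
        m = (a + b) / 2.0
        keep = m != 0
        d = (a[keep] - b[keep]) / m[keep] * 100.0
    elif mode == "raw":
        d = a - b
    else:
        raise ValueError("mode must be 'percent' or 'raw'")
    if d.size < 2:
        raise ValueError("need at least 2 usable pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        sd_diff=sd,
        n_used=int(d.size),
    )


def icc_absolute(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_targets, n_raters) array; needs n_targets >= 3 and
    nonzero between-target variance.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be (n_targets, n_raters) with >= 2 raters")
    n, k = r.shape
    if n < 3:
        raise ValueError("need at least 3 targets")
    if np.ptp(r.mean(axis=1)) == 0 and np.allclose(r.var(axis=1), 0):
        raise ValueError("zero variance: ICC undefined")
    import pingouin as pg

    df = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": r.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # degenerate (e.g. identical-rater) inputs make pingouin's CI
        # arithmetic warn; the point estimate itself is well defined
        icc = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        )
    # the absolute-agreement single-measure row is labelled ICC2 or ICC(A,1)
    # depending on the pingouin version
    row = icc[icc["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa, (p_o − p_e)/(1 − p_e); errors when p_e = 1."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label sequences must be non-empty and equal length")
    cats, ai = np.unique(a, return_inverse=True)
    cats_b, bi = np.unique(b, return_inverse=True)
    # expected agreement from the marginals
    all_cats = np.unique(np.concatenate([cats, cats_b]))
    pa = np.array([(a == c).mean() for c in all_cats])
    pb = np.array([(b == c).mean() for c in all_cats])
    pe = float((pa * pb).sum())
    if pe == 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(a, b))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(g1, g2, alpha: float = 0.05) -> tuple[str, float, float]:
    """Two-group comparison with a Shapiro-Wilk normality screen.

    Both groups normal at ``alpha`` -> Student's t-test (equal variances);
    otherwise Mann-Whitney U (two-sided).  Returns (test_name, statistic, p).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs at least 3 observations")

    def _normal(g) -> bool:
        if np.ptp(g) == 0:
            return False  # degenerate; Shapiro is undefined on constants
        return sps.shapiro(g).pvalue > alpha

    if _normal(g1) and _normal(g2):
        res = sps.ttest_ind(g1, g2, equal_var=True)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float(res.pvalue)


def agreement_report(a, b, mode: str = "percent") -> AgreementReport:
    """Bland-Altman plus ICC(2,1) of the same paired measurements."""
    rep = bland_altman(a, b, mode=mode)
    rep.icc = icc_absolute(np.column_stack([a, b]))
    return rep
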