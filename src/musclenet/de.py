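"""Variance filtering and moderated two-group differential expression.

The model is the standard small-sample workhorse for two-group microarray
comparisons: a per-gene linear model with an empirical-Bayes prior on the
residual variances.  Writing :math:`s_g^2` for the pooled residual
variance of gene *g* on :math:`d_g` degrees of freedom, the variances are
assumed to follow a scaled inverse-chi-square prior with scale
:math:`s_0^2` and :math:`d_0` degrees of freedom.  Both hyperparameters
are estimated by moment matching on :math:`\\log s_g^2`, the posterior
variance is the precision-weighted blend

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},

and the moderated t statistic
:math:`\\tilde t_g = \\widehat{\\Delta}_g / (\\tilde s_g \\sqrt{1/n_1 + 1/n_2})`
is referred to a t distribution on :math:`d_0 + d_g` degrees of freedom.
With :math:`d_0 = 0` the statistic reduces exactly to the classical
equal-variance two-sample t; with :math:`d_0 = \\infty` all genes share
one variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError
from .io import ExpressionMatrix, SampleAnnotation, log2_to_fold_change

__all__ = [
    "iqr_filter",
    "ModeratedTTest",
    "ModeratedTTestResults",
    "moderated_t_test",
    "bh_adjust",
    "select_de_genes",
    "select_de_from_printed",
]


def iqr_filter(
    matrix: ExpressionMatrix, iqr_min: float = 0.25, *, strict: bool = True
) -> ExpressionMatrix:
    """Drop genes whose interquartile range across all samples is small.

    The IQR is the 75th minus the 25th percentile of each gene's log2
    values, with percentiles computed by linear interpolation between
    order statistics.  Genes with IQR strictly greater than ``iqr_min``
    are kept (``strict=False`` keeps ties as well); gene order is
    preserved.
    """
    if iqr_min < 0:
        raise ConfigurationError("iqr_min must be ≥ 0")
    if matrix.n_samples < 2:
        raise ConfigurationError("iqr_filter needs at least 2 samples")
    q75, q25 = np.percentile(matrix.values, [75, 25], axis=1, method="linear")
    iqr = q75 - q25
    keep = iqr > iqr_min if strict else iqr >= iqr_min
    if not keep.any():
        raise ConfigurationError("iqr_filter removed every gene; lower iqr_min")
    return ExpressionMatrix(matrix.data.loc[keep])


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good start for both tails
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-12 * np.maximum(x, 1.0)):
            break
    return x if x.shape else float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled inverse-chi-square variance prior.

    Returns ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the
    observed spread of log variances is no larger than sampling noise
    alone (complete shrinkage).  Zero variances are excluded from the
    fit but still shrunk afterwards.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ConfigurationError("too few genes with positive variance to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * float(_trigamma_inverse(target))
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


@dataclass(frozen=True)
class ModeratedTTestResults:
    """Fit results; one row per gene in ``table``.

    Columns: per-group means, ``log2_fc`` (case − control), signed linear
    ``fold_change``, ``residual_var``, shrunken ``posterior_var``,
    moderated ``t``, raw ``p_value`` and BH-adjusted ``adj_p``.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    df_residual: int
    control_label: str
    case_label: str

    @property
    def df_total(self) -> float:
        return self.df_residual + self.prior_df

    def select(
        self, min_abs_log2fc: float = 1.0, max_adj_p: float = 0.05
    ) -> pd.DataFrame:
        """Genes passing both cutoffs, labelled up/down, sorted by raw p."""
        t = self.table
        sel = t[(t["log2_fc"].abs() >= min_abs_log2fc) & (t["adj_p"] <= max_adj_p)].copy()
        sel["direction"] = np.where(sel["log2_fc"] > 0, "up", "down")
        return sel.sort_values("p_value", kind="stable")

    def summary(self) -> str:
        n = len(self.table)
        n_sig = int((self.table["adj_p"] <= 0.05).sum())
        lines = [
            "Moderated two-group differential expression",
            f"  contrast        : {self.case_label} - {self.control_label}",
            f"  genes tested    : {n}",
            f"  residual df     : {self.df_residual}",
            f"  prior df (d0)   : {self.prior_df:.4g}",
            f"  prior var (s0^2): {self.prior_var:.4g}",
            f"  adj p <= 0.05   : {n_sig}",
        ]
        return "\n".join(lines)


class ModeratedTTest:
    """Two-group empirical-Bayes moderated t model for an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Genes × samples log2 intensities.
    annotation : SampleAnnotation
        Two-group sample labels covering every matrix sample.
    case : str, optional
        Which label is the case (numerator) group.  Defaults to the
        second label in annotation order; pipelines should pass it
        explicitly.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: SampleAnnotation,
        case: Optional[str] = None,
    ) -> None:
        annotation.check_covers(matrix)
        labels = annotation.group_labels
        if case is None:
            case = labels[1]
        if case not in labels:
            raise ConfigurationError(f"case label {case!r} not among groups {labels}")
        control = labels[0] if case == labels[1] else labels[1]
        ctrl_samples = [s for s in matrix.sample_ids if s in set(annotation.samples_in(control))]
        case_samples = [s for s in matrix.sample_ids if s in set(annotation.samples_in(case))]
        if len(ctrl_samples) < 2 or len(case_samples) < 2:
            raise ConfigurationError("each group needs at least 2 samples")
        self.matrix = matrix
        self.control_label = control
        self.case_label = case
        self._x_control = matrix.data[ctrl_samples].to_numpy()
        self._x_case = matrix.data[case_samples].to_numpy()

    def fit(self, prior_df: Optional[float] = None) -> ModeratedTTestResults:
        """Fit the model.

        ``prior_df=None`` estimates the prior from the data; ``0``
        disables shrinkage (classical pooled t); ``inf`` shrinks every
        gene to the common prior variance.
        """
        xc, xa = self._x_control, self._x_case
        n1, n2 = xc.shape[1], xa.shape[1]
        df = n1 + n2 - 2
        mean_c = xc.mean(axis=1)
        mean_a = xa.mean(axis=1)
        log2fc = mean_a - mean_c
        ss = ((xc - mean_c[:, None]) ** 2).sum(axis=1) + (
            (xa - mean_a[:, None]) ** 2
        ).sum(axis=1)
        s2 = ss / df

        if prior_df is None:
            d0, s0 = _fit_variance_prior(s2, df)
        elif prior_df == 0:
            d0, s0 = 0.0, 0.0
        elif np.isinf(prior_df):
            d0, s0 = _fit_variance_prior(s2, df)
            d0 = np.inf
        else:
            if prior_df < 0:
                raise ConfigurationError("prior_df must be ≥ 0")
            _, s0 = _fit_variance_prior(s2, df)
            d0 = float(prior_df)

        if np.isinf(d0):
            post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            post = (d0 * s0 + df * s2) / (d0 + df)
            df_total = d0 + df

        se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
            t = np.where((se == 0) & (log2fc != 0), np.sign(log2fc) * np.inf, t)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        table = pd.DataFrame(
            {
                "mean_control": mean_c,
                "mean_case": mean_a,
                "log2_fc": log2fc,
                "fold_change": [log2_to_fold_change(v) for v in log2fc],
                "residual_var": s2,
                "posterior_var": post,
                "t": t,
                "p_value": p,
                "adj_p": bh_adjust(p),
            },
            index=self.matrix.data.index,
        )
        return ModeratedTTestResults(
            table=table,
            prior_df=float(d0),
            prior_var=float(s0),
            df_residual=df,
            control_label=self.control_label,
            case_label=self.case_label,
        )


def moderated_t_test(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    case: Optional[str] = None,
    prior_df: Optional[float] = None,
) -> ModeratedTTestResults:
    """Convenience wrapper: build the model and fit in one call."""
    return ModeratedTTest(matrix, annotation, case=case).fit(prior_df=prior_df)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``adjusted_i = min_{j ≥ i} (m · p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def select_de_genes(
    result: ModeratedTTestResults,
    min_abs_log2fc: float = 1.0,
    max_adj_p: float = 0.05,
) -> pd.DataFrame:
    """Cutoff-based DE gene selection (see :meth:`ModeratedTTestResults.select`)."""
    return result.select(min_abs_log2fc=min_abs_log2fc, max_adj_p=max_adj_p)


def select_de_from_printed(
    table: pd.DataFrame, min_abs_fc: float = 2.0, max_p: float = 0.05
) -> pd.DataFrame:
    """Apply the published cutoffs to a printed (p, signed linear FC) table.

    Expects ``p_value`` and ``fold_change`` columns (the packaged DE
    fixture's layout); |FC| ≥ ``min_abs_fc`` corresponds to
    |log2FC| ≥ log2(``min_abs_fc``).
    """
    sel = table[(table["fold_change"].abs() >= min_abs_fc) & (table["p_value"] <= max_p)].copy()
    sel["direction"] = np.where(sel["fold_change"] > 0, "up", "down")
    return sel
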