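"""Replicate and inter-panel agreement via Bland-Altman statistics.

For a pair of paired measurement vectors (A, B) the Bland-Altman summary
works with the differences d = A - B plotted against the means
m = (A + B)/2: the mean difference captures bias, the SD of differences
(denominator n-1) captures spread, and a degree-1 tricube local regression
of d on m exposes intensity-dependent trends. Pearson and Spearman
correlations of A vs B are reported side by side; a pair with zero
variance in either vector gets an explicit undefined marker (None) rather
than a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .io_formats import ExpressionMatrix
from .smoothing import loess_fit

TREND_POINTS = 100


@dataclass
class AgreementSummary:
    label_a: str
    label_b: str
    n: int
    differences: np.ndarray
    means: np.ndarray
    mean_diff: float
    sd_diff: float
    pearson_r: float | None
    spearman_rho: float | None
    trend: pd.DataFrame  # columns: mean, fitted_diff (sorted by mean)

    def as_row(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
        }


def bland_altman_stats(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.6,
    label_a: str = "A",
    label_b: str = "B",
) -> AgreementSummary:
    """Bland-Altman summary of paired vectors with a local-regression trend."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ParameterError(f"need at least 3 paired values, got {x.size}")
    d = x - y
    m = 0.5 * (x + y)
    sd = float(np.std(d, ddof=1))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = spearman = None
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    grid = np.linspace(m.min(), m.max(), TREND_POINTS) if np.ptp(m) > 0 else np.array([m[0]])
    fitted = loess_fit(m, d, span=span, eval_x=grid)
    trend = pd.DataFrame({"mean": grid, "fitted_diff": fitted})
    return AgreementSummary(
        label_a=label_a,
        label_b=label_b,
        n=int(x.size),
        differences=d,
        means=m,
        mean_diff=float(d.mean()),
        sd_diff=sd,
        pearson_r=pearson,
        spearman_rho=spearman,
        trend=trend,
    )


def _primary_sample(group: pd.DataFrame) -> pd.Series:
    first_extract = group[group["extract"] == group["extract"].min()]
    return first_extract.loc[first_extract["order_index"].idxmin()]


def replicate_agreement(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    mode: str,
    span: float = 0.6,
) -> list[AgreementSummary]:
    """One Bland-Altman summary per (primary, replicate) sample pair.

    ``mode='technical'`` pairs the first measurement of the first extract
    with its repeat hybridization of the same extract; ``mode='extract'``
    pairs it with the first measurement of the second RNA extract.
    Subjects lacking the requested replicate are skipped. Rows of
    ``matrix`` (probes or genes) are the paired units; the first vector of
    each pair is the primary sample.
    """
    if mode not in ("technical", "extract"):
        raise ParameterError(f"mode must be 'technical' or 'extract', got {mode!r}")
    meta = metadata[metadata["sample_id"].isin(matrix.sample_ids)]
    summaries = []
    for _, grp in meta.groupby("subject_id", sort=True):
        reps = grp[grp["replicate_kind"] == mode]
        if reps.empty:
            continue
        primary = _primary_sample(grp)
        rep = reps.loc[reps["order_index"].idxmin()]
        summaries.append(
            bland_altman_stats(
                matrix.values[primary["sample_id"]].to_numpy(),
                matrix.values[rep["sample_id"]].to_numpy(),
                span=span,
                label_a=primary["sample_id"],
                label_b=rep["sample_id"],
            )
        )
    return summaries


def interpanel_agreement(
    gene_a: ExpressionMatrix,
    gene_b: ExpressionMatrix,
    units: str = "genes",
    seq_matches: pd.DataFrame | None = None,
    span: float = 0.6,
) -> list[AgreementSummary]:
    """Per-sample agreement between the two panels.

    ``units='genes'`` compares shared gene-level rows; ``units='seq_probes'``
    compares probe-level rows paired by the sequence-match table (pass the
    probe-level matrices in that case). The first panel plays the role of
    measurement A in every summary.
    """
    shared_samples = [s for s in gene_a.sample_ids if s in set(gene_b.sample_ids)]
    if not shared_samples:
        raise ParameterError("panels share no sample ids")
    if units == "genes":
        shared_units = [g for g in gene_a.probe_ids if g in set(gene_b.probe_ids)]
        if not shared_units:
            raise ParameterError("panels share no gene keys")
        a_vals = gene_a.values.loc[shared_units]
        b_vals = gene_b.values.loc[shared_units]
    elif units == "seq_probes":
        if seq_matches is None or seq_matches.empty:
            raise ParameterError("units='seq_probes' requires a nonempty match table")
        a_vals = gene_a.values.loc[seq_matches["panelA_probe_id"]]
        b_vals = gene_b.values.loc[seq_matches["panelB_probe_id"]]
    else:
        raise ParameterError(f"unknown units {units!r}")
    return [
        bland_altman_stats(
            a_vals[s].to_numpy(),
            b_vals[s].to_numpy(),
            span=span,
            label_a=f"{gene_a.panel_id}:{s}",
            label_b=f"{gene_b.panel_id}:{s}",
        )
        for s in shared_samples
    ]


def agreement_table(summaries: list[AgreementSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per pair (trend curves omitted)."""
    return pd.DataFrame([s.as_row() for s in summaries])
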