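"""Differential expression between HER2+ and HER2- groups.

Welch unequal-variance t-tests at the probe or gene level, with level-
specific candidacy rules (probe: p < 0.01 and |log2FC| > 1.0; gene:
p < 0.05 and |log2FC| > 0.5, both strict), fold-change direction
concordance across panels over a grid of noise thresholds, and a two-sided
Fisher exact test for 2x2 contingency tables by full hypergeometric
enumeration.

Only one sample per subject enters the tests: the first measurement of the
first RNA extract, so replicate hybridizations never inflate the group
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConsistencyError, ParameterError
from .io_formats import ExpressionMatrix

PROBE_P, PROBE_FC = 0.01, 1.0
GENE_P, GENE_FC = 0.05, 0.5
DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class TestResult:
    t: float
    df: float
    p: float


def candidate_flag(p, log2fc, level: str):
    """Differential-expression candidacy rule, strict at both cut-offs.

    Probe level: p < 0.01 and |log2FC| > 1.0; gene level: p < 0.05 and
    |log2FC| > 0.5. Accepts scalars or arrays.
    """
    if level not in ("probe", "gene"):
        raise ParameterError(f"level must be 'probe' or 'gene', got {level!r}")
    p_cut, fc_cut = (PROBE_P, PROBE_FC) if level == "probe" else (GENE_P, GENE_FC)
    return (np.asarray(p) < p_cut) & (np.abs(log2fc) > fc_cut)


def select_analysis_samples(metadata: pd.DataFrame) -> list[str]:
    """One sample per subject: lowest order_index among first-extract samples."""
    chosen = []
    for subj, grp in metadata.groupby("subject_id", sort=True):
        first = grp[grp["extract"] == grp["extract"].min()]
        if first.empty:
            raise ConsistencyError(f"subject {subj!r} has no samples")
        chosen.append(first.loc[first["order_index"].idxmin(), "sample_id"])
    return chosen


def welch_t_test(a, b) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom. Two identical zero-variance
    groups give t=0, p=1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    t, df, p = _welch_rows(a[None, :], b[None, :])
    return TestResult(float(t[0]), float(df[0]), float(p[0]))


def _welch_rows(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch test over rows of two (units x samples) arrays."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom2 = va + vb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    zero = denom2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(zero, na + nb - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), np.finfo(float).tiny, p)
    p = np.where(zero & (diff == 0), 1.0, p)
    return t, df, np.minimum(p, 1.0)


def differential_expression(
    matrix: ExpressionMatrix, metadata: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Per-unit Welch test and candidacy call; sorted ascending by p.

    log2FC sign convention is HER2+ minus HER2-. ``level`` selects the
    candidacy rule only; pass a probe-level or gene-level matrix to match.
    """
    if level not in ("probe", "gene"):
        raise ParameterError(f"level must be 'probe' or 'gene', got {level!r}")
    if matrix.scale != "log2":
        raise ParameterError("differential expression expects log2 values")
    samples = select_analysis_samples(metadata)
    meta = metadata.set_index("sample_id").loc[samples]
    pos = [s for s in samples if meta.at[s, "group"] == "HER2+"]
    neg = [s for s in samples if meta.at[s, "group"] == "HER2-"]
    if len(pos) < 2 or len(neg) < 2:
        raise ParameterError(
            f"need >=2 subjects per group, got {len(pos)} HER2+ / {len(neg)} HER2-"
        )
    a = matrix.values[pos].to_numpy(dtype=float)
    b = matrix.values[neg].to_numpy(dtype=float)
    t, df, p = _welch_rows(a, b)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {
            "unit_id": matrix.values.index,
            "level": level,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "candidate": candidate_flag(p, log2fc, level),
        }
    )
    return table.sort_values(["p", "unit_id"], kind="stable").reset_index(drop=True)


def fold_change_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    drop_both_zero: bool = False,
) -> pd.DataFrame:
    """Direction agreement of per-gene fold changes over noise thresholds.

    At each threshold tau, genes with |log2FC| > tau on at least one panel
    are retained; a retained gene is concordant when both fold changes are
    strictly positive or both strictly negative. A zero fold change is
    never concordant; pairs where both are zero count as discordant unless
    ``drop_both_zero``.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)
    merged = de_a[["unit_id", "log2fc"]].merge(
        de_b[["unit_id", "log2fc"]], on="unit_id", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ConsistencyError("the two tables share no gene keys")
    fa = merged["log2fc_a"].to_numpy()
    fb = merged["log2fc_b"].to_numpy()
    if drop_both_zero:
        keep = ~((fa == 0) & (fb == 0))
        fa, fb = fa[keep], fb[keep]
    rows = []
    for tau in thresholds:
        retained = (np.abs(fa) > tau) | (np.abs(fb) > tau)
        ra, rb = fa[retained], fb[retained]
        up_up = int(((ra > 0) & (rb > 0)).sum())
        down_down = int(((ra < 0) & (rb < 0)).sum())
        n_ret = int(retained.sum())
        rows.append(
            {
                "threshold": float(tau),
                "n_retained": n_ret,
                "up_up": up_up,
                "down_down": down_down,
                "discordant": n_ret - up_up - down_down,
                "proportion_concordant": (up_up + down_down) / n_ret if n_ret else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by full enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (with a
    relative 1e-12 tie tolerance).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ParameterError("table must be 2x2 nonnegative integers")
    a, b, c, d = (int(v) for v in np.round(arr).ravel())
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        raise ParameterError("all margins of the 2x2 table must be positive")
    k = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, total, col1, row1)
    p_obs = stats.hypergeom.pmf(a, total, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))
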