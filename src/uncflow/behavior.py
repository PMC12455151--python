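"""Behavioural analysis: screening, RT filtering, signal detection and
within-subject factorial statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SIGNAL_LETTER

__all__ = [
    "screen_participants",
    "filter_rts",
    "compute_dprime",
    "subject_summary",
    "rm_anova",
    "paired_contrasts",
    "paired_t_power",
    "paired_t_sample_size",
    "AnovaResult",
    "ContrastResult",
]

ACCURACY_CUTOFF = 0.55
RT_MIN_MS = 100.0
RT_MAX_MS = 2000.0


def screen_participants(
    tables: Mapping[str, pd.DataFrame], cutoff: float = ACCURACY_CUTOFF
) -> tuple[list[str], pd.DataFrame]:
    """Retain subjects whose overall accuracy exceeds ``cutoff``.

    Returns the retained subject ids (input order preserved) and an exclusion
    log with one row per subject (id, accuracy, retained flag).
    """
    retained: list[str] = []
    log_rows = []
    for subject, table in tables.items():
        if len(table) == 0:
            raise ValueError(f"trial table for subject {subject!r} is empty")
        acc = float(table["correct"].mean())
        keep = acc > cutoff
        if keep:
            retained.append(subject)
        log_rows.append({"subject": subject, "accuracy": acc, "retained": keep})
    return retained, pd.DataFrame(log_rows)


def filter_rts(
    table: pd.DataFrame,
    rt_min: float = RT_MIN_MS,
    rt_max: float = RT_MAX_MS,
) -> tuple[pd.DataFrame, float]:
    """Keep correct-response trials with rt strictly inside (rt_min, rt_max).

    The bounds are exclusive ("faster than 100 ms and slower than 2000 ms"
    are removed), so rows at exactly 100 or 2000 ms survive. Returns the
    filtered table and the removed fraction.
    """
    keep = (table["correct"] == 1) & (table["rt_ms"] >= rt_min) & (table["rt_ms"] <= rt_max)
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("RT filtering removed every trial", stacklevel=2)
    removed_fraction = 1.0 - len(out) / len(table) if len(table) else 0.0
    return out, removed_fraction


def compute_dprime(hits: int, misses: int, fas: int, crs: int) -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    Extreme rates (0 or 1) are replaced by 1/(2N) and 1 - 1/(2N) where N is
    the relevant trial count, keeping the inverse normal finite.
    """
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal trial and one noise trial")

    def _rate(k: int, n: int) -> float:
        r = k / n
        if r <= 0.0:
            return 1.0 / (2 * n)
        if r >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    return float(stats.norm.ppf(_rate(hits, n_signal)) - stats.norm.ppf(_rate(fas, n_noise)))


def subject_summary(table: pd.DataFrame, signal_letter: str = SIGNAL_LETTER) -> pd.DataFrame:
    """Per condition x validity: d', mean RT of filtered trials, accuracy, n used.

    Hits are correct responses to the signal letter; false alarms are
    signal responses to the noise letter.
    """
    rows = []
    for (cond, validity), cell in table.groupby(["condition", "validity"], sort=False):
        is_signal = cell["target"] == signal_letter
        said_signal = cell["response"] == signal_letter
        hits = int((is_signal & said_signal).sum())
        misses = int((is_signal & ~said_signal).sum())
        fas = int((~is_signal & said_signal).sum())
        crs = int((~is_signal & ~said_signal).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered, _ = filter_rts(cell)
        rows.append(
            {
                "condition": cond,
                "validity": validity,
                "d_prime": compute_dprime(hits, misses, fas, crs),
                "mean_rt": float(filtered["rt_ms"].mean()) if len(filtered) else np.nan,
                "accuracy": float(cell["correct"].mean()),
                "n_trials_used": len(filtered),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA table (one row per effect)."""

    table: pd.DataFrame  # effect, F, df_num, df_den, p, partial_eta_squared

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    factor_a: str = "condition",
    factor_b: str = "validity",
) -> AnovaResult:
    """Two-way fully within-subject ANOVA by sums-of-squares decomposition.

    Each effect is tested against its own effect-by-subject interaction
    (no sphericity correction; df are the uncorrected cell-structure values).
    partial eta squared = SS_effect / (SS_effect + SS_error).
    """
    cols = [subject, factor_a, factor_b, dv]
    d = data[cols].copy()
    subjects = d[subject].unique()
    a_levels = d[factor_a].unique()
    b_levels = d[factor_b].unique()
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if n < 2:
        raise ValueError("need at least 2 subjects")

    cell = d.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv, aggfunc="mean")
    expected = [(ai, bi) for ai in a_levels for bi in b_levels]
    missing = [c for c in expected if c not in cell.columns or cell[c].isna().any()]
    if missing:
        raise ValueError(f"missing design cells: {missing}")
    cell = cell.loc[subjects, expected]
    y = cell.to_numpy().reshape(n, a, b)  # subject x A x B

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        (f"{factor_a}:{factor_b}", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ]:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "F": float(F),
                "df_num": df_eff,
                "df_den": df_err,
                "p": p,
                "partial_eta_squared": float(pes),
            }
        )
    return AnovaResult(table=pd.DataFrame(rows))


@dataclass
class ContrastResult:
    t: float
    df: int
    p: float
    mean_diff: float


def paired_contrasts(values_a: Sequence[float], values_b: Sequence[float]) -> ContrastResult:
    """Two-sided paired t test on per-subject cell values (A minus B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("cell value vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects for a paired contrast")
    diff = a - b
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return ContrastResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(mean))


def paired_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of a two-sided paired t test via the noncentral t distribution."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = effect_size * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def paired_t_sample_size(
    effect_size: float, power: float = 0.8, alpha: float = 0.05, n_max: int = 10_000
) -> int:
    """Smallest n whose two-sided paired t test reaches the target power."""
    for n in range(2, n_max + 1):
        if paired_t_power(n, effect_size, alpha) >= power:
            return n
    raise ValueError("no sample size up to n_max reaches the requested power")
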