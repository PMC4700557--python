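"""Second-stage frequentist tests on posterior-mean parameter estimates.

The participant-level posterior means of each diffusion parameter are
treated as observations: 2x2 (language x stimulus type) within-subject
ANOVAs for intercepts and slopes, one-sample t-tests of the length slopes
against 0, and a paired t-test on the per-language boundary. Effect sizes
for ANOVA effects are generalized eta squared (subject-variance terms in
the denominator, so values are comparable across designs). All tests are
two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def rm_anova_2x2(
    values: pd.DataFrame,
    dv: str = "value",
    factor_a: str = "language",
    factor_b: str = "type",
    subject: str = "participant",
) -> pd.DataFrame:
    """Two-way fully-within-subject ANOVA on a complete 2x2 table.

    Returns one row per effect (A, B, A:B) with F, (1, n-1) dfs, p, and
    generalized eta squared. Computed by explicit sums of squares; each
    effect is tested against its own effect-by-subject interaction.
    """
    wide = values.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("need a complete 2x2 within-participant table")
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    n = wide.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")

    y = np.stack(
        [[wide[(a, b)].to_numpy() for b in b_levels] for a in a_levels]
    )  # (2, 2, n)
    grand = y.mean()
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_ab = y.mean(axis=2)
    m_s = y.mean(axis=(0, 1))
    m_as = y.mean(axis=1)  # (2, n)
    m_bs = y.mean(axis=0)  # (2, n)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_s = 4 * np.sum((m_s - grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[:, None] - m_s[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[:, None] - m_s[None, :] + grand) ** 2)
    ss_abs = np.sum(
        (
            y
            - m_ab[:, :, None]
            - m_as[:, None, :]
            - m_bs[None, :, :]
            + m_a[:, None, None]
            + m_b[None, :, None]
            + m_s[None, None, :]
            - grand
        )
        ** 2
    )

    df_err = n - 1
    denom_g = ss_s + ss_as + ss_bs + ss_abs
    # numerical zero: sums of squares are quadratic in the data scale
    tol = 1e-12 * max(float(np.sum((y - grand) ** 2)), np.finfo(float).tiny)
    rows = []
    for name, ss_eff, ss_err in (
        (factor_a, ss_a, ss_as),
        (factor_b, ss_b, ss_bs),
        (f"{factor_a}:{factor_b}", ss_ab, ss_abs),
    ):
        if ss_eff < tol:
            ss_eff = 0.0
        if ss_err < tol:
            F = 0.0 if ss_eff == 0 else np.inf
            p = 1.0 if ss_eff == 0 else 0.0
            warnings.warn(f"zero error variance for effect {name}")
        else:
            F = (ss_eff / 1) / (ss_err / df_err)
            p = float(stats.f.sf(F, 1, df_err))
        ges = ss_eff / (ss_eff + denom_g) if (ss_eff + denom_g) > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "statistic": "F",
                "value": float(F),
                "df1": 1,
                "df2": df_err,
                "p": p,
                "ges": float(ges),
            }
        )
    return pd.DataFrame(rows)


def one_sample_ttests_vs_zero(
    slopes: pd.DataFrame,
    dv: str = "value",
    by: tuple[str, ...] = ("language", "type"),
) -> pd.DataFrame:
    """Per condition, t = mean / (SD/sqrt(n)) against 0, df = n-1, two-sided."""
    rows = []
    for key, cell in slopes.groupby(list(by)):
        x = cell[dv].to_numpy(dtype=float)
        n = len(x)
        if n < 2:
            raise ValueError("need at least 2 observations per condition")
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        if x.std(ddof=1) <= 1e-12 * max(abs(x.mean()), 1.0):
            warnings.warn(f"zero variance in condition {key}; t undefined")
            row.update(
                statistic="t", value=np.nan, df1=np.nan, df2=n - 1, p=np.nan,
                mean=float(x.mean()), zero_variance=True,
            )
        else:
            t, p = stats.ttest_1samp(x, 0.0)
            row.update(
                statistic="t", value=float(t), df1=np.nan, df2=n - 1, p=float(p),
                mean=float(x.mean()), zero_variance=False,
            )
        row["effect"] = "slope_vs_0"
        rows.append(row)
    return pd.DataFrame(rows)


def paired_ttest(values_a: np.ndarray, values_b: np.ndarray, label: str = "paired") -> pd.DataFrame:
    """Paired t-test (one-sample test on within-participant differences)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if d.std(ddof=1) <= 1e-12 * max(abs(d.mean()), 1.0):
        if np.allclose(d, 0.0):
            row = dict(effect=label, statistic="t", value=0.0, df1=np.nan, df2=n - 1,
                       p=1.0, mean_difference=0.0, zero_variance=True)
        else:
            warnings.warn("constant nonzero differences; t undefined")
            row = dict(effect=label, statistic="t", value=np.nan, df1=np.nan, df2=n - 1,
                       p=np.nan, mean_difference=float(d.mean()), zero_variance=True)
        return pd.DataFrame([row])
    t, p = stats.ttest_rel(a, b)
    return pd.DataFrame(
        [
            dict(
                effect=label, statistic="t", value=float(t), df1=np.nan, df2=n - 1,
                p=float(p), mean_difference=float(d.mean()), zero_variance=False,
            )
        ]
    )


def posterior_inference(participant_means: pd.DataFrame) -> pd.DataFrame:
    """The full second-stage battery on a participant-level posterior-mean
    table (columns: participant, language, type, t0, t1, v0, v1, alpha).

    ANOVAs for t0, t1, v0, v1; slope t-tests for t1 and v1 per condition;
    paired t-test on alpha between language blocks.
    """
    frames = []
    for par in ("t0", "t1", "v0", "v1"):
        tab = rm_anova_2x2(
            participant_means.rename(columns={par: "value"})[
                ["participant", "language", "type", "value"]
            ]
        )
        tab.insert(0, "parameter", par)
        frames.append(tab)
    for par in ("t1", "v1"):
        tab = one_sample_ttests_vs_zero(
            participant_means.rename(columns={par: "value"})[
                ["participant", "language", "type", "value"]
            ]
        )
        tab.insert(0, "parameter", par)
        frames.append(tab)
    alpha = participant_means.pivot_table(index="participant", columns="language", values="alpha")
    tab = paired_ttest(
        alpha["german"].to_numpy(), alpha["english"].to_numpy(), label="alpha_german_vs_english"
    )
    tab.insert(0, "parameter", "alpha")
    frames.append(tab)
    return pd.concat(frames, ignore_index=True)
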