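"""Factor-wise 2x2 repeated-measures ANOVA and simple-effect contrasts.

Each retained factor's peak-amplitude table (one value per participant per
Constraint x Face cell) is decomposed classically: every within-subject
effect is tested against its own subject-by-effect interaction stratum, so
with two levels per factor each effect has df = (1, n-1).  Effect sizes are
partial eta squared, SS_effect / (SS_effect + SS_error).

Simple effects (e.g. the Face effect within each Constraint level) are
participant-wise contrasts of cell means: b is the mean contrast, the
standard error comes from the participant distribution of the contrast
(df = n-1), and p-values are Bonferroni-adjusted over the requested family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CONSTRAINT_LEVELS, FACE_LEVELS, DatasetError

__all__ = [
    "rm_anova_2x2",
    "partial_eta_sq",
    "simple_effect_contrasts",
    "DEFAULT_CONTRASTS",
]


def _cell_cube(cells: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Pivot a long CellTable into a (n, 2, 2) cube; checks completeness."""
    required = {"participant", "constraint", "face", "amplitude"}
    missing = required - set(cells.columns)
    if missing:
        raise DatasetError(f"cell table missing columns: {sorted(missing)}")
    participants = sorted(cells["participant"].unique())
    Y = np.full((len(participants), 2, 2), np.nan)
    pidx = {p: i for i, p in enumerate(participants)}
    aidx = {lev: i for i, lev in enumerate(CONSTRAINT_LEVELS)}
    bidx = {lev: i for i, lev in enumerate(FACE_LEVELS)}
    for _, row in cells.iterrows():
        Y[pidx[row["participant"]], aidx[row["constraint"]], bidx[row["face"]]] = row[
            "amplitude"
        ]
    if np.isnan(Y).any():
        holes = [
            (participants[i], CONSTRAINT_LEVELS[a], FACE_LEVELS[b])
            for i, a, b in zip(*np.nonzero(np.isnan(Y)))
        ]
        raise DatasetError(f"incomplete cell table; missing cells: {holes}")
    return Y, participants


def rm_anova_2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """Two-way (Constraint x Face) within-subject ANOVA on a complete table.

    Returns one row per effect with df, MSE, F, partial eta squared and p.
    """
    Y, participants = _cell_cube(cells)
    n = len(participants)
    if n < 2:
        raise DatasetError("need at least two participants")
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # subject
    m_a = Y.mean(axis=(0, 2))  # constraint
    m_b = Y.mean(axis=(0, 1))  # face
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_a = n * 2 * ((m_a - grand) ** 2).sum()
    ss_b = n * 2 * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = 2 * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = 2 * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = (resid**2).sum()

    rows = []
    df_err = n - 1
    for name, ss_eff, ss_err in (
        ("Constraint", ss_a, ss_sa),
        ("Face", ss_b, ss_sb),
        ("Constraint*Face", ss_ab, ss_sab),
    ):
        mse = ss_err / df_err
        if ss_err <= 0:
            warnings.warn(f"zero error SS for {name}; F undefined", stacklevel=2)
            F = np.nan if ss_eff > 0 else 0.0
            p = np.nan
            pes = np.nan
        else:
            F = (ss_eff / 1.0) / mse
            p = float(stats.f.sf(F, 1, df_err))
            pes = ss_eff / (ss_eff + ss_err)
        rows.append(
            dict(
                effect=name,
                df_effect=1,
                df_error=df_err,
                MSE=mse,
                F=F,
                pes=pes,
                p=p,
            )
        )
    return pd.DataFrame(rows)


def partial_eta_sq(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta squared recovered from an F statistic and its df.

    eta_p^2 = F * df_effect / (F * df_effect + df_error); the identity by
    which effect sizes can be recomputed from printed ANOVA tables.
    """
    if F < 0:
        raise DatasetError("F statistic must be non-negative")
    return float(F * df_effect / (F * df_effect + df_error))


#: default simple-effect family: Face effect within each Constraint level
DEFAULT_CONTRASTS = (
    ("Face|HC", {("HC", "Face"): 1.0, ("HC", "NoFace"): -1.0}),
    ("Face|LC", {("LC", "Face"): 1.0, ("LC", "NoFace"): -1.0}),
)


def simple_effect_contrasts(
    cells: pd.DataFrame,
    contrasts=DEFAULT_CONTRASTS,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-adjusted participant-wise contrasts of the 2x2 cell means.

    Each contrast is a zero-sum weighting of the four (constraint, face)
    cells.  The family defaults to the set of contrasts in the call.
    """
    Y, participants = _cell_cube(cells)
    n = len(participants)
    fam = family_size if family_size is not None else len(contrasts)
    aidx = {lev: i for i, lev in enumerate(CONSTRAINT_LEVELS)}
    bidx = {lev: i for i, lev in enumerate(FACE_LEVELS)}
    rows = []
    for name, weights in contrasts:
        if abs(sum(weights.values())) > 1e-12:
            raise DatasetError(f"contrast {name!r} weights do not sum to zero")
        v = np.zeros(n)
        for (con, fac), w in weights.items():
            v += w * Y[:, aidx[con], bidx[fac]]
        b = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(n))
        if se == 0:
            t = 0.0 if b == 0 else np.inf * np.sign(b)
            p_raw = 1.0 if b == 0 else 0.0
        else:
            t = b / se
            p_raw = float(2 * stats.t.sf(abs(t), n - 1))
        rows.append(
            dict(
                contrast=name,
                estimate=b,
                se=se,
                t_ratio=t,
                df=n - 1,
                p_raw=p_raw,
                p_adj=min(1.0, fam * p_raw),
                family_size=fam,
            )
        )
    return pd.DataFrame(rows)
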