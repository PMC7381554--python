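"""Fixed-effects meta-regression over per-pair treatment effect sizes.

Each screened host-parasite pair contributes one effect size: the log-scale
treatment coefficient ``y`` from its NB (mixed) model with variance
``v = SE^2``.  The cumulative effect is the inverse-variance weighted mean;
moderator models are weighted least squares with known weights ``1/v``,

    b = (X' W X)^{-1} X' W y,    Cov(b) = (X' W X)^{-1},

with the residual heterogeneity statistic ``Q_T = (y - Xb)' W (y - Xb)``
on ``k - p`` degrees of freedom and the moderator omnibus ``Q_M`` a Wald
chi-square that all non-intercept coefficients vanish (``p - 1`` df).

Two standard moderator codings are provided: life stage + taxonomic group
(treatment contrasts, reference adult acanthocephalans) and organ location
(non-exclusive presence/absence dummies, reference muscle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, RankDeficientError
from .synthetic_data import GROUPS, ORGANS, STAGES

#: Table-style column orders for the two moderator models
MODEL1_COLUMNS = (
    "intercept",
    "stage[larva]",
    "group[Cestoda]",
    "group[Hirudinea]",
    "group[Nematoda]",
    "group[Trematoda]",
)
#: organ order of the location model; muscle is the intercept/reference
MODEL2_ORGAN_ORDER = (
    "body_cavity",
    "pyloric_ceca",
    "stomach",
    "intestine",
    "kidney",
    "heart",
    "fins",
    "liver",
    "gonad",
    "gills",
    "eye",
    "buccal_cavity",
)
MODEL2_COLUMNS = ("intercept",) + tuple(
    f"location[{o}]" for o in MODEL2_ORGAN_ORDER
)


@dataclass(frozen=True)
class EffectSize:
    """One pair's treatment effect: log-scale coefficient, variance and
    moderator labels."""

    pair_id: str
    y: float
    v: float
    stage: str
    group: str
    organs: frozenset

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise InvalidInputError(f"{self.pair_id}: effect variance must be > 0")
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        bad = set(self.organs) - set(ORGANS)
        if bad:
            raise InvalidInputError(f"unknown organs {sorted(bad)}")
        if not self.organs:
            raise InvalidInputError(f"{self.pair_id}: needs at least one organ")


@dataclass
class MetaFit:
    """Meta-regression output: per-term table plus Q statistics."""

    coefficients: dict
    standard_errors: dict
    z_values: dict
    p_values: dict
    QT: float
    df_QT: int
    p_QT: float
    QM: float
    df_QM: int
    p_QM: float
    k_effects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "estimate": list(self.coefficients.values()),
                "se": [self.standard_errors[t] for t in self.coefficients],
                "z": [self.z_values[t] for t in self.coefficients],
                "p": [self.p_values[t] for t in self.coefficients],
            }
        )


def _effects_arrays(effects: Sequence[EffectSize]) -> tuple:
    if not effects:
        raise InvalidInputError("no effect sizes supplied")
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def cumulative_effect(effects: Sequence[EffectSize]) -> MetaFit:
    """Inverse-variance weighted mean effect (intercept-only model)."""
    y, v = _effects_arrays(effects)
    w = 1.0 / v
    beta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    qt = float(np.sum(w * (y - beta) ** 2))
    df = len(y) - 1
    p_qt = float(stats.chi2.sf(qt, df)) if df > 0 else math.nan
    return MetaFit(
        coefficients={"intercept": beta},
        standard_errors={"intercept": se},
        z_values={"intercept": z},
        p_values={"intercept": p},
        QT=qt,
        df_QT=df,
        p_QT=p_qt,
        QM=math.nan,
        df_QM=0,
        p_QM=math.nan,
        k_effects=len(y),
    )


def meta_glm(effects: Sequence[EffectSize], design: pd.DataFrame) -> MetaFit:
    """Fixed-effects meta-regression by weighted least squares.

    ``design`` must contain an ``intercept`` column plus moderator columns;
    rows align with ``effects``.  Rank deficiency (e.g. an empty moderator
    level) raises with the aliased column named.
    """
    y, v = _effects_arrays(effects)
    if len(design) != len(y):
        raise InvalidInputError("design rows must match the number of effects")
    names = [str(c) for c in design.columns]
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise RankDeficientError(
                    f"moderator design is rank deficient: column "
                    f"{names[j - 1]!r} is aliased"
                )
    w = 1.0 / v
    XtW = X.T * w
    fisher = XtW @ X
    beta = np.linalg.solve(fisher, XtW @ y)
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))

    resid = y - X @ beta
    qt = float(np.sum(w * resid**2))
    df_qt = len(y) - X.shape[1]
    p_qt = float(stats.chi2.sf(qt, df_qt)) if df_qt > 0 else math.nan

    mod_idx = [j for j, n in enumerate(names) if n != "intercept"]
    df_qm = len(mod_idx)
    if df_qm:
        b_m = beta[mod_idx]
        cov_m = cov[np.ix_(mod_idx, mod_idx)]
        qm = float(b_m @ np.linalg.solve(cov_m, b_m))
        p_qm = float(stats.chi2.sf(qm, df_qm))
    else:
        qm, p_qm = math.nan, math.nan

    return MetaFit(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        z_values=dict(zip(names, z.tolist())),
        p_values=dict(zip(names, p.tolist())),
        QT=qt,
        df_QT=df_qt,
        p_QT=p_qt,
        QM=qm,
        df_QM=df_qm,
        p_QM=p_qm,
        k_effects=len(y),
    )


def encode_model1(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Life-stage + taxonomic-group design (treatment contrasts).

    Reference cell: adult acanthocephalans; columns follow the published
    coefficient layout (intercept, stage[larva], then groups in
    alphabetical order after the reference).
    """
    rows = []
    for e in effects:
        rows.append(
            {
                "intercept": 1.0,
                "stage[larva]": 1.0 if e.stage == "larva" else 0.0,
                "group[Cestoda]": 1.0 if e.group == "Cestoda" else 0.0,
                "group[Hirudinea]": 1.0 if e.group == "Hirudinea" else 0.0,
                "group[Nematoda]": 1.0 if e.group == "Nematoda" else 0.0,
                "group[Trematoda]": 1.0 if e.group == "Trematoda" else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=list(MODEL1_COLUMNS))


def encode_model2(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Organ-location design: non-exclusive 0/1 dummies, muscle reference.

    A pair recorded in several organs sets several indicators; a pair with
    no organs raises.
    """
    rows = []
    for e in effects:
        if not e.organs:
            raise InvalidInputError(f"{e.pair_id}: all organ flags are false")
        row = {"intercept": 1.0}
        for organ in MODEL2_ORGAN_ORDER:
            row[f"location[{organ}]"] = 1.0 if organ in e.organs else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=list(MODEL2_COLUMNS))


def read_effects_csv(path) -> list:
    """Read an effects table: pair_id, y, v, stage, group, 13 organ flags."""
    df = pd.read_csv(path)
    required = {"pair_id", "y", "v", "stage", "group"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"effects CSV missing columns {sorted(missing)}")
    effects = []
    for _, row in df.iterrows():
        organs = frozenset(o for o in ORGANS if o in df.columns and bool(row[o]))
        effects.append(
            EffectSize(
                pair_id=str(row["pair_id"]),
                y=float(row["y"]),
                v=float(row["v"]),
                stage=str(row["stage"]),
                group=str(row["group"]),
                organs=organs,
            )
        )
    return effects


def effects_to_frame(effects: Iterable[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        row = {
            "pair_id": e.pair_id,
            "y": e.y,
            "v": e.v,
            "stage": e.stage,
            "group": e.group,
        }
        for o in ORGANS:
            row[o] = int(o in e.organs)
        rows.append(row)
    return pd.DataFrame(rows)


def meta_fit_to_csv(fit: MetaFit, path) -> None:
    """Write a coefficient table with Q_T/Q_M footer rows."""
    table = fit.to_frame()
    footer = pd.DataFrame(
        {
            "term": ["Q_T", "Q_M"],
            "estimate": [fit.QT, fit.QM],
            "df": [fit.df_QT, fit.df_QM],
            "p": [fit.p_QT, fit.p_QM],
        }
    )
    pd.concat([table, footer], ignore_index=True).to_csv(path, index=False)
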