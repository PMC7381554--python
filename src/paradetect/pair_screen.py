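"""Per host-parasite pair screening of the preservation effect.

Pipeline: pool both treatment arms to summarize each pair's prevalence and
mean abundance; retain pairs with prevalence strictly above the screening
threshold (5% by default); fit an NB model of counts on treatment + host
standard length per retained pair (with a tow random intercept for English
sole, whose specimens came from multiple trawl tows); Bonferroni-correct
the treatment p-values across all retained pairs jointly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, ModelFitError
from .nb_models import ModelFit, fit_lmm, fit_nb_glm, fit_nb_glmm
from .synthetic_data import validate_counts_table


@dataclass
class PairResult:
    """Screening outcome for one host-parasite pair."""

    taxon: str
    host_species: str
    prevalence: float
    mean_abundance: float
    se_mean_abundance: float
    treatment_estimate: float
    treatment_se: float
    treatment_z: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    direction: str  # higher_in_preserved / lower_in_preserved / none
    converged: bool
    group: str | None = None
    stage: str | None = None
    organs: frozenset = frozenset()

    @property
    def pair_id(self) -> str:
        return f"{self.host_species}:{self.taxon}"


def summarize_pairs(counts: pd.DataFrame) -> pd.DataFrame:
    """Prevalence, mean abundance and its SE per (host, taxon), pooling
    treatments and counting zero-count hosts."""
    validate_counts_table(counts)
    if counts.empty:
        raise InvalidInputError("empty counts table")

    def agg(sub: pd.DataFrame) -> pd.Series:
        y = sub["count"].to_numpy(dtype=float)
        n = len(y)
        sd = y.std(ddof=1) if n > 1 else 0.0
        return pd.Series(
            {
                "prevalence": float((y > 0).mean()),
                "mean_abundance": float(y.mean()),
                "se_mean_abundance": float(sd / math.sqrt(n)) if n else 0.0,
                "n_hosts": n,
            }
        )

    out = (
        counts.groupby(["host_species", "taxon"] if "host_species" in counts else ["species", "taxon"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out = out.rename(columns={"species": "host_species"})
    out["n_hosts"] = out["n_hosts"].astype(int)
    return out


def prevalence_filter(
    summaries: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Retain pairs with prevalence strictly greater than ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    retained = summaries[summaries["prevalence"] > threshold].reset_index(drop=True)
    retained.attrs["m"] = len(retained)
    return retained


def bonferroni_z_threshold(m: int, alpha: float = 0.05) -> float:
    """Two-sided |z| cut-off after Bonferroni correction over ``m`` pairs."""
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return float(stats.norm.ppf(1.0 - alpha / (2.0 * m)))


def _fit_pair(sub: pd.DataFrame) -> ModelFit:
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "treatment": (sub["treatment"] == "preserved").astype(float),
            "standard_length_mm": sub["standard_length_mm"].astype(float),
        },
        index=sub.index,
    )
    tows = sub["tow_id"] if "tow_id" in sub else pd.Series(dtype=object)
    use_glmm = (
        sub["species"].iloc[0] == "english_sole"
        and tows.notna().all()
        and tows.nunique() >= 2
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_glmm:
            return fit_nb_glmm(sub["count"].to_numpy(), design, tows)
        return fit_nb_glm(sub["count"].to_numpy(), design)


def screen_all(
    counts: pd.DataFrame,
    threshold: float = 0.05,
    alpha: float = 0.05,
) -> list:
    """Run the full per-pair screen; returns a list of PairResult.

    The Bonferroni family is all retained pairs across species jointly
    (``m`` = retained count); non-converged fits stay in the family but are
    reported non-significant.
    """
    validate_counts_table(counts)
    summaries = summarize_pairs(counts)
    retained = prevalence_filter(summaries, threshold)
    m = len(retained)
    results: list = []
    for _, row in retained.iterrows():
        sub = counts[
            (counts["species"] == row["host_species"])
            & (counts["taxon"] == row["taxon"])
        ]
        try:
            fit = _fit_pair(sub)
            est = fit.coefficients["treatment"]
            se = fit.standard_errors["treatment"]
            z = fit.z_values["treatment"]
            p_raw = fit.p_values["treatment"]
            converged = fit.converged and math.isfinite(p_raw)
        except (ModelFitError, InvalidInputError):
            est = se = z = math.nan
            p_raw = 1.0
            converged = False
        p_bonf = min(1.0, m * p_raw) if math.isfinite(p_raw) else 1.0
        significant = bool(converged and p_bonf < alpha)
        if significant:
            direction = "higher_in_preserved" if est > 0 else "lower_in_preserved"
        else:
            direction = "none"
        positive = sub[sub["count"] > 0]
        organs = (
            frozenset(positive["organ"].dropna().unique())
            if "organ" in sub
            else frozenset()
        )
        results.append(
            PairResult(
                taxon=row["taxon"],
                host_species=row["host_species"],
                prevalence=row["prevalence"],
                mean_abundance=row["mean_abundance"],
                se_mean_abundance=row["se_mean_abundance"],
                treatment_estimate=est,
                treatment_se=se,
                treatment_z=z,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=significant,
                direction=direction,
                converged=converged,
                group=sub["group"].iloc[0] if "group" in sub else None,
                stage=sub["stage"].iloc[0] if "stage" in sub else None,
                organs=organs,
            )
        )
    return results


def results_to_frame(results: Sequence[PairResult]) -> pd.DataFrame:
    """Tidy per-pair table (screening CSV with z-scores and calls)."""
    return pd.DataFrame(
        {
            "host_species": [r.host_species for r in results],
            "taxon": [r.taxon for r in results],
            "prevalence": [r.prevalence for r in results],
            "mean_abundance": [r.mean_abundance for r in results],
            "se_mean_abundance": [r.se_mean_abundance for r in results],
            "treatment_estimate": [r.treatment_estimate for r in results],
            "treatment_se": [r.treatment_se for r in results],
            "z": [r.treatment_z for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
            "converged": [r.converged for r in results],
        }
    )


def length_balance(specimens: pd.DataFrame) -> dict:
    """Per-species check that randomization balanced standard length.

    Fits a Gaussian (mixed) model of length on treatment per species, with
    a tow random intercept where tow identifiers exist.  Returns a mapping
    species -> ModelFit (t statistics with residual df).
    """
    required = {"species", "standard_length_mm", "treatment"}
    if not required <= set(specimens.columns):
        raise InvalidInputError(f"need columns {sorted(required)}")
    out: dict = {}
    for sp, sub in specimens.groupby("species", sort=False):
        if len(sub) < 2:
            raise InvalidInputError(f"need >= 2 fish for species {sp}")
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "treatment": (sub["treatment"] == "preserved").astype(float),
            },
            index=sub.index,
        )
        groups = None
        if "tow_id" in sub and sub["tow_id"].notna().all():
            groups = sub["tow_id"]
        out[sp] = fit_lmm(
            sub["standard_length_mm"].to_numpy(), design, groups
        )
    return out
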