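"""End-to-end orchestration: cohort -> balance check -> screen -> meta.

`run_full_pipeline` wires the stages together under one master seed, writes
the per-stage CSV outputs into an output directory and records a manifest
(seed, parameters, per-stage record counts, content hashes).  Identical
configurations and seeds produce identical content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .errors import InvalidInputError, ParadetectError
from .literature_summary import read_study_lengths, summarize_lengths
from .meta_regression import (
    EffectSize,
    cumulative_effect,
    encode_model1,
    encode_model2,
    meta_fit_to_csv,
    meta_glm,
)
from .pair_screen import length_balance, results_to_frame, screen_all
from .synthetic_data import (
    COUNTS_COLUMNS,
    SPECIES,
    load_default_profiles,
    simulate_cohort,
    validate_counts_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    profile_file: str | None = None
    n_per_treatment: Mapping | int | None = None
    prevalence_threshold: float = 0.05
    alpha: float = 0.05
    sigma_tow: float = 0.25
    n_tows: int = 7
    output_dir: str = "paradetect_output"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_threshold < 1.0:
            raise InvalidInputError("prevalence_threshold must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must be in (0, 1)")


def load_study_csv(path, column_map: Mapping | None = None) -> pd.DataFrame:
    """Load a long-format dissection CSV into a validated counts table.

    ``column_map`` renames source columns to the canonical header (e.g.
    ``{"fish_id": "specimen_id"}``) so deposits with a different schema can
    be adapted.  Extra columns are kept but ignored (with a warning);
    missing required columns or non-integer counts raise with the
    offending rows named.
    """
    import warnings

    df = pd.read_csv(path, dtype={"tow_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"specimen_id", "species", "standard_length_mm", "treatment",
                "taxon", "count"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing required columns {sorted(missing)}")
    extras = set(df.columns) - set(COUNTS_COLUMNS)
    if extras:
        warnings.warn(f"ignoring extra columns {sorted(extras)}", stacklevel=2)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != counts.round())]
    if len(bad):
        raise InvalidInputError(
            f"non-integer or negative counts at rows {bad.tolist()[:10]}"
        )
    df["count"] = counts.astype(int)
    unknown = df.index[~df["species"].isin(SPECIES)]
    if len(unknown):
        raise InvalidInputError(
            f"unknown species at rows {unknown.tolist()[:10]}"
        )
    validate_counts_table(df)
    logger.info("loaded %d rows, %d specimens, %d taxa", len(df),
                df["specimen_id"].nunique(), df["taxon"].nunique())
    return df


def _effects_from_results(results) -> list:
    effects = []
    for r in results:
        if not r.converged or not math.isfinite(r.treatment_se) or r.treatment_se <= 0:
            continue
        if r.group is None or r.stage is None or not r.organs:
            continue
        effects.append(
            EffectSize(
                pair_id=r.pair_id,
                y=r.treatment_estimate,
                v=r.treatment_se**2,
                stage=r.stage,
                group=r.group,
                organs=r.organs,
            )
        )
    return effects


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(
    config: PipelineConfig, counts: pd.DataFrame | None = None
) -> dict:
    """Run simulate -> length balance -> screen -> meta and write outputs.

    If ``counts`` is given it is used instead of simulating a cohort.
    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure raises with the stage name; outputs written before the
    failure are left on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "prevalence_threshold": config.prevalence_threshold,
            "alpha": config.alpha,
            "sigma_tow": config.sigma_tow,
            "n_tows": config.n_tows,
        },
        "stages": {},
        "outputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                _write_manifest(manifest, out)
                raise ParadetectError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)
            return result
        return deco

    @stage("simulate")
    def counts_table():
        if counts is not None:
            return validate_counts_table(counts)
        profiles = load_default_profiles(config.profile_file)
        return simulate_cohort(
            profiles,
            n_per_treatment=config.n_per_treatment,
            n_tows=config.n_tows,
            sigma_tow=config.sigma_tow,
            seed=config.seed,
        )

    counts_path = out / "cohort_counts.csv"
    counts_table.to_csv(counts_path, index=False)
    manifest["stages"]["simulate"]["n_rows"] = len(counts_table)

    @stage("length_balance")
    def balance():
        specimens = counts_table.drop_duplicates("specimen_id")
        fits = length_balance(specimens)
        rows = []
        for sp, fit in fits.items():
            rows.append(
                {
                    "species": sp,
                    "estimate": fit.coefficients["treatment"],
                    "se": fit.standard_errors["treatment"],
                    "t": fit.z_values["treatment"],
                    "df": fit.df_resid,
                    "p": fit.p_values["treatment"],
                }
            )
        return pd.DataFrame(rows)

    balance.to_csv(out / "length_balance.csv", index=False)
    manifest["stages"]["length_balance"]["n_species"] = len(balance)

    @stage("screen")
    def screen_results():
        return screen_all(
            counts_table,
            threshold=config.prevalence_threshold,
            alpha=config.alpha,
        )

    screen_frame = results_to_frame(screen_results)
    screen_frame.to_csv(out / "pair_screen.csv", index=False)
    manifest["stages"]["screen"]["n_retained"] = len(screen_results)
    manifest["stages"]["screen"]["n_significant"] = int(
        screen_frame["significant"].sum()
    )

    effects = _effects_from_results(screen_results)
    if not effects:
        manifest["stages"]["meta"] = {"skipped": "no usable effect sizes"}
        logger.warning("meta stage skipped: no usable effect sizes")
    else:
        @stage("meta")
        def meta_outputs():
            overall = cumulative_effect(effects)
            meta_fit_to_csv(overall, out / "meta_cumulative.csv")
            res = {"k_effects": len(effects)}
            try:
                m1 = meta_glm(effects, encode_model1(effects))
                meta_fit_to_csv(m1, out / "meta_model1_stage_group.csv")
                res["model1_df_QT"] = m1.df_QT
            except InvalidInputError as exc:
                logger.warning("stage/group model skipped: %s", exc)
            try:
                m2 = meta_glm(effects, encode_model2(effects))
                meta_fit_to_csv(m2, out / "meta_model2_organs.csv")
                res["model2_df_QT"] = m2.df_QT
            except InvalidInputError as exc:
                logger.warning("organ model skipped: %s", exc)
            return res

        manifest["stages"]["meta"].update(meta_outputs)

    @stage("litsummary")
    def lit():
        summary = summarize_lengths(read_study_lengths())
        pd.DataFrame([summary]).to_csv(out / "literature_summary.csv",
                                       index=False)
        return summary

    manifest["stages"]["litsummary"]["n_studies"] = lit["n"]

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _hash_file(f)
    manifest["content_hash"] = hashlib.sha256(
        json.dumps(manifest["outputs"], sort_keys=True).encode()
    ).hexdigest()
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
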