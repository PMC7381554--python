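"""Synthetic fish cohorts with negative-binomial parasite burdens.

This module generates per-specimen parasite-count tables with the
statistical structure the downstream screening, meta-regression and power
analyses assume: each host-parasite pair has a target prevalence (fraction
of hosts infected) and mean abundance (parasites per host, zeros included),
reconciled into a single NB2 law (variance mu + mu^2/k) by calibrating the
dispersion k from the NB zero-probability identity

    P(X = 0) = (k / (k + mu))^k.

Treatments act multiplicatively on the mean (a log-scale coefficient), host
standard length enters through a log-scale slope, and English sole counts
may receive a shared tow-level Gaussian random intercept.  Treatment labels
come from length-stratified pair randomization: fish are sorted by length,
paired off, and one member of each pair goes to the preservation treatment
by a fair coin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .errors import InvalidInputError

SPECIES = ("pollock", "eulachon", "english_sole")

GROUPS = ("Nematoda", "Trematoda", "Cestoda", "Acanthocephala", "Hirudinea")

STAGES = ("adult", "larva")

#: the thirteen host tissues examined at dissection
ORGANS = (
    "body_cavity",
    "buccal_cavity",
    "heart",
    "gills",
    "stomach",
    "intestine",
    "pyloric_ceca",
    "fins",
    "muscle",
    "liver",
    "kidney",
    "gonad",
    "eye",
)

#: column layout of the long-format counts CSV
COUNTS_COLUMNS = (
    "specimen_id",
    "species",
    "standard_length_mm",
    "treatment",
    "tow_id",
    "taxon",
    "group",
    "stage",
    "organ",
    "count",
)

K_POISSON = math.inf


@dataclass(frozen=True)
class SpecimenRecord:
    """One fish: identity, species, size, treatment arm and (sole only) tow."""

    specimen_id: str
    species: str
    standard_length_mm: float
    treatment: str
    tow_id: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidInputError(f"unknown species {self.species!r}")
        if self.treatment not in ("control", "preserved"):
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")
        if not (self.standard_length_mm > 0):
            raise InvalidInputError("standard_length_mm must be positive")
        has_tow = self.tow_id is not None
        if has_tow != (self.species == "english_sole"):
            raise InvalidInputError(
                "tow_id must be present exactly for english_sole specimens"
            )


@dataclass(frozen=True)
class TaxonProfile:
    """Generative parameters for one host-parasite pair.

    ``prevalence_target`` and ``mean_abundance_target`` are the pooled
    (both-treatment) summaries the pair should reproduce at
    ``treatment_log_ratio = 0``; ``dispersion_k`` is the NB2 size parameter
    (``math.inf`` means Poisson), and ``poisson_fallback`` flags profiles
    whose prevalence target is unattainable under NB overdispersion.
    """

    taxon: str
    host_species: str
    group: str
    stage: str
    organs: frozenset
    prevalence_target: float
    mean_abundance_target: float
    dispersion_k: float = K_POISSON
    treatment_log_ratio: float = 0.0
    length_slope: float = 0.0
    poisson_fallback: bool = False

    def __post_init__(self) -> None:
        if self.host_species not in SPECIES:
            raise InvalidInputError(f"unknown species {self.host_species!r}")
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        bad = set(self.organs) - set(ORGANS)
        if bad:
            raise InvalidInputError(f"unknown organ labels {sorted(bad)}")
        if not self.organs:
            raise InvalidInputError("profile needs at least one organ")
        if not 0.0 <= self.prevalence_target <= 1.0:
            raise InvalidInputError("prevalence_target must lie in [0, 1]")
        if self.mean_abundance_target < 0:
            raise InvalidInputError("mean_abundance_target must be >= 0")
        if self.mean_abundance_target == 0 and self.prevalence_target > 0:
            raise InvalidInputError("zero mean abundance forces zero prevalence")
        if not self.dispersion_k > 0:
            raise InvalidInputError("dispersion_k must be positive")

    @classmethod
    def calibrated(cls, **kwargs) -> "TaxonProfile":
        """Build a profile with ``dispersion_k`` solved from the targets."""
        prev = kwargs["prevalence_target"]
        mean = kwargs["mean_abundance_target"]
        if mean == 0 or prev == 0:
            return cls(dispersion_k=K_POISSON, **kwargs)
        k = calibrate_dispersion(prev, mean)
        return cls(
            dispersion_k=k, poisson_fallback=not math.isfinite(k), **kwargs
        )

    @property
    def pair_id(self) -> str:
        return f"{self.host_species}:{self.taxon}"


@dataclass(frozen=True)
class LengthDistribution:
    """Per-species standard-length model: uniform on [min, max], recentred
    so the sample mean targets ``mean_mm``."""

    min_mm: float
    max_mm: float
    mean_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.min_mm <= self.max_mm:
            raise InvalidInputError("need 0 < min_mm <= max_mm")
        if not self.min_mm * 0.5 <= self.mean_mm <= self.max_mm * 1.5:
            raise InvalidInputError("mean_mm inconsistent with range")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = rng.uniform(self.min_mm, self.max_mm, size=n)
        shift = self.mean_mm - 0.5 * (self.min_mm + self.max_mm)
        return np.maximum(draws + shift, 1.0)


#: study-scale defaults: length ranges/means and total fish per species
DEFAULT_LENGTHS: dict = {
    "pollock": LengthDistribution(87.0, 225.0, 146.0),
    "eulachon": LengthDistribution(113.0, 205.0, 167.0),
    "english_sole": LengthDistribution(81.0, 240.0, 155.0),
}
DEFAULT_N_PER_TREATMENT: dict = {"pollock": 55, "eulachon": 35, "english_sole": 50}


def calibrate_dispersion(prevalence: float, mean: float) -> float:
    """Solve the NB2 size ``k`` reconciling a prevalence/mean target pair.

    Finds ``k`` with ``1 - (k/(k+mean))^k = prevalence`` by root-finding on
    ``log k``.  The NB zero probability decreases from 1 (k -> 0) to
    ``exp(-mean)`` (Poisson limit), so prevalence targets above
    ``1 - exp(-mean)`` are unattainable under overdispersion: those return
    ``inf`` with a warning and the caller should flag the profile.
    """
    if not (math.isfinite(prevalence) and math.isfinite(mean)):
        raise InvalidInputError("prevalence and mean must be finite")
    if not (0.0 < prevalence < 1.0) or mean <= 0:
        raise InvalidInputError("need 0 < prevalence < 1 and mean > 0")
    log_p0 = math.log1p(-prevalence)
    if log_p0 <= -mean:  # prevalence >= Poisson prevalence
        if not math.isclose(log_p0, -mean, rel_tol=1e-12):
            warnings.warn(
                f"prevalence {prevalence:.4f} exceeds the Poisson bound "
                f"1-exp(-{mean:.4f}); falling back to Poisson counts",
                stacklevel=2,
            )
        return K_POISSON

    def gap(log_k: float) -> float:
        k = math.exp(log_k)
        return k * (log_k - math.log(k + mean)) - log_p0

    lo, hi = math.log(1e-8), math.log(1e10)
    return math.exp(brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14))


def stratified_pair_assignment(
    lengths: Sequence[float], seed: int | np.random.Generator
) -> list:
    """Length-stratified pair randomization into control/preserved arms.

    Fish are sorted by length and consecutive pairs formed; within each
    pair a fair coin sends one fish to the preservation treatment and the
    other to the control.  With an odd count the leftover (longest) fish is
    assigned by an independent coin toss.  Group sizes per call therefore
    differ by at most one.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 2:
        raise InvalidInputError("need at least two fish to pair")
    rng = np.random.default_rng(seed)
    order = np.argsort(lengths, kind="stable")
    labels = np.empty(lengths.size, dtype=object)
    n_pairs = lengths.size // 2
    coins = rng.integers(0, 2, size=n_pairs + (lengths.size % 2))
    for p in range(n_pairs):
        i, j = order[2 * p], order[2 * p + 1]
        if coins[p]:
            labels[i], labels[j] = "preserved", "control"
        else:
            labels[i], labels[j] = "control", "preserved"
    if lengths.size % 2:
        labels[order[-1]] = "preserved" if coins[-1] else "control"
    return labels.tolist()


def _resolve_per_species(value, default: Mapping, what: str) -> dict:
    if value is None:
        return dict(default)
    if isinstance(value, Mapping):
        bad = set(value) - set(SPECIES)
        if bad:
            raise InvalidInputError(f"unknown species in {what}: {sorted(bad)}")
        out = dict(default)
        out.update(value)
        return out
    return {sp: value for sp in SPECIES}


def simulate_specimens(
    species_n: Mapping,
    length_params: Mapping,
    n_tows: int,
    rng: np.random.Generator,
) -> list:
    """Draw specimens with lengths, stratified treatment labels and tows."""
    specimens: list = []
    for sp in SPECIES:
        n = int(species_n.get(sp, 0))
        if n == 0:
            continue
        lengths = length_params[sp].sample(n, rng)
        labels = stratified_pair_assignment(lengths, rng)
        tows = None
        if sp == "english_sole":
            tows = rng.integers(0, n_tows, size=n)
        for i in range(n):
            specimens.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_{i + 1:03d}",
                    species=sp,
                    standard_length_mm=float(lengths[i]),
                    treatment=labels[i],
                    tow_id=None if tows is None else f"tow_{tows[i] + 1}",
                )
            )
    return specimens


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    if not np.all(np.isfinite(mu)):
        raise InvalidInputError("non-finite NB mean")
    if math.isinf(k):
        return rng.poisson(mu)
    # NB2: Poisson-gamma mixture keeps the mean exact for heterogeneous mu
    lam = rng.gamma(shape=k, scale=mu / k)
    return rng.poisson(lam)


def simulate_cohort(
    profiles: Iterable[TaxonProfile],
    n_per_treatment: int | Mapping | None = None,
    length_params: Mapping | None = None,
    n_tows: int = 7,
    sigma_tow: float = 0.25,
    seed: int | np.random.Generator = 0,
    dropout: float = 0.0,
) -> pd.DataFrame:
    """Simulate a long-format counts table for one experimental cohort.

    For each specimen and profile the count is NB2 with log-mean

        log(mu_control) + treatment_log_ratio * 1{preserved}
        + length_slope * (length - mean length) + tow intercept,

    where the control mean is set so the pooled two-arm mean matches the
    profile's ``mean_abundance_target`` and tow intercepts ~ N(0,
    sigma_tow^2) apply to English sole only.  Each row is labelled with one
    organ sampled uniformly from the profile's organ set.  ``dropout``
    removes that fraction of fish after randomization (default 0).
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    length_params = {**DEFAULT_LENGTHS, **(length_params or {})}

    per_treat = _resolve_per_species(
        n_per_treatment, DEFAULT_N_PER_TREATMENT, "n_per_treatment"
    )
    wanted = {p.host_species for p in profiles}
    species_n = {sp: 2 * per_treat[sp] for sp in SPECIES if sp in wanted}
    if any(n < 2 for n in species_n.values()):
        raise InvalidInputError("n_per_treatment must be >= 1")

    specimens = simulate_specimens(species_n, length_params, n_tows, rng)
    if dropout > 0:
        keep = rng.random(len(specimens)) >= dropout
        specimens = [s for s, kp in zip(specimens, keep) if kp]

    tow_effects = rng.normal(0.0, sigma_tow, size=n_tows) if sigma_tow > 0 else np.zeros(n_tows)

    frames = []
    by_species: dict = {}
    for s in specimens:
        by_species.setdefault(s.species, []).append(s)

    for prof in profiles:
        hosts = by_species.get(prof.host_species, [])
        if not hosts:
            continue
        lengths = np.array([s.standard_length_mm for s in hosts])
        treated = np.array([s.treatment == "preserved" for s in hosts])
        mean_len = length_params[prof.host_species].mean_mm
        r = prof.treatment_log_ratio
        mu_control = 2.0 * prof.mean_abundance_target / (1.0 + math.exp(r))
        eta = (
            math.log(mu_control) if mu_control > 0 else -math.inf
        ) + r * treated + prof.length_slope * (lengths - mean_len)
        if prof.host_species == "english_sole":
            tow_idx = np.array([int(s.tow_id.split("_")[1]) - 1 for s in hosts])
            eta = eta + tow_effects[tow_idx]
        if prof.mean_abundance_target == 0:
            counts = np.zeros(len(hosts), dtype=int)
        else:
            counts = _nb_draw(rng, np.exp(eta), prof.dispersion_k)
        organ_pool = sorted(prof.organs)
        organs = rng.choice(organ_pool, size=len(hosts))
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": [s.specimen_id for s in hosts],
                    "species": prof.host_species,
                    "standard_length_mm": lengths,
                    "treatment": [s.treatment for s in hosts],
                    "tow_id": [s.tow_id for s in hosts],
                    "taxon": prof.taxon,
                    "group": prof.group,
                    "stage": prof.stage,
                    "organ": organs,
                    "count": counts,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[list(COUNTS_COLUMNS)]


def validate_counts_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format invariants; returns the table unchanged."""
    # tow_id may legitimately be absent for cohorts without english_sole
    required = {"specimen_id", "species", "standard_length_mm", "treatment",
                "taxon", "count"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"counts table missing columns {sorted(missing)}")
    if df.duplicated(["specimen_id", "taxon"]).any():
        raise InvalidInputError("duplicate (specimen, taxon) rows")
    counts = df["count"]
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise InvalidInputError("counts must be non-negative integers")
    bad = set(df["species"].unique()) - set(SPECIES)
    if bad:
        raise InvalidInputError(f"unknown species {sorted(bad)}")
    return df


def write_counts_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"specimen_id": str, "tow_id": str})
    return validate_counts_table(df)


def load_default_profiles(path=None) -> list:
    """Load the shipped (or a user) profile configuration.

    The default file mirrors the study's 27 screened host-parasite pairs:
    printed prevalence/mean-abundance targets plus synthetic stage, group
    and organ assignments consistent with the reported composition.
    Dispersion is calibrated from the targets at load time.
    """
    if path is None:
        src = resources.files("paradetect.data").joinpath("default_profiles.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    profiles = []
    for row in raw["profiles"]:
        profiles.append(
            TaxonProfile.calibrated(
                taxon=row["taxon"],
                host_species=row["host_species"],
                group=row["group"],
                stage=row["stage"],
                organs=frozenset(row["organs"]),
                prevalence_target=float(row["prevalence"]),
                mean_abundance_target=float(row["mean_abundance"]),
                treatment_log_ratio=float(row.get("treatment_log_ratio", 0.0)),
                length_slope=float(row.get("length_slope", 0.0)),
            )
        )
    return profiles


def with_null_treatment(profiles: Iterable[TaxonProfile]) -> list:
    """Copies of *profiles* with the treatment effect switched off."""
    return [replace(p, treatment_log_ratio=0.0) for p in profiles]
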