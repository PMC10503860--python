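"""Synthetic longitudinal cohorts with known ground truth.

Emulates the data layout of a longitudinal aging/dementia imaging study:

* per-subject linear ADAS-Cog13 trajectories ``score(t) = baseline +
  (aging_slope + acceleration) * t + noise`` clipped to the instrument's
  0-85 range, with the normal-aging and disease-acceleration components
  kept separate in a truth table;
* one T1w-like 3D volume per visit whose *aging region* mean intensity is a
  linear function of the normal-aging score component only, and whose
  *disease region* encodes the disease component, so an image model can in
  principle recover the aging signal;
* Hardy-Weinberg genotypes with optional LD blocks and planted causal
  variants whose per-allele effects (points/year) add up to the subject's
  disease acceleration.

Time is stored in days from baseline; every slope in the package is in
ADAS-Cog13 points per year (365.25 days). A single integer seed drives all
stages through a documented ``numpy.random.SeedSequence`` spawn scheme
(trajectories, volumes, genotypes, in that order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet, VARIANT_COLUMNS

DAYS_PER_YEAR = 365.25
ADAS_MAX = 85.0

Region = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_cohort`.

    Defaults describe a desk-scale cohort: mild normal-aging decline around
    1 point/year with subject-level spread, six-monthly visits, 32^3 volumes
    (configurable up to full 128x160x128 resolution), and a few hundred SNPs
    with one planted causal variant.
    """

    n_subjects: int = 150
    visits_min: int = 3
    visits_max: int = 6
    visit_interval_days: float = 182.625  # 6 months
    visit_jitter_days: float = 14.0
    scan_offset_sd_days: float = 10.0  # scan date relative to assessment date

    volume_shape: tuple[int, int, int] = (32, 32, 32)
    aging_region: Region = ((4, 12), (4, 12), (4, 12))
    disease_region: Region = ((20, 28), (20, 28), (20, 28))
    background_intensity: float = 0.5
    intensity_intercept: float = 0.6
    intensity_slope: float = -0.01  # intensity units per ADAS point
    volume_noise_sd: float = 0.05

    baseline_mean: float = 12.0
    baseline_sd: float = 5.0
    baseline_age_mean: float = 72.0
    baseline_age_sd: float = 7.0
    aging_slope_mean: float = 1.0
    aging_slope_sd: float = 0.8
    acceleration_sd: float = 0.6  # residual acceleration beyond genetics
    score_noise_sd: float = 1.0

    # a few thousand variants keep kinship and PC estimates stable while
    # staying desk-scale
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: tuple[tuple[int, float], ...] = ((25, 0.6),)
    ld_block_len: int = 1  # 1 disables LD structure
    ld_copy_prob: float = 0.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing_bp: int = 5_000

    # diagnosis from true acceleration: below cut1 -> CN, below cut2 -> MCI,
    # else AD; None -> tertile cut-points of the realized accelerations
    dx_cutpoints: tuple[float, float] | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not (1 <= self.visits_min <= self.visits_max):
            raise ValueError("need 1 <= visits_min <= visits_max")
        for sd in (
            self.visit_jitter_days,
            self.scan_offset_sd_days,
            self.volume_noise_sd,
            self.baseline_sd,
            self.aging_slope_sd,
            self.acceleration_sd,
            self.score_noise_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if any(d <= 0 for d in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        self._check_region(self.aging_region)
        self._check_region(self.disease_region)
        if _regions_overlap(self.aging_region, self.disease_region):
            raise ValueError("aging_region and disease_region must be disjoint")
        for idx, _beta in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal SNP index {idx} outside [0, {self.n_snps})")
        if not (0.0 <= self.ld_copy_prob <= 1.0):
            raise ValueError("ld_copy_prob must be in [0, 1]")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")

    def _check_region(self, region: Region) -> None:
        for (lo, hi), n in zip(region, self.volume_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"region bounds {(lo, hi)} outside volume shape {n}")

    def region_slices(self, region: Region) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in region)


def _regions_overlap(a: Region, b: Region) -> bool:
    return all(alo < bhi and blo < ahi for (alo, ahi), (blo, bhi) in zip(a, b))


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Deterministic per-stage generators spawned from one integer seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("trajectories", "volumes", "genotypes")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def render_volume(
    aging_component: float,
    disease_component: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one 3D volume encoding the two score components.

    The aging region's mean intensity is ``intensity_intercept +
    intensity_slope * aging_component``; the disease region encodes the
    disease component the same way; everything else is flat background.
    Additive i.i.d. Gaussian noise (``volume_noise_sd``) covers the whole
    volume.
    """
    if not (np.isfinite(aging_component) and np.isfinite(disease_component)):
        raise ValueError("score components must be finite")
    vol = np.full(config.volume_shape, config.background_intensity, dtype=float)
    vol[config.region_slices(config.aging_region)] = (
        config.intensity_intercept + config.intensity_slope * aging_component
    )
    vol[config.region_slices(config.disease_region)] = (
        config.intensity_intercept + config.intensity_slope * disease_component
    )
    if config.volume_noise_sd > 0:
        vol += rng.normal(0.0, config.volume_noise_sd, size=config.volume_shape)
    return vol


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_len: int = 1,
    ld_copy_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_spacing_bp: int = 5_000,
) -> GenotypeSet:
    """Hardy-Weinberg genotypes with optional blockwise LD.

    Two haplotypes are drawn per sample. Within an LD block of
    ``ld_block_len`` consecutive variants, each haplotype copies the allele
    of the previous variant with probability ``ld_copy_prob`` and otherwise
    draws a fresh Bernoulli(ALT frequency) allele; copy probability 1 gives
    pairwise r^2 = 1 inside the block, 0 gives independent variants.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    freqs = rng.uniform(lo, hi, size=n_snps)
    haplos = np.empty((2, n_samples, n_snps), dtype=np.int8)
    for j in range(n_snps):
        fresh = rng.random((2, n_samples)) < freqs[j]
        if ld_block_len > 1 and j % ld_block_len != 0:
            copy = rng.random((2, n_samples)) < ld_copy_prob
            haplos[:, :, j] = np.where(copy, haplos[:, :, j - 1], fresh)
        else:
            haplos[:, :, j] = fresh
    dosages = haplos.sum(axis=0).astype(float)

    bases = ("A", "C", "G", "T")
    ref = rng.integers(0, 4, size=n_snps)
    alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos_start + pos_spacing_bp * np.arange(n_snps),
            "rsid": [f"rs{1_000_000 + j}" for j in range(n_snps)],
            "ref": [bases[i] for i in ref],
            "alt": [bases[i] for i in alt],
        }
    )[VARIANT_COLUMNS]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeSet(sample_ids=sample_ids, variants=variants, dosages=dosages)


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray], GenotypeSet, pd.DataFrame]:
    """Simulate visits, scans, volumes, genotypes and the truth table.

    Returns
    -------
    visits : DataFrame (subject_id, visit_day, age_years, diagnosis, adas13, sex)
    scans : DataFrame (subject_id, scan_day, scan_id)
    volumes : dict scan_id -> 3D ndarray
    genotypes : GenotypeSet (samples = subjects)
    truth : DataFrame, one row per subject with true aging slope,
        true acceleration (points/year) and diagnosis; plus per-variant
        effects in ``truth.attrs['variant_effects']``.
    """
    rngs = _stage_rngs(config.seed)
    rng_t, rng_v, rng_g = rngs["trajectories"], rngs["volumes"], rngs["genotypes"]

    genotypes = simulate_genotypes(
        max(config.n_subjects, 2),
        config.n_snps,
        config.maf_range,
        config.ld_block_len,
        config.ld_copy_prob,
        seed=rng_g,
        chrom=config.chrom,
        pos_start=config.pos_start,
        pos_spacing_bp=config.pos_spacing_bp,
    )
    genotypes = GenotypeSet(
        sample_ids=[f"SUBJ{i:04d}" for i in range(max(config.n_subjects, 2))],
        variants=genotypes.variants,
        dosages=genotypes.dosages,
    )

    subject_ids = genotypes.sample_ids[: config.n_subjects]
    n = config.n_subjects

    sex = rng_t.integers(0, 2, n)
    aging_slopes = rng_t.normal(config.aging_slope_mean, config.aging_slope_sd, n)
    baselines = rng_t.normal(config.baseline_mean, config.baseline_sd, n).clip(0, ADAS_MAX)
    baseline_ages = rng_t.normal(config.baseline_age_mean, config.baseline_age_sd, n)
    genetic_accel = np.zeros(n)
    for idx, beta in config.causal_snps:
        g = np.nan_to_num(genotypes.dosages[:n, idx])
        genetic_accel += beta * (g - g.mean())
    accelerations = genetic_accel + rng_t.normal(0.0, config.acceleration_sd, n)

    if config.dx_cutpoints is None:
        cut1, cut2 = np.quantile(accelerations, [1 / 3, 2 / 3])
    else:
        cut1, cut2 = config.dx_cutpoints
    diagnosis = np.where(
        accelerations <= cut1, "CN", np.where(accelerations <= cut2, "MCI", "AD")
    )

    visit_rows, scan_rows = [], []
    volumes: dict[str, np.ndarray] = {}
    for i, sid in enumerate(subject_ids):
        n_visits = int(rng_t.integers(config.visits_min, config.visits_max + 1))
        gaps = config.visit_interval_days + rng_t.normal(
            0.0, config.visit_jitter_days, n_visits - 1
        )
        days = np.concatenate([[0.0], np.cumsum(np.maximum(gaps, 1.0))]).round()
        for k, day in enumerate(days):
            t_years = day / DAYS_PER_YEAR
            aging_comp = baselines[i] + aging_slopes[i] * t_years
            disease_comp = accelerations[i] * t_years
            noise = rng_t.normal(0.0, config.score_noise_sd) if config.score_noise_sd else 0.0
            score = np.clip(aging_comp + disease_comp + noise, 0.0, ADAS_MAX)
            visit_rows.append(
                (sid, day, baseline_ages[i] + t_years, diagnosis[i], score, sex[i])
            )
            scan_day = day
            if config.scan_offset_sd_days > 0 and k > 0:
                scan_day = max(0.0, round(day + rng_t.normal(0.0, config.scan_offset_sd_days)))
            scan_id = f"{sid}_d{int(scan_day):05d}"
            scan_rows.append((sid, float(scan_day), scan_id))
            volumes[scan_id] = render_volume(aging_comp, disease_comp, config, rng_v)

    visits = pd.DataFrame(
        visit_rows,
        columns=["subject_id", "visit_day", "age_years", "diagnosis", "adas13", "sex"],
    )
    scans = pd.DataFrame(scan_rows, columns=["subject_id", "scan_day", "scan_id"])
    scans = scans.drop_duplicates(subset=["subject_id", "scan_day"]).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "aging_slope": aging_slopes,
            "acceleration": accelerations,
            "baseline": baselines,
            "diagnosis": diagnosis,
            "sex": sex,
        }
    )
    effects = np.zeros(config.n_snps)
    for idx, beta in config.causal_snps:
        effects[idx] = beta
    truth.attrs["variant_effects"] = effects
    return visits, scans, volumes, genotypes, truth
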