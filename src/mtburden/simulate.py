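"""Synthetic paired tumor-normal cohorts with known truth.

The generative model mirrors the minimal structure the downstream analyses
assume: per-patient Poisson burden with Gleason-category-dependent means,
heteroplasmic allele frequencies drawn in tumor-cell-fraction space from a
truncated Beta and multiplied by the patient's purity to give the observed
tumor frequency (so purity adjustment inverts the scaling exactly), and
exponential relapse times with a proportional-hazards multiplier for patients
carrying at least one variant, administratively censored within a window.

All randomness flows from ``config.seed`` through named substreams, so every
output is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference
from .burden import GLEASON_CATEGORIES
from .errors import ConfigError, DegenerateCohortError

DEFAULT_HAPLOGROUP_FREQS = {
    "H": 0.43, "U": 0.14, "J": 0.11, "T": 0.09, "K": 0.08, "other": 0.15,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible substream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass
class SimulationConfig:
    n_patients: int = 115
    gleason_category_probs: tuple[float, float, float] = (26 / 115, 40 / 115, 49 / 115)
    burden_mean_per_category: tuple[float, float, float] = (0.23, 0.68, 0.88)
    raw_af_beta: tuple[float, float] = (1.3, 1.6)  # Beta params in tumor-cell-fraction space
    raw_af_range: tuple[float, float] = (0.12, 1.0)
    # Beta params per Gleason category; means ~0.47 / 0.60 / 0.60
    purity_beta_per_category: tuple = ((4.7, 5.3), (6.0, 4.0), (6.0, 4.0))
    purity_range: tuple[float, float] = (0.05, 0.85)
    normal_contamination_af: float = 0.0
    baseline_relapse_hazard: float = 0.005  # per month
    hazard_ratio_per_burden_group: float = 2.17  # multiplier when burden >= 1
    censoring_window_months: tuple[float, float] = (24.0, 150.0)
    sequencing_depth: int = 2000
    hotspot_fraction: float = 0.0  # fraction of variants forced into control region + tRNAs
    n_null_sites: int = 0  # extra AF-0 sites per patient for count emission
    haplogroup_freqs: dict = field(default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise DegenerateCohortError(
                f"need at least 2 patients, got {self.n_patients}"
            )
        if abs(sum(self.gleason_category_probs) - 1.0) > 1e-9:
            raise ConfigError("gleason_category_probs must sum to 1")
        if any(p < 0 for p in self.gleason_category_probs):
            raise ConfigError("gleason_category_probs must be nonnegative")
        if any(m < 0 for m in self.burden_mean_per_category):
            raise ConfigError("burden means must be nonnegative")
        if self.baseline_relapse_hazard <= 0:
            raise ConfigError("baseline_relapse_hazard must be positive")
        if self.hazard_ratio_per_burden_group <= 0:
            raise ConfigError("hazard ratio must be positive")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")
        lo, hi = self.raw_af_range
        if not 0 < lo < hi <= 1:
            raise ConfigError(f"invalid raw_af_range {self.raw_af_range}")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ConfigError(f"invalid purity_range {self.purity_range}")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ConfigError("hotspot_fraction must be in [0,1]")
        if not 0 <= self.normal_contamination_af < 1:
            raise ConfigError("normal_contamination_af must be in [0,1)")
        lo, hi = self.censoring_window_months
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid censoring window {self.censoring_window_months}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthVariant:
    position: int
    ref: str
    alt: str
    tcf_af: float  # allele frequency in tumor-cell-fraction space
    tumor_af: float  # observed tumor allele frequency = tcf_af * purity


@dataclass
class TruthRecord:
    patient_id: str
    gleason_category: str
    purity: float
    variants: list[TruthVariant]
    relapse_time: float
    event: int  # 1 = relapse observed, 0 = censored

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "gleason_category": self.gleason_category,
            "purity": self.purity,
            "variants": [asdict(v) for v in self.variants],
            "relapse_time": self.relapse_time,
            "event": self.event,
        }


def _truncated_beta(rng, a, b, lo, hi, size):
    """Inverse-CDF sampling of Beta(a, b) truncated to [lo, hi]."""
    u = rng.uniform(sps.beta.cdf(lo, a, b), sps.beta.cdf(hi, a, b), size=size)
    return sps.beta.ppf(u, a, b)


def _valid_positions() -> np.ndarray:
    seq = reference.load_sequence()
    return np.array([i + 1 for i, base in enumerate(seq) if base in "ACGT"])


def _hotspot_positions() -> np.ndarray:
    sets = reference.class_position_sets()
    pool = sets["control_region"] | sets["tRNA"]
    seq = reference.load_sequence()
    return np.array(sorted(p for p in pool if seq[p - 1] in "ACGT"))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TruthRecord]]:
    """Draw a full cohort: clinical table, paired variant-call table, truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = stage_rng(config.seed, "cohort")
    n = config.n_patients
    seq = reference.load_sequence()
    genome = _valid_positions()
    hotspots = _hotspot_positions() if config.hotspot_fraction > 0 else None

    cats = rng.choice(3, size=n, p=np.asarray(config.gleason_category_probs))
    means = np.asarray(config.burden_mean_per_category)[cats]
    burdens = rng.poisson(means)

    purities = np.empty(n)
    for c in range(3):
        idx = np.where(cats == c)[0]
        if len(idx):
            a, b = config.purity_beta_per_category[c]
            purities[idx] = _truncated_beta(
                rng, a, b, config.purity_range[0], config.purity_range[1], len(idx)
            )

    # survival: exponential hazard with a burden-group multiplier
    hazards = config.baseline_relapse_hazard * np.where(
        burdens >= 1, config.hazard_ratio_per_burden_group, 1.0
    )
    event_times = rng.exponential(1.0 / hazards)
    censor_times = rng.uniform(*config.censoring_window_months, size=n)
    observed_times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)

    ages = np.clip(np.round(rng.normal(61, 6, size=n)), 46, 75).astype(int)
    psa = np.round(np.clip(rng.normal(8.0, 3.0, size=n), 2.43, 18.6), 2)
    hap_names = list(config.haplogroup_freqs)
    hap_p = np.asarray(list(config.haplogroup_freqs.values()), dtype=float)
    hap_p = hap_p / hap_p.sum()
    haplogroups = rng.choice(hap_names, size=n, p=hap_p)
    gleason_sums = np.select(
        [cats == 0, cats == 1], [6, 7], default=0
    ) + np.where(cats == 2, rng.choice([8, 9, 10], size=n), 0)
    # biopsy-core category: agrees with the prostatectomy category half the time
    biopsy_cats = cats.copy()
    flip = rng.random(n) < 0.5
    shift = rng.choice([-1, 1], size=n)
    biopsy_cats[flip] = np.clip(cats[flip] + shift[flip], 0, 2)

    truths: list[TruthRecord] = []
    call_rows = []
    clin_rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        k = int(burdens[i])
        chosen: list[int] = []
        taken = set()
        while len(chosen) < k:
            if hotspots is not None and rng.random() < config.hotspot_fraction:
                pos = int(hotspots[rng.integers(len(hotspots))])
            else:
                pos = int(genome[rng.integers(len(genome))])
            if pos not in taken:
                taken.add(pos)
                chosen.append(pos)
        variants = []
        for pos in chosen:
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            tcf = float(
                _truncated_beta(
                    rng, *config.raw_af_beta,
                    config.raw_af_range[0], config.raw_af_range[1], 1,
                )[0]
            )
            tumor_af = tcf * purities[i]
            variants.append(TruthVariant(pos, ref, alt, tcf, tumor_af))
            call_rows.append(
                {
                    "patient_id": pid,
                    "position": pos,
                    "ref_base": ref,
                    "alt_base": alt,
                    "tumor_af": tumor_af,
                    "normal_af": config.normal_contamination_af,
                    "tumor_depth": config.sequencing_depth,
                    "normal_depth": config.sequencing_depth,
                }
            )
        truths.append(
            TruthRecord(
                patient_id=pid,
                gleason_category=GLEASON_CATEGORIES[cats[i]],
                purity=float(purities[i]),
                variants=variants,
                relapse_time=float(observed_times[i]),
                event=int(events[i]),
            )
        )
        clin_rows.append(
            {
                "patient_id": pid,
                "age": int(ages[i]),
                "psa": float(psa[i]),
                "gleason_rp": int(gleason_sums[i]),
                "gleason_category": GLEASON_CATEGORIES[cats[i]],
                "gleason_biopsy_category": GLEASON_CATEGORIES[biopsy_cats[i]],
                "purity": float(purities[i]),
                "haplogroup": str(haplogroups[i]),
                "follow_up_months": float(observed_times[i]),
                "relapse": int(events[i]),
                "relapse_month": float(observed_times[i]) if events[i] else "",
            }
        )

    clinical = pd.DataFrame(clin_rows)
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "patient_id", "position", "ref_base", "alt_base",
            "tumor_af", "normal_af", "tumor_depth", "normal_depth",
        ],
    )
    return clinical, calls, truths


def emit_allele_counts(truths: list[TruthRecord], config: SimulationConfig) -> pd.DataFrame:
    """Site-level binomial read counts from truth records.

    Alt counts are Binomial(depth, observed AF) independently per sample, with
    ``config.n_null_sites`` extra AF-0 sites per patient. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = stage_rng(config.seed, "counts")
    depth = config.sequencing_depth
    seq = reference.load_sequence()
    genome = _valid_positions()
    rows = []
    for rec in truths:
        used = {v.position for v in rec.variants}
        for v in rec.variants:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "position": v.position,
                    "ref_base": v.ref,
                    "alt_base": v.alt,
                    "tumor_alt": int(rng.binomial(depth, min(v.tumor_af, 1.0))),
                    "tumor_depth": depth,
                    "normal_alt": int(rng.binomial(depth, config.normal_contamination_af)),
                    "normal_depth": depth,
                }
            )
        added = 0
        while added < config.n_null_sites:
            pos = int(genome[rng.integers(len(genome))])
            if pos in used:
                continue
            used.add(pos)
            added += 1
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "position": pos,
                    "ref_base": ref,
                    "alt_base": alt,
                    "tumor_alt": 0,
                    "tumor_depth": depth,
                    "normal_alt": 0,
                    "normal_depth": depth,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "position", "ref_base", "alt_base",
            "tumor_alt", "tumor_depth", "normal_alt", "normal_depth",
        ],
    )


def truth_to_json(truths: list[TruthRecord], config: SimulationConfig) -> str:
    return json.dumps(
        {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "records": [t.to_dict() for t in truths],
        },
        indent=2,
        sort_keys=True,
    )
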