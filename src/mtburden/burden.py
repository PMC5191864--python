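"""Per-patient mutational-burden metrics and per-region variant densities.

Purity adjustment divides the observed allele frequency by the pathologist's
tumor-purity estimate and is deliberately NOT capped at 1 (adjusted values up
to ~1.8 are meaningful under imperfect purity estimates). The cumulative
variant frequency (CVF) is the per-patient sum of adjusted frequencies; a raw
(unadjusted) CVF variant is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import reference, stats
from .errors import (
    DegeneratePartitionError,
    EmptySetError,
    JoinError,
    PurityDomainError,
)

GLEASON_CATEGORIES = ("<7", "=7", ">7")

DEFAULT_FUNCTIONAL_THRESHOLD = 0.70


def gleason_category(score: int) -> str:
    """Map a Gleason sum to the ordinal category used throughout."""
    if score < 7:
        return "<7"
    if score == 7:
        return "=7"
    return ">7"


@dataclass(frozen=True)
class BurdenProfile:
    """Per-patient burden statistics."""

    patient_id: str
    n_snv: int
    raw_afs: tuple[float, ...] = field(default_factory=tuple)
    adjusted_afs: tuple[float, ...] = field(default_factory=tuple)
    cvf: float = 0.0
    n_functional: int = 0
    n_nonsynonymous: int = 0


def adjust_af(raw_af: float, purity: float) -> float:
    """raw_af / purity; may exceed 1 when the purity estimate is conservative."""
    if not 0 < purity <= 1:
        raise PurityDomainError(f"purity must be in (0,1], got {purity}")
    if not 0 <= raw_af <= 1:
        raise PurityDomainError(f"raw allele frequency must be in [0,1], got {raw_af}")
    return raw_af / purity


def compute_cvf(adjusted_afs) -> float:
    """Sum of adjusted allele frequencies; 0 for a patient with no variants."""
    return float(sum(adjusted_afs))


def flag_functional(adjusted_af: float, threshold: float = DEFAULT_FUNCTIONAL_THRESHOLD) -> bool:
    """True iff the adjusted allele frequency strictly exceeds the threshold."""
    if adjusted_af < 0:
        raise PurityDomainError(f"adjusted allele frequency must be >= 0, got {adjusted_af}")
    return adjusted_af > threshold


def build_profiles(
    somatic: pd.DataFrame,
    clinical: pd.DataFrame,
    functional_threshold: float = DEFAULT_FUNCTIONAL_THRESHOLD,
    cvf_on_raw: bool = False,
) -> list[BurdenProfile]:
    """Burden profile for every patient in the clinical table.

    ``somatic`` is a per-(patient, variant) table with somatic_af and effect
    columns; ``clinical`` must carry patient_id and purity. Patients without
    calls get an all-zero profile. ``cvf_on_raw`` switches the CVF to sum raw
    (unadjusted) somatic allele frequencies.
    """
    purity = dict(zip(clinical["patient_id"], clinical["purity"]))
    unknown = set(somatic["patient_id"]) - set(purity) if len(somatic) else set()
    if unknown:
        raise JoinError(f"somatic calls for unknown patients: {sorted(unknown)}")
    profiles = []
    grouped = dict(tuple(somatic.groupby("patient_id"))) if len(somatic) else {}
    for pid in clinical["patient_id"]:
        rows = grouped.get(pid)
        if rows is None or not len(rows):
            profiles.append(BurdenProfile(patient_id=pid, n_snv=0))
            continue
        raw = tuple(float(v) for v in rows["somatic_af"])
        adj = tuple(adjust_af(v, purity[pid]) for v in raw)
        basis = raw if cvf_on_raw else adj
        profiles.append(
            BurdenProfile(
                patient_id=pid,
                n_snv=len(rows),
                raw_afs=raw,
                adjusted_afs=adj,
                cvf=compute_cvf(basis),
                n_functional=sum(flag_functional(a, functional_threshold) for a in adj),
                n_nonsynonymous=int((rows["effect"] == "non_synonymous").sum()),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[BurdenProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "n_snv": p.n_snv,
                "cvf": p.cvf,
                "n_functional": p.n_functional,
                "n_nonsynonymous": p.n_nonsynonymous,
                "mean_raw_af": (sum(p.raw_afs) / p.n_snv) if p.n_snv else 0.0,
                "mean_adjusted_af": (sum(p.adjusted_afs) / p.n_snv) if p.n_snv else 0.0,
            }
            for p in profiles
        ],
        columns=[
            "patient_id", "n_snv", "cvf", "n_functional",
            "n_nonsynonymous", "mean_raw_af", "mean_adjusted_af",
        ],
    )


def cohort_summary(profiles: list[BurdenProfile], clinical: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per Gleason category plus an overall column.

    Mean SNV count divides by every patient in the category; mean CVF and the
    mean per-variant allele frequencies average over variant-carrying patients
    and variants respectively.
    """
    cats = dict(zip(clinical["patient_id"], clinical["gleason_category"]))
    missing = [p.patient_id for p in profiles if p.patient_id not in cats]
    if missing:
        raise JoinError(f"profiles without clinical records: {missing}")
    extra = set(cats) - {p.patient_id for p in profiles}
    if extra:
        raise JoinError(f"clinical records without profiles: {sorted(extra)}")

    def summarize(subset: list[BurdenProfile]) -> dict:
        n_pat = len(subset)
        carriers = [p for p in subset if p.n_snv >= 1]
        all_raw = [a for p in subset for a in p.raw_afs]
        all_adj = [a for p in subset for a in p.adjusted_afs]
        total = sum(p.n_snv for p in subset)
        return {
            "n_patients": n_pat,
            "total_snvs": total,
            "patients_with_snvs": len(carriers),
            "pct_patients_with_snvs": 100.0 * len(carriers) / n_pat if n_pat else 0.0,
            "mean_snv_count": total / n_pat if n_pat else 0.0,
            "n_nonsynonymous": sum(p.n_nonsynonymous for p in subset),
            "mean_absolute_af": sum(all_raw) / len(all_raw) if all_raw else 0.0,
            "mean_adjusted_af": sum(all_adj) / len(all_adj) if all_adj else 0.0,
            "mean_cvf": (sum(p.cvf for p in carriers) / len(carriers)) if carriers else 0.0,
            "n_functional": sum(p.n_functional for p in subset),
        }

    columns = {}
    for cat in GLEASON_CATEGORIES:
        subset = [p for p in profiles if cats[p.patient_id] == cat]
        columns[cat] = summarize(subset)
    columns["ALL"] = summarize(profiles)
    return pd.DataFrame(columns)


@dataclass(frozen=True)
class RegionDensity:
    name: str
    region_class: str
    n_variants: int
    length_bp: int
    density_per_kb: float


def region_densities(
    unique_variants: pd.DataFrame,
    region_map=None,
) -> tuple[list[RegionDensity], dict[str, RegionDensity]]:
    """Unique-variant counts and per-kb densities per region and per class.

    A variant inside overlapping genes contributes one count to each gene's
    tally but only one count to each class aggregate. The class aggregates use
    distinct genomic positions as lengths, so shared bases are not counted
    twice. ``noncoding_total`` aggregates control region + tRNA + unannotated
    spacers.
    """
    if region_map is None:
        region_map = reference.build_region_map()
    positions = [int(p) for p in unique_variants["position"]] if len(unique_variants) else []

    per_region: dict[str, dict] = {}
    for rec in region_map:
        entry = per_region.setdefault(
            rec.name,
            {"region_class": rec.region_class.value, "n": 0, "len": 0},
        )
        entry["len"] += rec.length
    for name, entry in per_region.items():
        segs = [r for r in region_map if r.name == name]
        entry["n"] = sum(1 for p in positions if any(s.contains(p) for s in segs))

    densities = [
        RegionDensity(
            name=name,
            region_class=entry["region_class"],
            n_variants=entry["n"],
            length_bp=entry["len"],
            density_per_kb=entry["n"] * 1000.0 / entry["len"],
        )
        for name, entry in per_region.items()
    ]

    class_sets = reference.class_position_sets(region_map)
    aggregates: dict[str, RegionDensity] = {}
    for klass in ("protein_coding", "rRNA", "tRNA", "control_region", "other_noncoding"):
        pos_set = class_sets[klass]
        n = sum(1 for p in set(positions) if p in pos_set)
        aggregates[klass] = RegionDensity(
            name=klass,
            region_class=klass,
            n_variants=n,
            length_bp=len(pos_set),
            density_per_kb=n * 1000.0 / len(pos_set) if pos_set else 0.0,
        )
    nc_pos = class_sets["control_region"] | class_sets["tRNA"] | class_sets["other_noncoding"]
    n_nc = sum(1 for p in set(positions) if p in nc_pos)
    aggregates["noncoding_total"] = RegionDensity(
        name="noncoding_total",
        region_class="noncoding_total",
        n_variants=n_nc,
        length_bp=len(nc_pos),
        density_per_kb=n_nc * 1000.0 / len(nc_pos),
    )
    return densities, aggregates


def region_enrichment_test(
    n_variants_a: int, length_a: int, n_variants_b: int, length_b: int
) -> float:
    """Two-sided Fisher exact p for variant density in class A vs class B.

    The 2x2 table treats bases as trials: [variant positions, non-variant
    positions] per class.
    """
    if length_a <= 0 or length_b <= 0:
        raise DegeneratePartitionError("both partition classes must have positive length")
    if n_variants_a > length_a or n_variants_b > length_b:
        raise DegeneratePartitionError("variant count exceeds class length")
    return stats.fisher_exact_2x2(
        n_variants_a, length_a - n_variants_a, n_variants_b, length_b - n_variants_b
    )


def densities_to_frame(densities: list[RegionDensity], aggregates: dict[str, RegionDensity]) -> pd.DataFrame:
    rows = [
        {
            "name": d.name,
            "region_class": d.region_class,
            "n_variants": d.n_variants,
            "length_bp": d.length_bp,
            "density_per_kb": d.density_per_kb,
            "scope": "region",
        }
        for d in densities
    ] + [
        {
            "name": d.name,
            "region_class": d.region_class,
            "n_variants": d.n_variants,
            "length_bp": d.length_bp,
            "density_per_kb": d.density_per_kb,
            "scope": "aggregate",
        }
        for d in aggregates.values()
    ]
    if not rows:
        raise EmptySetError("no densities to tabulate")
    return pd.DataFrame(rows)
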