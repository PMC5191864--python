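"""Somatic SNV identification from paired tumor-normal allele frequencies.

The caller operates on allele-frequency pairs (or raw allele counts through
:func:`estimate_af`): a site is somatic when the tumor allele frequency
exceeds the matched normal frequency by strictly more than the threshold
(default 0.10). Losses — normal exceeding tumor by more than the threshold —
are surfaced on a diagnostics stream, never as somatic calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import reference
from .errors import (
    AlphabetError,
    CountError,
    DuplicateCallError,
    EmptySetError,
    IncompletePairError,
)

logger = logging.getLogger(__name__)

DEFAULT_SOMATIC_THRESHOLD = 0.10
DEFAULT_MIN_DEPTH = 100

SUBSTITUTION_CLASSES = ("C>T", "T>C", "C>A", "C>G", "T>A", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: novelty contexts ordered most-specific first
NOVELTY_ORDER = ("prostate", "cancer", "disease")
NOVELTY_LABELS = {
    "prostate": "known_prostate",
    "cancer": "known_cancer",
    "disease": "known_disease",
}


@dataclass(frozen=True)
class VariantCall:
    """One paired tumor-normal observation at an mtDNA position."""

    patient_id: str
    position: int
    ref_base: str
    alt_base: str
    tumor_af: float | None
    normal_af: float | None
    tumor_depth: int | None = None
    normal_depth: int | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise AlphabetError(
                f"ref and alt are identical ({self.ref_base}) at {self.position}"
            )
        for af in (self.tumor_af, self.normal_af):
            if af is not None and not 0.0 <= af <= 1.0:
                raise IncompletePairError(
                    f"allele frequency {af} outside [0,1] at {self.position}"
                )
        reference._check_position(self.position)


@dataclass(frozen=True)
class SomaticVariant:
    """A called somatic SNV with spectrum, region and effect annotation."""

    patient_id: str
    position: int
    ref_base: str
    alt_base: str
    tumor_af: float
    normal_af: float
    somatic_af: float
    substitution_class: str
    is_transition: bool
    regions: tuple[str, ...] = field(default_factory=tuple)
    effect: str = reference.Effect.noncoding.value


def estimate_af(alt_count: int, total_count: int, min_depth: int = DEFAULT_MIN_DEPTH) -> float | None:
    """Allele frequency from counts, or None below the depth floor.

    Sites returning None are excluded from calling rather than treated as 0.
    """
    if alt_count < 0 or total_count < 0 or alt_count > total_count:
        raise CountError(
            f"inconsistent counts: alt={alt_count}, total={total_count}"
        )
    if total_count < min_depth:
        return None
    return alt_count / total_count


def call_somatic(call: VariantCall, threshold: float = DEFAULT_SOMATIC_THRESHOLD) -> bool:
    """True iff tumor_af - normal_af > threshold (strict; tumor gains only)."""
    if call.tumor_af is None or call.normal_af is None:
        raise IncompletePairError(
            f"missing allele frequency for patient {call.patient_id} "
            f"at position {call.position}"
        )
    return call.tumor_af - call.normal_af > threshold


def is_loss(call: VariantCall, threshold: float = DEFAULT_SOMATIC_THRESHOLD) -> bool:
    """True iff the normal exceeds the tumor by more than the threshold (diagnostic)."""
    if call.tumor_af is None or call.normal_af is None:
        raise IncompletePairError(
            f"missing allele frequency for patient {call.patient_id} "
            f"at position {call.position}"
        )
    return call.normal_af - call.tumor_af > threshold


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Pyrimidine-strand substitution class and transition flag.

    Purine-reference pairs are collapsed onto their reverse complement
    (G>A -> C>T, A>G -> T>C, ...), so the class is always one of the six
    pyrimidine-referenced categories.
    """
    ref, alt = ref.upper(), alt.upper()
    for base in (ref, alt):
        if base not in reference.VALID_BASES:
            raise AlphabetError(f"invalid base {base!r}")
    if ref == alt:
        raise AlphabetError(f"ref and alt are identical: {ref}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    klass = f"{ref}>{alt}"
    return klass, klass in TRANSITIONS


def annotate_call(
    call: VariantCall,
    region_map=None,
    sequence: str | None = None,
) -> SomaticVariant:
    """Attach spectrum class, region memberships and effect to a somatic call."""
    klass, is_ts = classify_substitution(call.ref_base, call.alt_base)
    regions = tuple(r.name for r in reference.locate(call.position, region_map))
    effect = reference.classify_effect(
        call.position, call.ref_base, call.alt_base, region_map, sequence
    )
    return SomaticVariant(
        patient_id=call.patient_id,
        position=call.position,
        ref_base=call.ref_base,
        alt_base=call.alt_base,
        tumor_af=call.tumor_af,
        normal_af=call.normal_af,
        somatic_af=call.tumor_af - call.normal_af,
        substitution_class=klass,
        is_transition=is_ts,
        regions=regions,
        effect=effect.value,
    )


def call_cohort(
    calls: list[VariantCall],
    threshold: float = DEFAULT_SOMATIC_THRESHOLD,
    annotate: bool = True,
) -> tuple[list[SomaticVariant], pd.DataFrame]:
    """Run the somatic rule over a cohort of paired calls.

    Returns the somatic variants plus a diagnostics table of loss events
    (normal > tumor by more than the threshold).
    """
    somatic: list[SomaticVariant] = []
    losses = []
    for call in calls:
        if call_somatic(call, threshold):
            if annotate:
                somatic.append(annotate_call(call))
            else:
                klass, is_ts = classify_substitution(call.ref_base, call.alt_base)
                somatic.append(
                    SomaticVariant(
                        patient_id=call.patient_id,
                        position=call.position,
                        ref_base=call.ref_base,
                        alt_base=call.alt_base,
                        tumor_af=call.tumor_af,
                        normal_af=call.normal_af,
                        somatic_af=call.tumor_af - call.normal_af,
                        substitution_class=klass,
                        is_transition=is_ts,
                    )
                )
        elif is_loss(call, threshold):
            losses.append(
                {
                    "patient_id": call.patient_id,
                    "position": call.position,
                    "ref_base": call.ref_base,
                    "alt_base": call.alt_base,
                    "tumor_af": call.tumor_af,
                    "normal_af": call.normal_af,
                    "event": "loss",
                }
            )
    diagnostics = pd.DataFrame(
        losses,
        columns=[
            "patient_id", "position", "ref_base", "alt_base",
            "tumor_af", "normal_af", "event",
        ],
    )
    return somatic, diagnostics


def deduplicate(variants: list[SomaticVariant]) -> pd.DataFrame:
    """Collapse per-patient calls to unique (position, ref, alt) variants.

    Returns a table keyed by (position, ref_base, alt_base) with a
    ``recurrence`` column counting distinct patients carrying the variant.
    Duplicate (patient, position, ref, alt) rows are input errors.
    """
    seen: set[tuple] = set()
    for v in variants:
        key = (v.patient_id, v.position, v.ref_base, v.alt_base)
        if key in seen:
            raise DuplicateCallError(
                f"duplicate call for patient {v.patient_id} at "
                f"{v.position} {v.ref_base}>{v.alt_base}"
            )
        seen.add(key)
    counts: dict[tuple, dict] = {}
    for v in variants:
        key = (v.position, v.ref_base, v.alt_base)
        if key not in counts:
            counts[key] = {
                "position": v.position,
                "ref_base": v.ref_base,
                "alt_base": v.alt_base,
                "substitution_class": v.substitution_class,
                "is_transition": v.is_transition,
                "regions": ";".join(v.regions),
                "effect": v.effect,
                "recurrence": 0,
            }
        counts[key]["recurrence"] += 1
    df = pd.DataFrame(
        list(counts.values()),
        columns=[
            "position", "ref_base", "alt_base", "substitution_class",
            "is_transition", "regions", "effect", "recurrence",
        ],
    )
    return df.sort_values(["position", "ref_base", "alt_base"]).reset_index(drop=True)


def annotate_novelty(unique_variants: pd.DataFrame, catalog: pd.DataFrame | None) -> tuple[pd.Series, int]:
    """Label unique variants against a known-variant catalog.

    The catalog carries (position, ref, alt, context) rows with context in
    {prostate, cancer, disease}; the most specific matching context wins.
    Malformed catalog rows are skipped with a logged warning. Returns the
    label series plus the number of skipped catalog rows.
    """
    lookup: dict[tuple, str] = {}
    skipped = 0
    if catalog is not None:
        for _, row in catalog.iterrows():
            try:
                pos = int(row["position"])
                ref = str(row["ref_base"]).upper()
                alt = str(row["alt_base"]).upper()
                ctx = str(row["context"]).lower()
                if ctx not in NOVELTY_ORDER or ref not in reference.VALID_BASES \
                        or alt not in reference.VALID_BASES or not 1 <= pos <= reference.GENOME_LENGTH:
                    raise ValueError(f"bad catalog row: {row.to_dict()}")
            except (ValueError, KeyError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping malformed catalog row: %s", exc)
                continue
            key = (pos, ref, alt)
            prev = lookup.get(key)
            if prev is None or NOVELTY_ORDER.index(ctx) < NOVELTY_ORDER.index(prev):
                lookup[key] = ctx
    labels = []
    for _, row in unique_variants.iterrows():
        ctx = lookup.get((int(row["position"]), row["ref_base"], row["alt_base"]))
        labels.append(NOVELTY_LABELS[ctx] if ctx else "novel")
    return pd.Series(labels, index=unique_variants.index, name="novelty"), skipped


def spectrum_summary(variants: list[SomaticVariant] | pd.DataFrame) -> dict[str, float]:
    """Proportion of calls in each of the six pyrimidine-strand classes."""
    if isinstance(variants, pd.DataFrame):
        classes = list(variants["substitution_class"])
    else:
        classes = [v.substitution_class for v in variants]
    if not classes:
        raise EmptySetError("spectrum_summary requires at least one variant")
    n = len(classes)
    return {k: classes.count(k) / n for k in SUBSTITUTION_CLASSES}


def variants_to_frame(variants: list[SomaticVariant]) -> pd.DataFrame:
    """Somatic variants as a flat table (one row per patient-variant)."""
    return pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "position": v.position,
                "ref_base": v.ref_base,
                "alt_base": v.alt_base,
                "tumor_af": v.tumor_af,
                "normal_af": v.normal_af,
                "somatic_af": v.somatic_af,
                "substitution_class": v.substitution_class,
                "is_transition": v.is_transition,
                "regions": ";".join(v.regions),
                "effect": v.effect,
            }
            for v in variants
        ],
        columns=[
            "patient_id", "position", "ref_base", "alt_base", "tumor_af",
            "normal_af", "somatic_af", "substitution_class", "is_transition",
            "regions", "effect",
        ],
    )
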