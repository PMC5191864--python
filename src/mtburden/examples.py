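"""Deterministic worked-example cohorts built from published marginal counts.

These fixtures reconstruct a 115-patient cohort whose marginal statistics are
fully specified by printed summary counts: 26/40/49 patients per Gleason
category, 76 somatic calls split 6/27/43 across categories, carried by
4/19/27 patients (50 in total), with one variant (position 16093) recurring in
three patients and every other call a singleton. Per-patient counts stay
within the printed ranges (0-2 / 0-3 / 0-4). They are used by the test suite
and the acceptance report; no randomness is involved.
"""

from __future__ import annotations

import pandas as pd

from . import reference
from .burden import GLEASON_CATEGORIES

# per-carrier SNV counts per Gleason category; zeros fill the rest
_CARRIER_COUNTS = {
    "<7": [2, 2, 1, 1],                     # 26 patients, 6 calls, range 0-2
    "=7": [3] + [2] * 6 + [1] * 12,         # 40 patients, 27 calls, range 0-3
    ">7": [4, 3] + [2] * 11 + [1] * 14,     # 49 patients, 43 calls, range 0-4
}
_N_PATIENTS = {"<7": 26, "=7": 40, ">7": 49}
_PURITY = {"<7": 0.47, "=7": 0.60, ">7": 0.60}

RECURRENT_POSITION = 16093


def _distinct_positions(n: int) -> list[int]:
    """n distinct A/C/G/T positions spread over the genome, skipping 16093."""
    seq = reference.load_sequence()
    out = []
    pos = 101
    step = 16569 // (n + 2)
    while len(out) < n:
        p = pos % reference.GENOME_LENGTH + 1
        if p != RECURRENT_POSITION and seq[p - 1] in "ACGT":
            out.append(p)
        pos += step
    return out


def table1_marginal_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(clinical table, somatic-call table) matching the printed marginals.

    The call table has 76 rows over 50 carrier patients; the variant at
    position 16093 appears for three distinct patients, all other calls are
    distinct (position, ref, alt) singletons.
    """
    seq = reference.load_sequence()
    clin_rows = []
    pid = 0
    patients_by_cat: dict[str, list[str]] = {c: [] for c in GLEASON_CATEGORIES}
    for cat in GLEASON_CATEGORIES:
        for _ in range(_N_PATIENTS[cat]):
            pid += 1
            name = f"P{pid:04d}"
            patients_by_cat[cat].append(name)
            clin_rows.append(
                {
                    "patient_id": name,
                    "gleason_category": cat,
                    "gleason_biopsy_category": cat,
                    "purity": _PURITY[cat],
                    "follow_up_months": 107.0,
                    "relapse": 0,
                    "relapse_month": "",
                    "haplogroup": "H",
                }
            )
    clinical = pd.DataFrame(clin_rows)

    n_singletons = 76 - 3  # one variant recurs in three patients
    singleton_positions = iter(_distinct_positions(n_singletons))
    recurrent_assigned = 0
    call_rows = []
    # the three recurrent carriers are spread over the categories with >=3 carriers
    recurrent_slots = {"=7": 1, ">7": 2}
    for cat in GLEASON_CATEGORIES:
        carriers = _CARRIER_COUNTS[cat]
        take_recurrent = recurrent_slots.get(cat, 0)
        for i, k in enumerate(carriers):
            patient = patients_by_cat[cat][i]
            for j in range(k):
                if j == 0 and take_recurrent > 0:
                    take_recurrent -= 1
                    recurrent_assigned += 1
                    pos = RECURRENT_POSITION
                else:
                    pos = next(singleton_positions)
                ref = seq[pos - 1]
                # deterministic transition-biased alternates
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
                call_rows.append(
                    {
                        "patient_id": patient,
                        "position": pos,
                        "ref_base": ref,
                        "alt_base": alt,
                        "tumor_af": 0.12 + 0.01 * (len(call_rows) % 80),
                        "normal_af": 0.0,
                        "somatic_af": 0.12 + 0.01 * (len(call_rows) % 80),
                        "effect": "noncoding",
                    }
                )
    assert recurrent_assigned == 3
    calls = pd.DataFrame(call_rows)
    assert len(calls) == 76
    assert calls["patient_id"].nunique() == 50
    return clinical, calls
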