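"""Readers and writers for the table and VCF formats the pipeline exchanges.

Tables are TSV with ``#``-prefixed header comment lines carrying the
parameters (and seed) that produced them. Variant pairs can also be exchanged
as one minimal VCF 4.2 file per patient with TUMOR/NORMAL samples and FORMAT
fields AF and AD.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import pysam

from .calling import VariantCall, estimate_af
from .errors import ValidationError
from .reference import GENOME_LENGTH, load_sequence

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mtburden
##contig=<ID=chrM,length=16569>
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele frequency">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (meta or {}).items():
        buf.write(f"# {key}: {value}\n")
    # shortest round-trip repr so numeric columns survive a write/read cycle
    df.to_csv(buf, sep="\t", index=False, float_format=lambda v: repr(float(v)))
    path.write_text(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read table {path}: {exc}") from exc


def calls_from_frame(df: pd.DataFrame) -> list[VariantCall]:
    """VariantCall objects from a flat paired-call table (AF columns)."""
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                patient_id=str(row.patient_id),
                position=int(row.position),
                ref_base=str(row.ref_base),
                alt_base=str(row.alt_base),
                tumor_af=float(row.tumor_af),
                normal_af=float(row.normal_af),
                tumor_depth=int(row.tumor_depth) if hasattr(row, "tumor_depth") else None,
                normal_depth=int(row.normal_depth) if hasattr(row, "normal_depth") else None,
            )
        )
    return calls


def calls_from_counts(df: pd.DataFrame, min_depth: int = 100) -> list[VariantCall]:
    """VariantCall objects from a site-level read-count table.

    Sites where either sample fails the depth floor get a missing AF and are
    skipped by the caller (never treated as AF 0).
    """
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                patient_id=str(row.patient_id),
                position=int(row.position),
                ref_base=str(row.ref_base),
                alt_base=str(row.alt_base),
                tumor_af=estimate_af(int(row.tumor_alt), int(row.tumor_depth), min_depth),
                normal_af=estimate_af(int(row.normal_alt), int(row.normal_depth), min_depth),
                tumor_depth=int(row.tumor_depth),
                normal_depth=int(row.normal_depth),
            )
        )
    return calls


def write_patient_vcf(path: str | Path, patient_calls: pd.DataFrame, seed=None) -> None:
    """Write one patient's paired calls as a minimal uncompressed VCF 4.2."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [VCF_HEADER if seed is None else VCF_HEADER.replace(
        "##source=mtburden\n", f"##source=mtburden\n##mtburden_seed={seed}\n"
    )]
    for row in patient_calls.sort_values("position").itertuples(index=False):
        t_depth = int(getattr(row, "tumor_depth", 0) or 0)
        n_depth = int(getattr(row, "normal_depth", 0) or 0)
        t_alt = int(round(row.tumor_af * t_depth))
        n_alt = int(round(row.normal_af * n_depth))
        lines.append(
            f"chrM\t{int(row.position)}\t.\t{row.ref_base}\t{row.alt_base}\t.\tPASS\t.\t"
            f"AF:AD\t{row.tumor_af:.6g}:{t_depth - t_alt},{t_alt}\t"
            f"{row.normal_af:.6g}:{n_depth - n_alt},{n_alt}\n"
        )
    path.write_text("".join(lines))


def read_patient_vcf(path: str | Path, patient_id: str, min_depth: int = 0) -> list[VariantCall]:
    """Parse a paired TUMOR/NORMAL VCF into VariantCall objects.

    AF is taken from the AF FORMAT field when present, otherwise computed from
    AD. Indels are skipped (SNV-only analysis downstream).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if "TUMOR" not in samples or "NORMAL" not in samples:
        raise ValidationError(f"{path}: VCF must carry TUMOR and NORMAL samples")
    calls = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel: excluded from burden statistics
        if not 1 <= rec.pos <= GENOME_LENGTH:
            raise ValidationError(f"{path}: position {rec.pos} out of range")

        def _af(sample):
            fmt = rec.samples[sample]
            if "AF" in fmt and fmt["AF"] is not None:
                return float(fmt["AF"])
            if "AD" in fmt and fmt["AD"] is not None:
                ad = fmt["AD"]
                total = int(ad[0]) + int(ad[1])
                return estimate_af(int(ad[1]), total, min_depth)
            return None

        calls.append(
            VariantCall(
                patient_id=patient_id,
                position=rec.pos,
                ref_base=ref,
                alt_base=alt,
                tumor_af=_af("TUMOR"),
                normal_af=_af("NORMAL"),
            )
        )
    return calls


def check_reference_consistency(df: pd.DataFrame) -> list[str]:
    """Rows whose ref base disagrees with the packaged rCRS (issue strings)."""
    seq = load_sequence()
    issues = []
    for row in df.itertuples(index=False):
        pos = int(row.position)
        if not 1 <= pos <= GENOME_LENGTH:
            issues.append(f"position {pos} out of range for patient {row.patient_id}")
        elif seq[pos - 1] != str(row.ref_base).upper():
            issues.append(
                f"ref mismatch at {pos} for patient {row.patient_id}: "
                f"{row.ref_base} vs rCRS {seq[pos - 1]}"
            )
    return issues
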