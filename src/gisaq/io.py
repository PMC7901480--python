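"""File formats: FASTA/FASTQ sequences, TSV count tables, YAML configs.

Tables are features x samples TSV with a header row of sample ids and the
feature id in the first column; counts must be non-negative integers.
Gradient designs and calibration coefficients travel as YAML for human
review.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrate import CalibrationCoefficients
from .errors import ParseError
from .quantify import GradientDesign


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA/FASTQ (optionally gzipped) into SeqRecords."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sequence file: {path}")
    fmt = _sniff_format(path)
    with _open_text(path) as handle:
        try:
            return list(SeqIO.parse(handle, fmt))
        except ValueError as exc:
            raise ParseError(f"{path}: malformed {fmt}: {exc}") from exc


def write_sequences(records: Iterable, path: str | Path, fmt: str | None = None,
                    default_quality: int = 40) -> None:
    """Write SeqRecords or (id, seq) pairs; format inferred from suffix."""
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rec = SeqRecord(Seq(rec[1]), id=rec[0], description="")
        if fmt == "fastq" and "phred_quality" not in rec.letter_annotations:
            rec = SeqRecord(rec.seq, id=rec.id, description=rec.description)
            rec.letter_annotations["phred_quality"] = [default_quality] * len(rec.seq)
        out.append(rec)
    with _open_text(path, "wt") as handle:
        SeqIO.write(out, handle, fmt)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV of integer counts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable TSV: {exc}") from exc
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids: {dupes}")
    for col in raw.columns:
        for fid, val in raw[col].items():
            try:
                ival = int(val)
                if ival != float(val):
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer count at feature {fid!r}, sample {col!r}: "
                    f"{val!r}") from None
            if ival < 0:
                raise ParseError(
                    f"{path}: negative count at feature {fid!r}, sample {col!r}")
    return raw.astype("int64")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def write_gradient_design(design: GradientDesign, path: str | Path) -> None:
    payload = {"region": design.region, "sample_mass_g": design.sample_mass_g,
               "concentrations": {k: float(v)
                                  for k, v in design.concentrations.items()}}
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def read_gradient_design(path: str | Path) -> GradientDesign:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    try:
        return GradientDesign(concentrations=payload["concentrations"],
                              region=payload.get("region", "16S_V3V4"),
                              sample_mass_g=payload.get("sample_mass_g", 1.0))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: invalid gradient design: {exc}") from exc


def write_calibration(calib: CalibrationCoefficients, path: str | Path) -> None:
    payload = {"kingdom": calib.kingdom, "c": float(calib.c), "d": float(calib.d),
               "alpha": float(calib.alpha),
               "provenance": {k: float(v) for k, v in calib.provenance.items()}}
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def read_calibration(path: str | Path) -> CalibrationCoefficients:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    try:
        return CalibrationCoefficients(kingdom=payload["kingdom"],
                                       c=payload["c"], d=payload["d"],
                                       alpha=payload.get("alpha", 0.05),
                                       provenance=payload.get("provenance", {}))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: invalid calibration file: {exc}") from exc


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Long-format qPCR TSV: group, kingdom, log10_conc, ct[, replicate]."""
    table = pd.read_csv(path, sep="\t")
    required = {"group", "kingdom", "log10_conc", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing qPCR columns: {sorted(missing)}")
    return table
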