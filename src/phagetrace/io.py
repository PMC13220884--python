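"""Readers and writers for the pipeline's plain-text artifacts.

The variant input dialect is a minimal single-contig VCF (v4.2 header, SNP
records, per-sample AD ref,alt depths) matching the shape of an upstream
joint-caller's output; an equivalent long-form TSV is accepted and emitted
everywhere a VCF is.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import AlleleObservation

VCF_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT")


class VcfParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def read_vcf_minimal(path) -> list[AlleleObservation]:
    """Parse a minimal VCF into one observation per sample x (biallelic) record.

    Multiallelic records are split into biallelic observations (the AD
    field carries ref,alt1,alt2,...).  Malformed lines raise
    :class:`VcfParseError` naming the line, and missing AD entries name the
    sample as well.
    """
    path = Path(path)
    samples: list[str] = []
    observations: list[AlleleObservation] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.lstrip("#").split("\t")
                if len(fields) < 10:
                    raise VcfParseError(path, line_no, "header has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise VcfParseError(path, line_no, "record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise VcfParseError(
                    path, line_no,
                    f"expected {9 + len(samples)} columns, got {len(fields)}",
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise VcfParseError(path, line_no, f"bad POS {fields[1]!r}") from None
            ref, alts = fields[3], fields[4].split(",")
            fmt = fields[8].split(":")
            if "AD" not in fmt:
                raise VcfParseError(path, line_no, "FORMAT lacks AD")
            ad_i = fmt.index("AD")
            for sample, cell in zip(samples, fields[9:]):
                parts = cell.split(":")
                if len(parts) <= ad_i or parts[ad_i] in (".", ""):
                    raise VcfParseError(
                        path, line_no, f"sample {sample}: missing AD field"
                    )
                try:
                    depths = [int(x) for x in parts[ad_i].split(",")]
                except ValueError:
                    raise VcfParseError(
                        path, line_no, f"sample {sample}: bad AD {parts[ad_i]!r}"
                    ) from None
                if len(depths) != 1 + len(alts):
                    raise VcfParseError(
                        path, line_no,
                        f"sample {sample}: AD arity {len(depths)} != {1 + len(alts)}",
                    )
                for alt, alt_depth in zip(alts, depths[1:]):
                    observations.append(
                        AlleleObservation(
                            sample=sample, position=pos, ref=ref, alt=alt,
                            ref_depth=depths[0], alt_depth=alt_depth,
                        )
                    )
    return observations


def write_vcf_minimal(
    allele_depths: pd.DataFrame,
    path,
    contig: str = "phage",
    contig_length: int | None = None,
):
    """Write a long-form allele-depth table (sample, position, ref, alt,
    ref_depth, alt_depth) as a single-contig VCF with per-sample AD."""
    path = Path(path)
    samples = sorted(allele_depths["sample"].unique())
    lines = ["##fileformat=VCFv4.2"]
    if contig_length:
        lines.append(f"##contig=<ID={contig},length={contig_length}>")
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#" + "\t".join(list(VCF_COLUMNS) + samples))
    for (pos, ref, alt), grp in allele_depths.groupby(
        ["position", "ref", "alt"], sort=True
    ):
        cells = []
        by_sample = grp.set_index("sample")
        for s in samples:
            if s in by_sample.index:
                row = by_sample.loc[s]
                cells.append(f"{int(row.ref_depth)},{int(row.alt_depth)}")
            else:
                cells.append(".")
        lines.append(
            "\t".join(
                [contig, str(pos), ".", ref, alt, ".", "PASS", ".", "AD"] + cells
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def observations_long_frame(observations) -> pd.DataFrame:
    from .filtering import observations_to_frame

    return observations_to_frame(observations)


def write_matrix(matrix: pd.DataFrame, path):
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False):
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def write_truth(truth, path):
    write_json(
        {
            "genotypes": truth.genotypes,
            "positions": list(truth.positions),
            "abundances": {
                s: truth.abundances.loc[s].to_dict() for s in truth.abundances.index
            },
            "phage_fraction": truth.phage_fraction.to_dict(),
            "event_log": truth.event_log,
        },
        path,
    )
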