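"""Readers and writers for the pipeline's on-disk formats.

Domains travel as BED6-like TSV (chrom, start, end, name, timing, strand
with ``+`` = right-replicating and ``-`` = left-replicating), timing
profiles as bedGraph, origins and masks as 3-column BED, mutations as TSV
(sample, chrom, pos, ref, alt[, context]) or per-sample VCF, catalogs and
signatures as labeled TSV.  All interval files are 0-based half-open;
mutation positions are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exposures import DirectionalSignature
from .mutation_types import TYPE96_LABELS, TYPE192_LABELS
from .regions import GenomicInterval, ReplicationDomain, TimingProfile

_STRAND_TO_DIRECTION = {"+": "right", "-": "left"}
_DIRECTION_TO_STRAND = {"right": "+", "left": "-"}


def read_bed(path) -> list[GenomicInterval]:
    """3+ column BED -> intervals (masks, origins)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_domains(path) -> list[ReplicationDomain]:
    """BED6-like domain TSV -> domains; strand column encodes direction."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(f)}")
            if f[5] not in _STRAND_TO_DIRECTION:
                raise ValueError(f"{path}:{ln}: invalid direction strand {f[5]!r}")
            out.append(
                ReplicationDomain(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    _STRAND_TO_DIRECTION[f[5]],
                    float(f[4]),
                )
            )
    return out


def write_domains(domains: list[ReplicationDomain], path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(domains):
            iv = d.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tdomain_{i}\t"
                f"{d.timing:.6g}\t{_DIRECTION_TO_STRAND[d.direction]}\n"
            )


def read_timing_bedgraph(path) -> TimingProfile:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "timing"])
    return TimingProfile.from_frame(df)


def write_timing_bedgraph(profile: TimingProfile, path) -> None:
    with open(path, "w") as fh:
        for chrom, (starts, ends, values) in sorted(profile.bins.items()):
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_mutations_tsv(path) -> pd.DataFrame:
    """Mutation TSV with header: sample, chrom, pos, ref, alt[, context]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_mutations_tsv(df: pd.DataFrame, path) -> None:
    cols = ["sample", "chrom", "pos", "ref", "alt"] + (
        ["context"] if "context" in df.columns else []
    )
    df[cols].to_csv(path, sep="\t", index=False)


def read_mutations_vcf(path, sample_id: str | None = None) -> pd.DataFrame:
    """SNVs from a VCF; multi-allelic records are split per alternate allele
    and non-SNV alleles dropped.  ``sample_id`` defaults to the file stem."""
    from cyvcf2 import VCF

    sample = sample_id or Path(path).stem.removesuffix(".vcf")
    rows = []
    for rec in VCF(str(path)):
        if rec.REF is None or len(rec.REF) != 1 or rec.REF not in "ACGT":
            continue
        for alt in rec.ALT:
            if len(alt) == 1 and alt in "ACGT":
                rows.append((sample, rec.CHROM, rec.POS, rec.REF, alt))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


def write_vcf(df: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """Minimal single-sample VCF writer for simulated cohorts."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, size in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if list(df.columns) != list(TYPE192_LABELS):
        raise ValueError(f"{path}: catalog columns are not the canonical 192 labels")
    return df


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index_label="sample")


def read_reference_signatures(path) -> pd.DataFrame:
    """Tab-delimited 96 x N reference (e.g. COSMIC-style) signature matrix.

    Rows must be labeled with the canonical 96 type labels (any order);
    returns the frame reindexed to canonical order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(TYPE96_LABELS):
        raise ValueError(f"{path}: row labels are not the 96 canonical mutation types")
    return df.loc[list(TYPE96_LABELS)]


def write_directional_signatures(sigs: list[DirectionalSignature], path) -> None:
    """Signature TSV: 96 rows; per signature a weight and direction column."""
    data = {}
    for s in sigs:
        data[f"{s.name}:weight"] = s.weights
        data[f"{s.name}:direction"] = np.where(s.leading_mask, "leading", "lagging")
    pd.DataFrame(data, index=pd.Index(TYPE96_LABELS, name="type")).to_csv(path, sep="\t")


def read_directional_signatures(path) -> list[DirectionalSignature]:
    df = pd.read_csv(path, sep="\t", index_col="type").loc[list(TYPE96_LABELS)]
    names = sorted({c.rsplit(":", 1)[0] for c in df.columns})
    out = []
    for name in names:
        out.append(
            DirectionalSignature(
                name,
                df[f"{name}:weight"].to_numpy(float),
                df[f"{name}:direction"].to_numpy(object) == "leading",
            )
        )
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
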