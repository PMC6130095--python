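"""Strand-resolved mutation catalogs.

Somatic SNVs are classified into the 96 pyrimidine-centric trinucleotide
types, oriented to the replication template strand of the pyrimidine
(leading vs lagging) using left/right-replicating domain annotations, and
accumulated into per-sample 192-element count catalogs.  Catalogs (or
signatures) can be renormalized by the trinucleotide composition of each
template strand relative to the whole genome, which makes strand-specific
spectra comparable with genome-based reference signatures.

Template-assignment rule: in a left-replicating region the reference (plus)
strand is the leading-strand template, so a pyrimidine seen on the plus
strand mutated there is a leading-template mutation; in a right-replicating
region the roles are swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutation_types import (
    N_TRINUC_32,
    N_TYPES_192,
    TRINUC64_CENTER_IS_PYR,
    TRINUC64_TO_PYR32,
    TYPE96_TO_TRINUC32,
    TYPE192_LABELS,
    classify_arrays,
    encode_bases,
    trinuc64_codes,
)
from .regions import LEFT, GenomicInterval, ReplicationDomain, mask_domains

REJECT_REASONS = (
    "ok",
    "ref_equals_alt",
    "non_acgt",
    "context_mismatch",
    "outside_domain",
    "masked",
    "unknown_chrom",
)

#: (pyrimidine_on_plus, direction) -> template. Plus strand is the leading
#: template in left-replicating regions.
def assign_template(pyr_on_plus: bool, direction: str) -> str:
    if direction == LEFT:
        return "leading" if pyr_on_plus else "lagging"
    return "lagging" if pyr_on_plus else "leading"


@dataclass
class TrinucFrequencies:
    """Counts of the 32 pyrimidine-centric 3-mers per template strand class,
    plus whole-genome counts (a site counts once; its two strand-symmetric
    readings are the same pyrimidine-centric class)."""

    leading: np.ndarray
    lagging: np.ndarray
    genome: np.ndarray

    def __post_init__(self):
        for arr in (self.leading, self.lagging, self.genome):
            if arr.shape != (N_TRINUC_32,):
                raise ValueError("expected 32-element trinucleotide count vectors")


def _genome_seq(genome, chrom: str) -> str:
    seq = genome[chrom]
    return str(seq[:]) if hasattr(seq, "__getitem__") and not isinstance(seq, str) else str(seq)


def count_trinucleotides(
    genome,
    domains: list[ReplicationDomain],
    masks: list[GenomicInterval] | None = None,
) -> TrinucFrequencies:
    """Count pyrimidine-centric 3-mers per template class over (masked)
    domains, and over the whole genome.

    ``genome`` is a mapping chromosome -> sequence (a dict of strings or a
    ``pyfaidx.Fasta``).  For each unmasked domain position the plus-strand
    3-mer centred there contributes to the template class its central
    pyrimidine sits on (purine centres contribute their reverse complement
    to the opposite class).  Positions containing N are skipped.
    """
    leading = np.zeros(N_TRINUC_32, dtype=np.int64)
    lagging = np.zeros(N_TRINUC_32, dtype=np.int64)
    genome_counts = np.zeros(N_TRINUC_32, dtype=np.int64)
    encoded: dict[str, np.ndarray] = {}
    chroms = {d.interval.chrom for d in domains} | set(
        genome.keys() if hasattr(genome, "keys") else []
    )
    for chrom in sorted(chroms):
        encoded[chrom] = encode_bases(_genome_seq(genome, chrom))
        codes = trinuc64_codes(encoded[chrom])
        valid = codes >= 0
        genome_counts += np.bincount(
            TRINUC64_TO_PYR32[codes[valid]], minlength=N_TRINUC_32
        )
    effective = mask_domains(domains, masks) if masks else domains
    for d in effective:
        enc = encoded.get(d.interval.chrom)
        if enc is None:
            continue
        start, end = d.interval.start, d.interval.end
        if end > len(enc):
            warnings.warn(
                f"domain {d.interval.chrom}:{start}-{end} beyond chromosome end; truncated"
            )
            end = len(enc)
        if end <= start:
            continue
        codes = trinuc64_codes(enc[max(start - 1, 0):min(end + 1, len(enc))])
        # centers correspond to genomic positions start..end-1
        offset = 1 if start > 0 else 0
        codes = codes[offset:offset + (end - start)] if start > 0 else codes[:end - start]
        valid = codes >= 0
        codes = codes[valid]
        tri32 = TRINUC64_TO_PYR32[codes]
        pyr_plus = TRINUC64_CENTER_IS_PYR[codes]
        # template of the pyrimidine: plus-centre -> assign(plus, dir)
        plus_leads = d.direction == LEFT
        lead_sel = pyr_plus if plus_leads else ~pyr_plus
        leading += np.bincount(tri32[lead_sel], minlength=N_TRINUC_32)
        lagging += np.bincount(tri32[~lead_sel], minlength=N_TRINUC_32)
    return TrinucFrequencies(leading, lagging, genome_counts)


def classify_mutations(mutations: pd.DataFrame, genome=None) -> pd.DataFrame:
    """Classify SNV records into 96 types and pyrimidine strand.

    ``mutations`` needs columns sample, chrom, pos (1-based), ref, alt and
    optionally context (plus-strand 3-mer centred on pos).  When a genome is
    given, contexts are looked up from it; a context column, if also present,
    is validated against the lookup.  Returns a copy with columns ``type96``
    (-1 for rejected records), ``pyr_on_plus`` and ``reason``.
    """
    df = mutations.copy().reset_index(drop=True)
    n = len(df)
    ref = np.array([_enc1(b) for b in df["ref"].astype(str)], dtype=np.int64)
    alt = np.array([_enc1(b) for b in df["alt"].astype(str)], dtype=np.int64)
    ctx5 = np.full(n, -1, dtype=np.int64)
    ctx3 = np.full(n, -1, dtype=np.int64)
    ctx_center = np.full(n, -1, dtype=np.int64)
    reason = np.zeros(n, dtype=np.int64)  # index into REJECT_REASONS

    have_col = "context" in df.columns
    if have_col:
        ctx = df["context"].astype(str).str.upper()
        ok3 = ctx.str.len() == 3
        enc = np.full((n, 3), -1, dtype=np.int64)
        for i, c in enumerate(ctx):
            if len(c) == 3:
                enc[i] = [_enc1(c[0]), _enc1(c[1]), _enc1(c[2])]
        ctx5, ctx_center, ctx3 = enc[:, 0], enc[:, 1], enc[:, 2]
        ctx5[~ok3.to_numpy()] = -1

    if genome is not None:
        g5 = np.full(n, -1, dtype=np.int64)
        gc = np.full(n, -1, dtype=np.int64)
        g3 = np.full(n, -1, dtype=np.int64)
        for chrom, idx in df.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            try:
                enc = encode_bases(_genome_seq(genome, str(chrom)))
            except KeyError:
                reason[idx] = REJECT_REASONS.index("unknown_chrom")
                continue
            pos0 = df.loc[idx, "pos"].to_numpy(np.int64) - 1
            inb = (pos0 >= 1) & (pos0 < len(enc) - 1)
            g5[idx[inb]] = enc[pos0[inb] - 1]
            gc[idx[inb]] = enc[pos0[inb]]
            g3[idx[inb]] = enc[pos0[inb] + 1]
        if have_col:
            mismatch = (
                ((ctx5 >= 0) & (g5 >= 0) & (ctx5 != g5))
                | ((ctx_center >= 0) & (gc >= 0) & (ctx_center != gc))
                | ((ctx3 >= 0) & (g3 >= 0) & (ctx3 != g3))
            )
            reason[mismatch & (reason == 0)] = REJECT_REASONS.index("context_mismatch")
        ctx5 = np.where(g5 >= 0, g5, ctx5)
        ctx_center = np.where(gc >= 0, gc, ctx_center)
        ctx3 = np.where(g3 >= 0, g3, ctx3)

    # context centre must equal ref
    center_bad = (ctx_center >= 0) & (ref >= 0) & (ctx_center != ref)
    reason[center_bad & (reason == 0)] = REJECT_REASONS.index("context_mismatch")
    same = (ref == alt) & (ref >= 0)
    reason[same & (reason == 0)] = REJECT_REASONS.index("ref_equals_alt")
    bad_base = (ref < 0) | (alt < 0) | (ctx5 < 0) | (ctx3 < 0)
    reason[bad_base & (reason == 0)] = REJECT_REASONS.index("non_acgt")

    type96, pyr_on_plus = classify_arrays(ref, alt, ctx5, ctx3)
    type96[reason != 0] = -1
    df["type96"] = type96
    df["pyr_on_plus"] = pyr_on_plus
    df["reason"] = [REJECT_REASONS[r] if r else ("ok" if t >= 0 else "non_acgt")
                    for r, t in zip(reason, type96)]
    return df


def _enc1(b: str) -> int:
    return {"A": 0, "C": 1, "G": 2, "T": 3}.get(b.upper(), -1) if len(b) == 1 else -1


def _domain_lookup(domains: list[ReplicationDomain]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sorted({d.interval.chrom for d in domains}):
        ds = sorted(
            (d for d in domains if d.interval.chrom == chrom),
            key=lambda d: d.interval.start,
        )
        by_chrom[chrom] = (
            np.array([d.interval.start for d in ds], dtype=np.int64),
            np.array([d.interval.end for d in ds], dtype=np.int64),
            np.array([d.direction == LEFT for d in ds]),
            np.array(ds, dtype=object),
        )
    return by_chrom


def annotate_templates(
    classified: pd.DataFrame,
    domains: list[ReplicationDomain],
    masks: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Attach the containing domain and template strand to classified records.

    Records outside every domain get reason ``outside_domain``; records in a
    domain but inside a mask get ``masked``.  Adds columns ``template``
    (leading/lagging or NA) and ``domain`` (the ReplicationDomain or NA).
    """
    df = classified.copy().reset_index(drop=True)
    n = len(df)
    template = np.full(n, None, dtype=object)
    domain_of = np.full(n, None, dtype=object)
    reason = df["reason"].to_numpy(object)

    full = _domain_lookup(domains)
    effective = _domain_lookup(mask_domains(domains, masks)) if masks else full
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        ok = np.array([reason[i] == "ok" for i in idx])
        idx = idx[ok]
        if len(idx) == 0:
            continue
        pos0 = df.loc[idx, "pos"].to_numpy(np.int64) - 1
        if str(chrom) not in full:
            reason[idx] = "outside_domain"
            continue
        starts, ends, _, _ = full[str(chrom)]
        j = np.searchsorted(starts, pos0, side="right") - 1
        inside = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        reason[idx[~inside]] = "outside_domain"
        # now check against masked (effective) intervals
        estarts, eends, eleft, eds = effective.get(
            str(chrom), (np.array([], np.int64), np.array([], np.int64),
                         np.array([], bool), np.array([], object))
        )
        sub = idx[inside]
        p = pos0[inside]
        if len(estarts):
            k = np.searchsorted(estarts, p, side="right") - 1
            kept = (k >= 0) & (p < eends[np.clip(k, 0, len(eends) - 1)])
        else:
            kept = np.zeros(len(sub), dtype=bool)
        reason[sub[~kept]] = "masked"
        for i, ki in zip(sub[kept], k[kept] if len(estarts) else []):
            d = eds[ki]
            domain_of[i] = d
            template[i] = assign_template(bool(df.at[i, "pyr_on_plus"]), d.direction)
    df["reason"] = reason
    df["template"] = template
    df["domain"] = domain_of
    return df


def build_catalog(
    mutations: pd.DataFrame,
    domains: list[ReplicationDomain],
    masks: list[GenomicInterval] | None = None,
    genome=None,
    stratify_by: dict[ReplicationDomain, str] | None = None,
) -> tuple[pd.DataFrame | dict[str, pd.DataFrame], pd.DataFrame]:
    """Build per-sample 192-element strand catalogs.

    Returns ``(catalog, drop_log)``.  Without stratification the catalog is a
    samples x 192 integer DataFrame with canonical column labels.  With
    ``stratify_by`` (a domain -> stratum mapping, e.g. timing quartiles) a
    dict of per-stratum catalogs is returned; the drop log counts records
    per rejection reason.
    """
    classified = classify_mutations(mutations, genome=genome)
    annotated = annotate_templates(classified, domains, masks=masks)
    samples = sorted(annotated["sample"].astype(str).unique())
    drop = (
        annotated.groupby("reason").size().rename("count").reset_index()
    )

    def _accumulate(sub: pd.DataFrame) -> pd.DataFrame:
        mat = np.zeros((len(samples), N_TYPES_192), dtype=np.int64)
        srow = {s: i for i, s in enumerate(samples)}
        ok = sub[sub["reason"] == "ok"]
        if len(ok):
            rows = ok["sample"].astype(str).map(srow).to_numpy(np.int64)
            cols = ok["type96"].to_numpy(np.int64) + np.where(
                ok["template"].to_numpy(object) == "leading", 0, 96
            )
            np.add.at(mat, (rows, cols), 1)
        return pd.DataFrame(mat, index=pd.Index(samples, name="sample"),
                            columns=list(TYPE192_LABELS))

    if stratify_by is None:
        return _accumulate(annotated), drop
    strata: dict[str, pd.DataFrame] = {}
    labels = annotated["domain"].map(lambda d: stratify_by.get(d) if d is not None else None)
    for label in sorted({v for v in stratify_by.values()}):
        strata[label] = _accumulate(annotated[labels == label])
    return strata, drop


def _norm_factors(
    freqs: TrinucFrequencies,
    on_zero: str,
    pseudocount: float,
    check_positive: np.ndarray | None,
) -> np.ndarray:
    """Per-192-column factor genome_count / strand_count."""
    tri = TYPE96_TO_TRINUC32
    factors = np.empty(N_TYPES_192, dtype=float)
    for block, strand_counts in ((0, freqs.leading), (96, freqs.lagging)):
        div = strand_counts[tri].astype(float)
        num = freqs.genome[tri].astype(float)
        zero = div == 0
        if np.any(zero):
            if on_zero == "pseudocount":
                div = div + pseudocount
            else:
                cols = block + np.where(zero)[0]
                if check_positive is not None and np.any(check_positive[cols]):
                    raise ValueError(
                        "zero strand trinucleotide count with nonzero catalog entries; "
                        "set on_zero='pseudocount' to impute"
                    )
                div = np.where(zero, 1.0, div)  # entries are zero anyway
                num = np.where(zero, 0.0, num)
        factors[block:block + 96] = num / div
    return factors


def normalize_catalog(
    data,
    freqs: TrinucFrequencies,
    on_zero: str = "error",
    pseudocount: float = 0.5,
):
    """Rescale 192-channel counts to genome-wide trinucleotide composition.

    Each (type, template) entry is divided by the count of the type's
    3-mer on that template strand and multiplied by its whole-genome count,
    so strand-specific spectra become comparable with genome-based reference
    signatures.  Accepts a samples x 192 DataFrame, a 192-vector, or a
    192 x K matrix; returns the same shape, real-valued.
    """
    values, put_back = _as_192(data)
    has_pos = (np.abs(values) > 0).any(axis=0)
    factors = _norm_factors(freqs, on_zero, pseudocount, has_pos)
    return put_back(values * factors)


def denormalize_catalog(
    data,
    freqs: TrinucFrequencies,
    on_zero: str = "error",
    pseudocount: float = 0.5,
):
    """Inverse of :func:`normalize_catalog` (multiply by strand/genome)."""
    values, put_back = _as_192(data)
    has_pos = (np.abs(values) > 0).any(axis=0)
    factors = _norm_factors(freqs, on_zero, pseudocount, has_pos)
    inv = np.where(factors > 0, 1.0 / np.where(factors > 0, factors, 1.0), 0.0)
    return put_back(values * inv)


def _as_192(data):
    """View input as (n, 192) float array + a function restoring the shape."""
    if isinstance(data, pd.DataFrame):
        values = data.to_numpy(float)
        if values.shape[1] != N_TYPES_192:
            raise ValueError("DataFrame must have 192 columns")
        return values, lambda v: pd.DataFrame(v, index=data.index, columns=data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != N_TYPES_192:
            raise ValueError("vector must have length 192")
        return arr[None, :], lambda v: v[0]
    if arr.shape[0] == N_TYPES_192:  # 192 x K matrix (signatures)
        return arr.T, lambda v: v.T
    if arr.shape[1] == N_TYPES_192:
        return arr, lambda v: v
    raise ValueError("cannot interpret input as 192-channel data")
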