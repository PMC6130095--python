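"""Synthetic genomes, replication annotations and mutation cohorts.

Every pipeline stage can be exercised against planted ground truth: a
random genome with controllable base composition, evenly spaced replication
origins with a triangular timing profile (origins are timing minima,
termini maxima, matching the package's rtu orientation where larger values
mean later replication), alternating left/right 20-kbp domains, a library
of directional signatures, and per-sample mutation lists drawn from
signature mixtures with a configurable matching:inverse strand-asymmetry
ratio and per-quartile rate multipliers.

Two generators are provided.  :func:`make_cohort` emits positioned,
plus-strand SNV records by sampling genomic sites compatible with each
drawn strand-resolved channel, so trinucleotide normalization and the
whole catalog stage are genuinely exercised.  :func:`simulate_catalogs`
skips placement and draws 192-element count catalogs directly from the
planted strand spectra; it is the fast route for cohort-statistics
calibration, where genomic position is irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import assign_template
from .exposures import DirectionalSignature
from .mutation_types import (
    BASES,
    N_TYPES_96,
    N_TYPES_192,
    TRINUC32_TO_CODE64,
    TYPE96_TO_TRINUC32,
    encode_bases,
    trinuc64_codes,
)
from .regions import (
    LEFT,
    RIGHT,
    GenomicInterval,
    QUARTILE_LABELS,
    ReplicationDomain,
    TimingProfile,
    assign_timing_quartiles,
)

#: default per-quartile (Q1 early .. Q4 late) mutation-rate multipliers,
#: emulating the roughly twofold increase from early- to late-replicating DNA
DEFAULT_QUARTILE_MULTIPLIERS = (1.0, 1.3, 1.6, 2.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic cohort."""

    signatures: list[DirectionalSignature]
    exposures: np.ndarray  # n_samples x n_signatures, relative weights
    asymmetry_ratio: float = 3.0
    quartile_multipliers: tuple = DEFAULT_QUARTILE_MULTIPLIERS
    seed: int | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.ndim != 2 or self.exposures.shape[1] != len(self.signatures):
            raise ValueError("exposures must be n_samples x n_signatures")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.exposures.shape[0])]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "asymmetry_ratio": self.asymmetry_ratio,
            "quartile_multipliers": list(self.quartile_multipliers),
            "sample_ids": self.sample_ids,
            "exposures": self.exposures.tolist(),
            "signatures": [
                {
                    "name": s.name,
                    "weights": s.weights.tolist(),
                    "leading_mask": s.leading_mask.astype(int).tolist(),
                }
                for s in self.signatures
            ],
        }


def strand_spectrum(sig: DirectionalSignature, asymmetry_ratio: float) -> np.ndarray:
    """Planted 192-element strand-resolved spectrum of a signature.

    A fraction r/(1+r) of each type's weight goes to its flagged template
    and 1/(1+r) to the other, with r the matching:inverse asymmetry ratio.
    """
    r = float(asymmetry_ratio)
    on, off = r / (1.0 + r), 1.0 / (1.0 + r)
    spec = np.zeros(N_TYPES_192)
    lead = sig.leading_mask
    spec[:N_TYPES_96] = sig.weights * np.where(lead, on, off)
    spec[N_TYPES_96:] = sig.weights * np.where(lead, off, on)
    return spec


def make_signatures(
    n: int,
    seed: int | None = None,
    n_active_types: int = 8,
    group_flags: bool = True,
) -> list[DirectionalSignature]:
    """Well-separated random directional signatures.

    Each signature concentrates its mass on ``n_active_types`` types drawn
    without replacement from a disjoint partition of the 96-type space (so
    planted signatures have near-orthogonal support).  Direction flags are
    drawn per substitution group when ``group_flags`` (each group wholly
    leading or lagging, the common real pattern), else per type.
    """
    rng = np.random.default_rng(seed)
    if n * n_active_types > N_TYPES_96:
        raise ValueError("too many signatures for disjoint support")
    perm = rng.permutation(N_TYPES_96)
    sigs = []
    for j in range(n):
        active = perm[j * n_active_types:(j + 1) * n_active_types]
        w = np.zeros(N_TYPES_96)
        w[active] = rng.dirichlet(np.full(n_active_types, 2.0))
        if group_flags:
            per_group = rng.random(6) < 0.5
            mask = np.repeat(per_group, 16)
        else:
            mask = rng.random(N_TYPES_96) < 0.5
        sigs.append(DirectionalSignature(f"planted_{j}", w, mask, provenance="planted"))
    return sigs


def make_truth(
    n_samples: int = 40,
    n_signatures: int = 5,
    seed: int | None = None,
    asymmetry_ratio: float = 3.0,
    quartile_multipliers: tuple = DEFAULT_QUARTILE_MULTIPLIERS,
    exposure_alpha: float = 2.0,
) -> SyntheticTruth:
    """Planted cohort configuration: signatures plus Dirichlet exposures."""
    rng = np.random.default_rng(seed)
    sigs = make_signatures(n_signatures, seed=rng.integers(2**31))
    expo = rng.dirichlet(np.full(n_signatures, exposure_alpha), size=n_samples)
    return SyntheticTruth(sigs, expo, asymmetry_ratio, tuple(quartile_multipliers), seed)


def make_genome(
    seed: int | None = None,
    n_chrom: int = 2,
    chrom_length: int = 4_000_000,
    gc_bias: float = 0.41,
    cpg_factor: float = 1.0,
) -> dict[str, str]:
    """Random genome with configurable GC content.

    With ``cpg_factor`` != 1 a first-order Markov chain scales the
    probability of G following C (CpG enrichment/depletion); otherwise
    bases are i.i.d.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    genome = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        if cpg_factor == 1.0:
            ints = rng.choice(4, size=chrom_length, p=p)
        else:
            T = np.tile(p, (4, 1))
            T[1, 2] *= cpg_factor  # C -> G
            T /= T.sum(axis=1, keepdims=True)
            cum = np.cumsum(T, axis=1)
            u = rng.random(chrom_length)
            ints = np.empty(chrom_length, dtype=np.int64)
            prev = int(rng.choice(4, p=p))
            for i in range(chrom_length):
                prev = int(np.searchsorted(cum[prev], u[i]))
                ints[i] = prev
        genome[name] = base_arr[ints].tobytes().decode()
    return genome


def make_domains(
    genome: dict[str, str],
    domain_width: int = 20_000,
    replicon_length: int = 1_000_000,
    timing_range: tuple[float, float] = (100.0, 500.0),
    profile_bin: int = 1_000,
) -> tuple[list[ReplicationDomain], TimingProfile, list[GenomicInterval]]:
    """Alternating left/right domains around evenly spaced origins.

    Origins sit at replicon_length/2, 3/2 replicon_length, ... on each
    chromosome; timing rises linearly (triangular wave) from ``timing_min``
    at an origin to ``timing_max`` at termini/chromosome ends, so a
    right-replicating half-replicon has positive timing slope.  Domains
    tile each monotone segment with fixed-width windows; the bedGraph-like
    profile and the origin intervals are returned alongside.
    """
    t_min, t_max = timing_range
    half = replicon_length // 2
    domains: list[ReplicationDomain] = []
    origins: list[GenomicInterval] = []
    prof_rows = []
    for chrom in sorted(genome):
        L = len(genome[chrom])
        origin_mids = list(range(half, L - half + 1, replicon_length))
        for mid in origin_mids:
            origins.append(GenomicInterval(chrom, mid - 500, mid + 500))

        def timing_at(pos: np.ndarray) -> np.ndarray:
            dist = np.min(
                np.abs(pos[:, None] - np.array(origin_mids)[None, :]), axis=1
            )
            return t_min + (t_max - t_min) * np.minimum(dist, half) / half

        starts = np.arange(0, L - profile_bin + 1, profile_bin)
        mids = starts + profile_bin / 2.0
        prof_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + profile_bin,
                 "timing": timing_at(mids)}
            )
        )
        # monotone segment boundaries: chromosome ends, origins, termini
        bounds = sorted({0, L} | {m for m in origin_mids}
                        | {m + half for m in origin_mids if m + half < L}
                        | {m - half for m in origin_mids if m - half > 0})
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            seg_mid = (b0 + b1) / 2
            nearest = min(origin_mids, key=lambda m: abs(m - seg_mid))
            direction = LEFT if seg_mid < nearest else RIGHT
            for w0 in range(b0, b1 - domain_width + 1, domain_width):
                w1 = w0 + domain_width
                centers = np.arange(w0, w1, profile_bin) + profile_bin / 2.0
                domains.append(
                    ReplicationDomain(
                        GenomicInterval(chrom, w0, w1),
                        direction,
                        float(timing_at(centers).mean()),
                    )
                )
    profile = TimingProfile.from_frame(pd.concat(prof_rows, ignore_index=True))
    return domains, profile, origins


def _site_index(genome, domains, quartile_multipliers):
    """Weighted site pools keyed by (plus-strand 3-mer code, direction)."""
    quartiles = assign_timing_quartiles(domains)
    mult = {q: m for q, m in zip(QUARTILE_LABELS, quartile_multipliers)}
    encoded = {c: encode_bases(genome[c]) for c in genome}
    codes = {c: trinuc64_codes(encoded[c]) for c in genome}
    chrom_names = sorted(genome)
    chrom_id = {c: i for i, c in enumerate(chrom_names)}
    pools: dict[tuple[int, str], list] = {}
    for d in domains:
        c = d.interval.chrom
        cd = codes[c][d.interval.start:d.interval.end]
        pos = np.arange(d.interval.start, d.interval.end)
        ok = cd >= 0
        cd, pos = cd[ok], pos[ok]
        order = np.argsort(cd, kind="stable")
        cd, pos = cd[order], pos[order]
        edges = np.searchsorted(cd, np.arange(65))
        w = mult[quartiles[d]]
        for code in np.unique(cd):
            seg = pos[edges[code]:edges[code + 1]]
            pools.setdefault((int(code), d.direction), []).append(
                (chrom_id[c], seg, w)
            )
    index = {}
    for key, parts in pools.items():
        positions = np.concatenate([p for _, p, _ in parts])
        chroms = np.concatenate([np.full(len(p), ci) for ci, p, _ in parts])
        weights = np.concatenate([np.full(len(p), w) for _, p, w in parts])
        index[key] = (chroms, positions, np.cumsum(weights))
    return index, chrom_names


def _channel_buckets(t96: int, template: str) -> list[tuple[int, str, bool]]:
    """(3-mer code, domain direction, centre_is_pyrimidine) site classes
    compatible with a strand-resolved channel."""
    tri32 = int(TYPE96_TO_TRINUC32[t96])
    code_pyr = int(TRINUC32_TO_CODE64[tri32])
    a, rest = divmod(code_pyr, 16)
    b, c = divmod(rest, 4)
    code_pur = 16 * (3 - c) + 4 * (3 - b) + (3 - a)
    out = []
    for direction in (LEFT, RIGHT):
        if assign_template(True, direction) == template:
            out.append((code_pyr, direction, True))
        if assign_template(False, direction) == template:
            out.append((code_pur, direction, False))
    return out


def make_cohort(
    genome: dict[str, str],
    domains: list[ReplicationDomain],
    truth: SyntheticTruth,
    mutations_per_sample: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Positioned SNV records for a synthetic cohort.

    Per sample the mutation count is Poisson around ``mutations_per_sample``;
    each mutation draws a signature by the sample's exposure weights and a
    192-channel from the signature's strand-resolved spectrum (planted
    asymmetry ratio applied), then a genomic position uniformly among the
    sites whose plus-strand trinucleotide and template orientation match
    the channel, weighted by the per-quartile rate multipliers.  Records
    are emitted as plus-strand (sample, chrom, pos, ref, alt, context)
    rows.  Channels with no compatible site are resampled within the
    signature and logged via a warning.
    """
    rng = np.random.default_rng(seed)
    index, chrom_names = _site_index(genome, domains, truth.quartile_multipliers)
    spectra = np.stack(
        [strand_spectrum(s, truth.asymmetry_ratio) for s in truth.signatures]
    )
    # per-channel availability
    channel_sites = []
    for ch in range(N_TYPES_192):
        t96, template = ch % 96, ("leading" if ch < 96 else "lagging")
        buckets = [
            (code, direction, pyr)
            for code, direction, pyr in _channel_buckets(t96, template)
            if (code, direction) in index
        ]
        channel_sites.append(buckets)
    available = np.array([len(b) > 0 for b in channel_sites])
    n_resampled = 0

    rows = {"sample": [], "chrom": [], "pos": [], "ref": [], "alt": [], "context": []}
    enc_genome = {c: genome[c] for c in chrom_names}
    for i, sample in enumerate(truth.sample_ids):
        n_mut = rng.poisson(mutations_per_sample)
        sig_counts = rng.multinomial(n_mut, truth.exposures[i])
        channel_counts = np.zeros(N_TYPES_192, dtype=np.int64)
        for j, cnt in enumerate(sig_counts):
            if cnt == 0:
                continue
            spec = spectra[j].copy()
            missing = ~available & (spec > 0)
            if missing.any():
                n_resampled += int(cnt * spec[missing].sum())
                spec[missing] = 0.0
                spec /= spec.sum()
            channel_counts += rng.multinomial(cnt, spec)
        for ch in np.nonzero(channel_counts)[0]:
            cnt = int(channel_counts[ch])
            t96 = ch % 96
            sub = t96 // 16
            alt_pyr = ("A", "G", "T", "A", "C", "G")[sub]  # pyrimidine-strand alt
            # split the channel's draws across its compatible site classes
            buckets = channel_sites[ch]
            totals = np.array([index[(c, d)][2][-1] for c, d, _ in buckets])
            split = rng.multinomial(cnt, totals / totals.sum())
            for (code, direction, pyr), m in zip(buckets, split):
                if m == 0:
                    continue
                chroms, positions, cumw = index[(code, direction)]
                u = rng.random(m) * cumw[-1]
                sel = np.searchsorted(cumw, u, side="right")
                sel = np.clip(sel, 0, len(positions) - 1)
                for s_i in sel:
                    c_name = chrom_names[chroms[s_i]]
                    p0 = int(positions[s_i])
                    ctx = enc_genome[c_name][p0 - 1:p0 + 2]
                    ref = ctx[1]
                    alt = alt_pyr if pyr else {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_pyr]
                    rows["sample"].append(sample)
                    rows["chrom"].append(c_name)
                    rows["pos"].append(p0 + 1)
                    rows["ref"].append(ref)
                    rows["alt"].append(alt)
                    rows["context"].append(ctx)
    if n_resampled:
        warnings.warn(f"{n_resampled} draws hit channels without compatible sites; resampled")
    df = pd.DataFrame(rows)
    return df.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_catalogs(
    truth: SyntheticTruth,
    mutations_per_sample: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Counts-level cohort: per-sample 192-element catalogs, no genome.

    Each sample's total is Poisson around ``mutations_per_sample`` and its
    channel counts multinomial from the exposure-weighted mixture of the
    planted strand-resolved spectra.  Returns a samples x 192 DataFrame
    with canonical column labels.
    """
    from .mutation_types import TYPE192_LABELS

    rng = np.random.default_rng(seed)
    spectra = np.stack(
        [strand_spectrum(s, truth.asymmetry_ratio) for s in truth.signatures]
    )
    n = truth.exposures.shape[0]
    mat = np.zeros((n, N_TYPES_192), dtype=np.int64)
    for i in range(n):
        mix = truth.exposures[i] @ spectra
        mix = mix / mix.sum()
        mat[i] = rng.multinomial(rng.poisson(mutations_per_sample), mix)
    return pd.DataFrame(mat, index=pd.Index(list(truth.sample_ids), name="sample"),
                        columns=list(TYPE192_LABELS))
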