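"""Cohort-level replication-asymmetry statistics.

The cohort questions are paired and non-parametric: per signature, do more
samples have matching than inverse exposure (strand asymmetry), and do
per-sample exposures rise or fall with replication-timing quartile?  Both
use the exact two-sided binomial sign test across samples, with
Benjamini-Hochberg correction across signatures within each metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom


def sign_test(values) -> float:
    """Exact two-sided binomial sign test.

    Zeros are discarded; with n nonzero values of which k are positive the
    p-value doubles the smaller tail of Binomial(n, 1/2), capped at 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("sign_test needs at least one value")
    v = v[v != 0]
    n = v.size
    if n == 0:
        warnings.warn("all values are zero; sign test undefined, returning p=1")
        return 1.0
    k = int((v > 0).sum())
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def tukey_outliers(values, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier split: fences at q25 - k*IQR and q75 + k*IQR.

    Quartiles use linear interpolation (numpy default).  Returns boolean
    masks (kept, outlier) aligned with the input.
    """
    v = np.asarray(values, dtype=float)
    q25, q75 = np.quantile(v, [0.25, 0.75])
    iqr = q75 - q25
    lo, hi = q25 - k * iqr, q75 + k * iqr
    outlier = (v < lo) | (v > hi)
    return ~outlier, outlier


def cohort_asymmetry(
    exposure_table: pd.DataFrame,
    min_exposure: float = 10.0,
    tukey_k: float | None = None,
) -> pd.DataFrame:
    """Per-signature strand-asymmetry summary across a cohort.

    ``exposure_table`` is the long table from
    :meth:`replisig.exposures.ExposureDecomposer.transform` (columns sample,
    signature, e_matching, e_inverse, difference).  Per signature, samples
    with total exposure >= ``min_exposure`` enter the sign test on the
    matching-inverse differences; ``tukey_k`` optionally removes
    Tukey-fence outliers on the differences first.  Returns one row per
    signature with n_exposed, n_outliers, median_difference, pct_matching,
    p and BH q (signatures with zero exposed samples are NA and excluded
    from the BH family).
    """
    rows = []
    for sig, sub in exposure_table.groupby("signature", sort=True):
        total = sub["e_matching"] + sub["e_inverse"]
        exposed = sub[total >= min_exposure]
        n_out = 0
        if len(exposed) and tukey_k is not None and len(exposed) >= 4:
            kept, out = tukey_outliers(exposed["difference"].to_numpy(), k=tukey_k)
            n_out = int(out.sum())
            exposed = exposed[kept]
        if len(exposed) == 0:
            rows.append({"signature": sig, "n_exposed": 0, "n_outliers": n_out,
                         "median_difference": np.nan, "pct_matching": np.nan,
                         "p": np.nan})
            continue
        diff = exposed["difference"].to_numpy(float)
        rows.append(
            {
                "signature": sig,
                "n_exposed": int(len(exposed)),
                "n_outliers": n_out,
                "median_difference": float(np.median(diff)),
                "pct_matching": 100.0 * float((diff > 0).mean()),
                "p": sign_test(diff),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_correct(out["p"].to_numpy())
    return out


def _slope(y: np.ndarray, x: np.ndarray) -> float:
    s = float(np.polyfit(x, y, 1)[0])
    # constant exposures must yield an exact zero so the sign test drops them
    if abs(s) < 1e-9 * max(1.0, float(np.abs(y).max())):
        return 0.0
    return s


def timing_trend(
    quartile_exposures: pd.DataFrame,
    min_exposure: float = 10.0,
    predictor: str = "index",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-signature replication-timing trend across a cohort.

    ``quartile_exposures`` is a long table with columns sample, signature,
    quartile (1..4 or 'Q1'..'Q4'), e_matching, e_inverse (one row per
    sample x signature x quartile, from running the exposure decomposition
    on per-quartile catalogs).  Per sample and signature an OLS line of
    exposure versus quartile index (or mean timing, with
    ``predictor='timing'`` and a ``timing`` column) gives a slope for the
    total, matching and inverse exposures; the cohort p-value is the sign
    test on the per-sample total-exposure slopes, BH-corrected across
    signatures.

    Returns ``(summary, quartile_means)``: per-signature summary with
    median slopes, pct_positive, p, q; and per signature x quartile mean
    and standard error of matching and inverse exposures for profile plots.
    """
    df = quartile_exposures.copy()
    qcol = df["quartile"]
    if qcol.dtype == object:
        df["qidx"] = qcol.astype(str).str.lstrip("Q").astype(int)
    else:
        df["qidx"] = qcol.astype(int)
    x_col = "timing" if predictor == "timing" else "qidx"
    rows = []
    means = []
    for sig, sub in df.groupby("signature", sort=True):
        slopes_total, slopes_m, slopes_i = [], [], []
        for _, s in sub.groupby("sample"):
            if len(s) < 2:
                continue
            total = (s["e_matching"] + s["e_inverse"]).to_numpy(float)
            if total.sum() < min_exposure:
                continue
            x = s[x_col].to_numpy(float)
            slopes_total.append(_slope(total, x))
            slopes_m.append(_slope(s["e_matching"].to_numpy(float), x))
            slopes_i.append(_slope(s["e_inverse"].to_numpy(float), x))
        if not slopes_total:
            rows.append({"signature": sig, "n": 0, "median_slope": np.nan,
                         "median_slope_matching": np.nan,
                         "median_slope_inverse": np.nan,
                         "pct_positive": np.nan, "p": np.nan})
        else:
            st = np.array(slopes_total)
            rows.append(
                {
                    "signature": sig,
                    "n": len(st),
                    "median_slope": float(np.median(st)),
                    "median_slope_matching": float(np.median(slopes_m)),
                    "median_slope_inverse": float(np.median(slopes_i)),
                    "pct_positive": 100.0 * float((st > 0).mean()),
                    "p": sign_test(st),
                }
            )
        for q, qs in sub.groupby("qidx"):
            for kind in ("e_matching", "e_inverse"):
                vals = qs[kind].to_numpy(float)
                means.append(
                    {
                        "signature": sig,
                        "quartile": int(q),
                        "orientation": kind.removeprefix("e_"),
                        "mean": float(vals.mean()) if len(vals) else np.nan,
                        "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1 else np.nan,
                    }
                )
    summary = pd.DataFrame(rows)
    summary["q"] = bh_correct(summary["p"].to_numpy())
    return summary, pd.DataFrame(means)


def plus_minus_exposures(
    per_bin_tables: dict,
    bin_directions: dict,
    signatures,
) -> pd.DataFrame:
    """Reattribute per-bin matching/inverse exposures to the plus and minus
    reference strands.

    ``per_bin_tables`` maps a bin key (e.g. signed origin-relative index)
    to the long exposure table of the catalog restricted to that bin, and
    ``bin_directions`` maps the same keys to the bin's replication
    direction.  For a signature whose dominant flag is the leading
    template, the matching exposure sits on the plus strand where the plus
    strand is the leading template (left-replicating bins) and on the
    minus strand otherwise; lagging-dominant signatures are the mirror
    case.  Returns a long frame (sample, signature, bin, strand, exposure)
    ready for :func:`spatial_profile`.
    """
    dominant_leading = {
        s.name: float(s.weights[s.leading_mask].sum()) >= float(
            s.weights[~s.leading_mask].sum())
        for s in signatures
    }
    rows = []
    for key, table in per_bin_tables.items():
        direction = bin_directions[key]
        for r in table.itertuples():
            lead_on_plus = direction == "left"
            matching_on_plus = dominant_leading[r.signature] == lead_on_plus
            e_plus = r.e_matching if matching_on_plus else r.e_inverse
            e_minus = r.e_inverse if matching_on_plus else r.e_matching
            rows.append({"sample": r.sample, "signature": r.signature,
                         "bin": key, "strand": "plus", "exposure": e_plus})
            rows.append({"sample": r.sample, "signature": r.signature,
                         "bin": key, "strand": "minus", "exposure": e_minus})
    return pd.DataFrame(rows)


def spatial_profile(
    bin_exposures: pd.DataFrame,
    tukey_k: float | None = 2.0,
) -> pd.DataFrame:
    """Mean exposure profile across spatial bins (transitions or origins).

    ``bin_exposures`` is a long table with columns sample, signature, bin
    (signed bin index relative to the anchor), strand ('plus'/'minus') and
    exposure.  Per signature, samples flagged as Tukey outliers on their
    total exposure are removed; the result has the across-sample mean and
    standard error per signature x bin x strand (SE is NaN with a single
    sample; bins with no data are absent rather than zero).
    """
    df = bin_exposures
    out = []
    for sig, sub in df.groupby("signature", sort=True):
        if tukey_k is not None:
            totals = sub.groupby("sample")["exposure"].sum()
            if len(totals) >= 4:
                kept, _ = tukey_outliers(totals.to_numpy(), k=tukey_k)
                sub = sub[sub["sample"].isin(totals.index[kept])]
        for (b, strand), g in sub.groupby(["bin", "strand"]):
            v = g["exposure"].to_numpy(float)
            out.append(
                {
                    "signature": sig,
                    "bin": b,
                    "strand": strand,
                    "mean": float(v.mean()),
                    "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
            )
    return pd.DataFrame(out)
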