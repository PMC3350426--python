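"""Two-color array normalization, feature-level error, and replicate combination.

Each array is linearly normalized (channel medians equalized over
well-above-background probes), then LOWESS-normalized on the M-vs-A
representation to remove intensity-dependent dye bias.  Dye-swap replicate
pairs are combined per probe by error-weighted averaging: each replicate's
oriented log2 ratio is weighted inversely to its variance, where the
per-replicate variance is the larger of a technology error (delta-method
propagation of additive + multiplicative intensity noise to the log2-ratio
scale) and the pooled between-replicate scatter.  Taking the maximum guards
against under-estimating error with only two replicates, which would
inflate false positives.  p-values come from a two-sided z test on the
weighted mean ratio.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

LN2 = math.log(2.0)

#: Columns of a probe-level input table.
PROBE_COLUMNS = ("probe_id", "gene_symbol", "red_raw", "green_raw",
                 "bg_mean", "bg_sd")


def background_threshold(background: np.ndarray) -> float:
    """99th percentile of the background population, nearest-rank convention."""
    bg = np.sort(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("background population is empty")
    rank = max(int(math.ceil(0.99 * bg.size)) - 1, 0)
    return float(bg[rank])


def well_above_background(
    red_raw: np.ndarray, green_raw: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """True where both raw channels strictly exceed the 99th percentile of
    the array's background signal population."""
    thr = background_threshold(background)
    red = np.asarray(red_raw, dtype=float)
    green = np.asarray(green_raw, dtype=float)
    return (red > thr) & (green > thr)


def linear_normalize(array: pd.DataFrame) -> pd.DataFrame:
    """Equalize channel medians over well-above-background probes.

    The red channel is the reference: green intensities are rescaled by
    ``median(red) / median(green)`` computed over the well-above-background
    probes.  Returns a copy with ``red``/``green`` normalized-intensity
    columns added.
    """
    out = array.copy()
    wab = well_above_background(out["red_raw"], out["green_raw"], out["bg_mean"])
    if not wab.any():
        raise ValueError("no well-above-background probes; cannot normalize")
    med_red = float(np.median(out.loc[wab, "red_raw"]))
    med_green = float(np.median(out.loc[wab, "green_raw"]))
    if med_red <= 0 or med_green <= 0:
        raise ValueError("degenerate input: a channel median is not positive")
    out["red"] = out["red_raw"].astype(float)
    out["green"] = out["green_raw"].astype(float) * (med_red / med_green)
    out["well_above_background"] = wab
    return out


def lowess_normalize(array: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Remove the intensity-dependent trend of M = log2(red/green).

    Fits a locally weighted regression of M on A = (log2 red + log2 green)/2
    (tricube weights, two robustness iterations) and subtracts the fit.
    ``linear_normalize`` must have been applied first.  Probes with a
    non-positive channel carry NaN for M and A.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if "red" not in array.columns or "green" not in array.columns:
        raise ValueError("run linear_normalize before lowess_normalize")
    out = array.copy()
    red = out["red"].to_numpy(dtype=float)
    green = out["green"].to_numpy(dtype=float)
    ok = (red > 0) & (green > 0)
    m = np.full(red.shape, np.nan)
    a = np.full(red.shape, np.nan)
    m[ok] = np.log2(red[ok] / green[ok])
    a[ok] = 0.5 * (np.log2(red[ok]) + np.log2(green[ok]))

    # Fit the trend on well-above-background probes only: probes at
    # background carry no dye information and their wild ratios would bend
    # the curve near the low-intensity edge.  The fitted curve is applied
    # to every probe, held constant beyond the fitted intensity range.
    if "well_above_background" in out.columns:
        wab = out["well_above_background"].to_numpy(dtype=bool)
    else:
        wab = well_above_background(out["red_raw"], out["green_raw"],
                                    out["bg_mean"])
    fit_mask = ok & wab
    fit = np.zeros_like(m)
    if fit_mask.sum() >= 10 and np.ptp(a[fit_mask]) > 0:
        curve = _sm_lowess(m[fit_mask], a[fit_mask], frac=span, it=2,
                           return_sorted=True)
        # Local regression is unstable where probes are sparse: beyond the
        # central 95% intensity range the local window is dominated by a
        # handful of probes whose chance regulation masquerades as a dye
        # trend, so the correction is held constant there.  The residual
        # dye bias this leaves at the tails is dye-swap-antisymmetric and
        # cancels in the oriented replicate mean.
        lo, hi = np.quantile(a[fit_mask], [0.025, 0.975])
        fit[ok] = np.interp(np.clip(a[ok], lo, hi), curve[:, 0], curve[:, 1])
    m_corr = m - fit
    # Re-express the correction in the channels, preserving A.
    out["red"] = np.where(ok, 2.0 ** (a + 0.5 * m_corr), red)
    out["green"] = np.where(ok, 2.0 ** (a - 0.5 * m_corr), green)
    out["M"] = m_corr
    out["A"] = a
    if "well_above_background" not in out.columns:
        out["well_above_background"] = well_above_background(
            out["red_raw"], out["green_raw"], out["bg_mean"]
        )
    return out


def normalize_array(array: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Linear then LOWESS normalization in one call."""
    return lowess_normalize(linear_normalize(array), span=span)


def _ma(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    red = table["red"].to_numpy(dtype=float)
    green = table["green"].to_numpy(dtype=float)
    ok = (red > 0) & (green > 0)
    m = np.full(red.shape, np.nan)
    a = np.full(red.shape, np.nan)
    m[ok] = np.log2(red[ok] / green[ok])
    a[ok] = 0.5 * (np.log2(red[ok]) + np.log2(green[ok]))
    return m, a, ok


def normalize_swap_pair(tables: list[pd.DataFrame],
                        span: float = 0.3) -> list[pd.DataFrame]:
    """Intensity-dependent normalization for a balanced dye-swap group.

    With equally many swapped and unswapped arrays, the per-probe mean of
    the *unoriented* M values cancels the biological signal and leaves the
    dye-bias curve plus noise, so the curve can be fitted free of signal
    composition — per-array fitting instead absorbs whatever real
    regulation is locally correlated with intensity, and that error is
    common-mode and survives dye-swap averaging.  The shared fitted curve
    is subtracted from every array (same sign: the bias follows the dye).
    Arrays must be linearly normalized and share one probe layout.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    mas = [_ma(t) for t in tables]
    ok_all = np.logical_and.reduce([ok for _, _, ok in mas])
    wab_all = np.logical_and.reduce(
        [t["well_above_background"].to_numpy(dtype=bool) for t in tables])
    mean_m = np.mean([m for m, _, _ in mas], axis=0)
    mean_a = np.mean([a for _, a, _ in mas], axis=0)

    fit_mask = ok_all & wab_all & np.isfinite(mean_m)
    fit = np.zeros(len(tables[0]))
    if fit_mask.sum() >= 10 and np.ptp(mean_a[fit_mask]) > 0:
        curve = _sm_lowess(mean_m[fit_mask], mean_a[fit_mask], frac=span,
                           it=2, return_sorted=True)
        lo, hi = np.quantile(mean_a[fit_mask], [0.025, 0.975])
        fit = np.where(
            np.isfinite(mean_a),
            np.interp(np.clip(mean_a, lo, hi), curve[:, 0], curve[:, 1]),
            0.0,
        )

    out = []
    for table, (m, a, ok) in zip(tables, mas):
        t = table.copy()
        m_corr = m - fit
        t["red"] = np.where(ok, 2.0 ** (a + 0.5 * m_corr), t["red"])
        t["green"] = np.where(ok, 2.0 ** (a - 0.5 * m_corr), t["green"])
        t["M"] = m_corr
        t["A"] = a
        out.append(t)
    return out


def feature_sigma(
    red: np.ndarray, green: np.ndarray, sigma_add: float, sigma_mult: float
) -> np.ndarray:
    """Technology error of a probe's log2 ratio (log2 units).

    Delta-method propagation of the additive + multiplicative noise model
    through log2(red/green):

        sigma_tech^2 = [ (sigma_add^2/red^2 + sigma_mult^2)
                       + (sigma_add^2/green^2 + sigma_mult^2) ] / ln(2)^2

    Strictly decreasing in each intensity; NaN (the undefined-error signal)
    where an intensity is not positive — such probes are excluded, never
    silently imputed.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sigma_add**2 / red**2 + sigma_mult**2
               + sigma_add**2 / green**2 + sigma_mult**2) / LN2**2
    return np.where((red > 0) & (green > 0), np.sqrt(var), np.nan)


def combine_replicates(
    ratios: np.ndarray, sigmas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Error-weighted average of oriented replicate log2 ratios.

    ``ratios`` and ``sigmas`` have shape (k, n): k replicates (already
    negated into a common orientation) by n probes.  Weights are 1/sigma^2.
    Returns (weighted_log2_ratio, combined_sigma, p_value) arrays of shape
    (n,); the p-value is the two-sided normal tail of ratio/sigma.
    """
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    sigmas = np.atleast_2d(np.asarray(sigmas, dtype=float))
    if ratios.shape[0] == 0:
        raise ValueError("no replicates to combine")
    if ratios.shape != sigmas.shape:
        raise ValueError("ratios and sigmas must have the same shape")
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    w = 1.0 / sigmas**2
    wsum = w.sum(axis=0)
    mean = (ratios * w).sum(axis=0) / wsum
    sigma = wsum**-0.5
    p = 2.0 * stats.norm.sf(np.abs(mean) / sigma)
    return mean, sigma, p


def pooled_replicate_variance(
    oriented: np.ndarray,
    intensity: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    n_bins: int = 10,
) -> np.ndarray:
    """Between-replicate variance of oriented log2 ratios, pooled over probes.

    Replicate scatter on two-color arrays depends strongly on intensity,
    so per-probe variances (which are extremely noisy with two replicates)
    are pooled within ``n_bins`` intensity quantile bins rather than into
    a single scalar — a scalar would overstate the error of bright probes
    and understate that of dim ones.

    Dye-swap pairs disagree systematically by twice the residual dye-bias
    curve, a component that cancels exactly in the oriented pair mean and
    therefore must not be charged to the mean's error.  Because the true
    signal cancels in the per-replicate deviations, that curve can be
    estimated composition-free: each replicate's deviation is smoothed
    against log intensity and the smooth is subtracted before pooling.

    ``mask`` restricts which probes inform the pooling (normally the
    well-above-background ones, since background-level ratios scatter
    with background noise, not replicate reproducibility).  Returns one
    pooled variance per probe.
    """
    oriented = np.asarray(oriented, dtype=float)
    k, n = oriented.shape
    if k < 2:
        return np.zeros(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN probes
        resid = oriented - np.nanmean(oriented, axis=0, keepdims=True)
    pool_mask = np.isfinite(resid).all(axis=0)
    if mask is not None and (pool_mask & mask).any():
        pool_mask &= np.asarray(mask, dtype=bool)
    if not pool_mask.any():
        return np.zeros(n)

    if intensity is not None and pool_mask.sum() >= 50:
        log_i = np.log2(np.maximum(np.asarray(intensity, dtype=float), 1e-12))
        for j in range(k):
            curve = _sm_lowess(resid[j, pool_mask], log_i[pool_mask],
                               frac=0.3, it=2, return_sorted=True)
            resid[j, pool_mask] -= np.interp(log_i[pool_mask],
                                             curve[:, 0], curve[:, 1])

    def pooled(sel: np.ndarray) -> float:
        r = resid[:, sel]
        return float((r**2).sum() / (r.shape[1] * (k - 1)))

    if intensity is None:
        return np.full(n, pooled(pool_mask))
    intensity = np.asarray(intensity, dtype=float)
    edges = np.quantile(intensity[pool_mask],
                        np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.digitize(intensity, edges)
    out = np.full(n, pooled(pool_mask))
    for b in range(n_bins):
        sel = pool_mask & (bins == b)
        if sel.sum() >= 20:
            out[bins == b] = pooled(sel)
    return out


def summarize_comparison(
    arrays,
    sigma_add: float,
    sigma_mult: float,
    span: float = 0.3,
    min_sigma: float = 1e-6,
) -> pd.DataFrame:
    """Normalize and combine the replicate arrays of one comparison.

    ``arrays`` is a sequence of ``ArrayData`` objects (or ``(table,
    swapped)`` pairs) sharing one probe layout.  Dye-swapped replicates
    have their M values negated into the canonical orientation.  Balanced
    dye-swap groups are normalized with a shared, composition-free bias
    curve (see :func:`normalize_swap_pair`); unbalanced groups fall back
    to per-array LOWESS.  Returns a per-probe frame with columns gene_id,
    probe_id, log2_ratio, sigma, p_value, intensity, wab; probes unusable
    on every array carry NaN statistics and wab False.
    """
    if len(arrays) == 0:
        raise ValueError("no arrays supplied for comparison")
    tables, swaps = [], []
    for arr in arrays:
        if hasattr(arr, "table"):
            tables.append(arr.table)
            swaps.append(arr.swapped)
        else:
            table, swapped = arr
            tables.append(table)
            swaps.append(bool(swapped))

    linear = [linear_normalize(t) for t in tables]
    if sum(swaps) * 2 == len(swaps):
        norm = normalize_swap_pair(linear, span=span)
    else:
        norm = [lowess_normalize(t, span=span) for t in linear]
    base = norm[0]
    n = len(base)
    oriented = np.empty((len(norm), n))
    sig_tech = np.empty((len(norm), n))
    intensity = np.zeros(n)
    wab = np.ones(n, dtype=bool)
    for i, (nt, swapped) in enumerate(zip(norm, swaps)):
        if not nt["probe_id"].equals(base["probe_id"]):
            raise ValueError("replicate arrays have different probe layouts")
        m = nt["M"].to_numpy()
        oriented[i] = -m if swapped else m
        sig_tech[i] = feature_sigma(
            nt["red"].to_numpy(), nt["green"].to_numpy(), sigma_add, sigma_mult
        )
        intensity += 0.5 * (nt["red"].to_numpy() + nt["green"].to_numpy())
        wab &= nt["well_above_background"].to_numpy()
    intensity /= len(norm)

    sigma_rep2 = pooled_replicate_variance(oriented, intensity=intensity,
                                           mask=wab)
    # Floor keeps weights defined in the noiseless limit (log2 units).
    sigmas = np.sqrt(np.maximum(np.maximum(sig_tech**2, sigma_rep2),
                                min_sigma**2))

    usable = np.isfinite(oriented).all(axis=0) & np.isfinite(sigmas).all(axis=0)
    ratio = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    p = np.full(n, np.nan)
    if usable.any():
        ratio[usable], sigma[usable], p[usable] = combine_replicates(
            oriented[:, usable], sigmas[:, usable]
        )
    return pd.DataFrame({
        "gene_id": base["gene_symbol"].to_numpy(),
        "probe_id": base["probe_id"].to_numpy(),
        "log2_ratio": ratio,
        "sigma": sigma,
        "p_value": p,
        "intensity": intensity,
        "wab": wab & usable,
    })


def summarize_experiment(
    arrays_by_comparison: dict[str, list],
    sigma_add: float,
    sigma_mult: float,
    span: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """``summarize_comparison`` for every comparison of an experiment."""
    return {
        cid: summarize_comparison(arrs, sigma_add, sigma_mult, span=span)
        for cid, arrs in arrays_by_comparison.items()
    }
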