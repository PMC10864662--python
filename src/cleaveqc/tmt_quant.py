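"""TMT reference-channel relative quantitation and differential statistics.

The chain: reporter intensities become log2 ratios against the mean of the
reference (pooled) channels within a plex; PSM-level ratios are cleaned by
recursive Dixon outlier removal within (peptide, channel) groups of more than
two PSMs; medians roll PSMs up to peptides and peptides up to proteins;
per-channel protein-ratio distributions are aligned so the mode of a fitted
two-component Gaussian mixture sits at zero and scaled so percentile-trimmed
standard deviations are equalized across channels; finally an empirical-Bayes
moderated two-sample t-test with Benjamini–Hochberg adjustment calls
differential abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PSM_LEVEL = "psm"
PEPTIDE_LEVEL = "peptide"
PROTEIN_LEVEL = "protein"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ReporterMatrix:
    """PSM-level reporter intensities: one row per PSM, one column per channel.

    ``data`` must carry ``psm_id``, ``peptide`` and ``protein`` columns (plus
    optionally ``plex``); every other column named in ``channel_roles`` is a
    reporter channel with role "sample" or "reference".
    """

    data: pd.DataFrame
    channel_roles: dict[str, str]

    def __post_init__(self):
        missing = [c for c in ("psm_id", "peptide", "protein") if c not in self.data.columns]
        if missing:
            raise ValueError(f"reporter matrix missing columns: {missing}")
        roles = set(self.channel_roles.values())
        if not roles <= {"sample", "reference"}:
            raise ValueError(f"unknown channel roles: {roles - {'sample', 'reference'}}")
        if "reference" not in roles:
            raise ValueError("reporter matrix has no reference channel")
        absent = [c for c in self.channel_roles if c not in self.data.columns]
        if absent:
            raise ValueError(f"channels missing from data: {absent}")

    @property
    def sample_channels(self) -> list[str]:
        return [c for c, r in self.channel_roles.items() if r == "sample"]

    @property
    def reference_channels(self) -> list[str]:
        return [c for c, r in self.channel_roles.items() if r == "reference"]


@dataclass
class LogRatioTable:
    """Long-format log2 ratios vs the reference pool, at PSM/peptide/protein level."""

    level: str
    data: pd.DataFrame  # columns: unit keys..., channel, log2_ratio, mean_reporter_intensity
    n_dropped_zero_reference: int = 0


@dataclass
class MixtureFit:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    density_mode: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Ratio formation
# ---------------------------------------------------------------------------

def to_log_ratios(matrix: ReporterMatrix) -> LogRatioTable:
    """PSM-level log2 ratios relative to the mean reference-channel intensity.

    Rows whose reference mean is zero are dropped and counted. Zero intensities
    in a sample channel are treated as missing for that channel only (the
    zero-feature-area convention), not floored.
    """
    ref = matrix.reference_channels
    smp = matrix.sample_channels
    df = matrix.data
    ref_mean = df[ref].mean(axis=1)
    keep = ref_mean > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d PSM rows with zero reference mean", n_dropped)
    df = df.loc[keep]
    ref_mean = ref_mean.loc[keep]
    all_channels = smp + ref
    mean_intensity = df[all_channels].mean(axis=1)

    blocks = []
    for ch in smp:
        vals = df[ch].to_numpy(dtype=float)
        ok = vals > 0
        block = pd.DataFrame(
            {
                "psm_id": df["psm_id"].to_numpy()[ok],
                "peptide": df["peptide"].to_numpy()[ok],
                "protein": df["protein"].to_numpy()[ok],
                "channel": ch,
                "log2_ratio": np.log2(vals[ok] / ref_mean.to_numpy()[ok]),
                "mean_reporter_intensity": mean_intensity.to_numpy()[ok],
            }
        )
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=["psm_id", "peptide", "protein", "channel", "log2_ratio", "mean_reporter_intensity"]
    )
    return LogRatioTable(PSM_LEVEL, out, n_dropped_zero_reference=n_dropped)


# ---------------------------------------------------------------------------
# Dixon's Q test
# ---------------------------------------------------------------------------

# Two-tailed critical values (Rorabacher 1991), n = 3..30.
# Variant schedule: r10 for 3<=n<=7, r11 for 8<=n<=10, r21 for 11<=n<=13, r22 for n>=14.
_DIXON_CRITICAL = {
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
        8: 0.608, 9: 0.564, 10: 0.530,
        11: 0.619, 12: 0.583, 13: 0.557,
        14: 0.586, 15: 0.565, 16: 0.546, 17: 0.529, 18: 0.514, 19: 0.501,
        20: 0.489, 21: 0.478, 22: 0.468, 23: 0.459, 24: 0.451, 25: 0.443,
        26: 0.436, 27: 0.429, 28: 0.423, 29: 0.417, 30: 0.412,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
        8: 0.717, 9: 0.672, 10: 0.635,
        11: 0.709, 12: 0.660, 13: 0.638,
        14: 0.670, 15: 0.647, 16: 0.627, 17: 0.610, 18: 0.594, 19: 0.580,
        20: 0.567, 21: 0.555, 22: 0.544, 23: 0.535, 24: 0.526, 25: 0.517,
        26: 0.510, 27: 0.502, 28: 0.495, 29: 0.489, 30: 0.483,
    },
}
_DIXON_MAX_N = 30


def _dixon_statistic(sorted_vals: np.ndarray) -> tuple[float, int]:
    """Two-sided Dixon ratio: test whichever extreme is more discordant.

    Returns (ratio, index-of-suspect) where the index refers to the sorted
    array (0 for the low extreme, n-1 for the high). The numerator/denominator
    gaps follow the variant schedule for the current n.
    """
    n = len(sorted_vals)
    if n <= 7:
        i, j = 1, 0  # r10: gap to nearest neighbour / full range
    elif n <= 10:
        i, j = 1, 1  # r11
    elif n <= 13:
        i, j = 2, 1  # r21
    else:
        i, j = 2, 2  # r22
    x = sorted_vals
    denom_high = x[-1] - x[j]
    denom_low = x[n - 1 - j] - x[0]
    r_high = (x[-1] - x[-1 - i]) / denom_high if denom_high > 0 else 0.0
    r_low = (x[i] - x[0]) / denom_low if denom_low > 0 else 0.0
    if r_high >= r_low:
        return r_high, n - 1
    return r_low, 0


def dixon_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[float]]:
    """Recursive two-sided Dixon outlier removal.

    Groups of two or fewer are never altered. At each pass the most extreme
    value is tested against the tabulated critical value for the current group
    size (variant by n; sizes above the table's reach are left unfiltered) and
    removed if the ratio exceeds it; recursion stops at the first
    non-rejection or when fewer than three values remain. Returns
    (retained, removed); retained preserves input order.
    """
    if alpha not in _DIXON_CRITICAL:
        raise ValueError(f"alpha must be one of {sorted(_DIXON_CRITICAL)}; got {alpha}")
    vals = [float(v) for v in values]
    if len(vals) <= 2:
        return vals, []
    removed: list[float] = []
    current = list(vals)
    while len(current) >= 3:
        n = len(current)
        if n > _DIXON_MAX_N:
            break
        srt = np.sort(np.asarray(current, dtype=float))
        if srt[-1] == srt[0]:
            break
        ratio, idx = _dixon_statistic(srt)
        if ratio > _DIXON_CRITICAL[alpha][n]:
            suspect = srt[idx]
            current.remove(suspect)
            removed.append(float(suspect))
        else:
            break
    return current, removed


def dixon_filter_table(
    table: LogRatioTable, alpha: float = 0.05
) -> tuple[LogRatioTable, int]:
    """Apply :func:`dixon_filter` within every (peptide, channel) PSM group.

    Only groups with more than two PSMs are touched. Returns the filtered
    table and the number of removed PSM entries.
    """
    if table.level != PSM_LEVEL:
        raise ValueError("Dixon filtering applies at the PSM level")
    df = table.data
    sizes = df.groupby(["peptide", "channel"], sort=False)["log2_ratio"].transform("size")
    small = df[sizes <= 2]
    big = df[sizes > 2]
    kept_parts = [small]
    n_removed = 0
    for _, grp in big.groupby(["peptide", "channel"], sort=False):
        retained, removed = dixon_filter(grp["log2_ratio"].tolist(), alpha)
        if removed:
            n_removed += len(removed)
            # drop the removed values (first occurrence each, matching dixon_filter)
            mask = np.ones(len(grp), dtype=bool)
            vals = grp["log2_ratio"].to_numpy()
            for r in removed:
                hit = np.flatnonzero(mask & (vals == r))
                if len(hit):
                    mask[hit[0]] = False
            kept_parts.append(grp[mask])
        else:
            kept_parts.append(grp)
    out = pd.concat(kept_parts).sort_index()
    return LogRatioTable(PSM_LEVEL, out, table.n_dropped_zero_reference), n_removed


# ---------------------------------------------------------------------------
# Median roll-up
# ---------------------------------------------------------------------------

def rollup(table: LogRatioTable, to_level: str) -> LogRatioTable:
    """Median roll-up: PSM ratios -> peptide ratio -> protein ratio.

    The intensity column is carried as the mean reporter intensity of the
    contributing rows.
    """
    df = table.data
    if table.level == PSM_LEVEL and to_level == PEPTIDE_LEVEL:
        keys = ["protein", "peptide", "channel"]
    elif table.level == PEPTIDE_LEVEL and to_level == PROTEIN_LEVEL:
        keys = ["protein", "channel"]
    else:
        raise ValueError(f"cannot roll up from {table.level} to {to_level}")
    agg = (
        df.groupby(keys, sort=True)
        .agg(
            log2_ratio=("log2_ratio", "median"),
            mean_reporter_intensity=("mean_reporter_intensity", "mean"),
        )
        .reset_index()
    )
    return LogRatioTable(to_level, agg, table.n_dropped_zero_reference)


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture and mode location
# ---------------------------------------------------------------------------

def _mixture_density(x: np.ndarray, weights, means, sds) -> np.ndarray:
    x = np.asarray(x, dtype=float)[:, None]
    return (sps.norm.pdf(x, loc=np.asarray(means), scale=np.asarray(sds))
            * np.asarray(weights)).sum(axis=1)


def fit_mixture(values: Sequence[float], k: int = 2, seed: int = 0) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM and locate its density mode.

    EM runs to a 1e-8 log-likelihood tolerance (max 500 iterations) over five
    seeded restarts, the first initialized by a quantile split of the data.
    The mode is found by a 2001-point grid search over the data range followed
    by local refinement.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(x) < 20:
        raise ValueError(f"need >= 20 finite values to fit a mixture; got {len(x)}")
    if np.ptp(x) == 0:
        c = float(x[0])
        return MixtureFit(
            weights=np.array([1.0]), means=np.array([c]), sds=np.array([0.0]),
            log_likelihood=float("inf"), density_mode=c, degenerate=True,
        )
    X = x[:, None]
    quantile_means = np.quantile(x, np.linspace(0.25, 0.75, k))[:, None]
    best = None
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
    for restart in range(5):
        if restart == 0:
            gm = GaussianMixture(
                n_components=k, tol=1e-8, max_iter=500,
                means_init=quantile_means, random_state=seed,
            )
        else:
            gm = GaussianMixture(
                n_components=k, tol=1e-8, max_iter=500,
                init_params="random", random_state=seed + restart,
            )
        gm.fit(X)
        ll = gm.score(X) * len(x)
        if best is None or ll > best[0]:
            best = (ll, gm)
    ll, gm = best
    weights = gm.weights_.ravel()
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())

    grid = np.linspace(x.min(), x.max(), 2001)
    dens = _mixture_density(grid, weights, means, sds)
    i = int(np.argmax(dens))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -_mixture_density([t], weights, means, sds)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    mode = float(res.x) if res.success else float(grid[i])
    return MixtureFit(weights, means, sds, float(ll), mode)


# ---------------------------------------------------------------------------
# Alignment and scaling normalization
# ---------------------------------------------------------------------------

@dataclass
class ChannelNormalization:
    channel: str
    offset: float
    trimmed_sd: float
    scale_factor: float
    method: str  # "mixture_mode" or "median_fallback"


def _trimmed_sd(ratios: np.ndarray, intensities: np.ndarray,
                trim_percentiles: tuple[float, float]) -> float:
    lo, hi = trim_percentiles
    r_lo, r_hi = np.percentile(ratios, [lo, hi])
    i_lo, i_hi = np.percentile(intensities, [lo, hi])
    mask = (ratios >= r_lo) & (ratios <= r_hi) & (intensities >= i_lo) & (intensities <= i_hi)
    sel = ratios[mask]
    if len(sel) < 2:
        sel = ratios
    return float(np.std(sel, ddof=1))


def align_and_scale(
    protein_table: LogRatioTable,
    trim_percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
    center: str = "mixture_mode",
) -> tuple[LogRatioTable, list[ChannelNormalization]]:
    """Center each channel's protein log-ratio distribution and equalize spread.

    Centering subtracts the mode of a fitted two-component Gaussian mixture
    (the density's maximum-likelihood point; ``center="major_mean"`` uses the
    dominant component's mean instead). Scaling divides each channel's
    centered ratios by (trimmed SD / median trimmed SD across channels), where
    the SD is computed over entries inside both the ratio and the intensity
    percentile bands — so the trimmed SDs end up equal across channels while
    the cross-channel median scale is preserved. Channels with fewer than 20
    entries fall back to median centering, flagged in the diagnostics.
    """
    if protein_table.level != PROTEIN_LEVEL:
        raise ValueError("align_and_scale expects a protein-level table")
    df = protein_table.data.copy()
    channels = sorted(df["channel"].unique())
    offsets: dict[str, float] = {}
    methods: dict[str, str] = {}
    for ch in channels:
        vals = df.loc[df["channel"] == ch, "log2_ratio"].to_numpy(dtype=float)
        if len(vals) < 20:
            offsets[ch] = float(np.median(vals))
            methods[ch] = "median_fallback"
            logger.warning("channel %s: %d entries, median-centering fallback", ch, len(vals))
            continue
        fit = fit_mixture(vals, k=2, seed=seed)
        if center == "major_mean" and not fit.degenerate:
            offsets[ch] = float(fit.means[int(np.argmax(fit.weights))])
        else:
            offsets[ch] = fit.density_mode
        methods[ch] = "mixture_mode" if center != "major_mean" else "major_mean"
    df["log2_ratio"] = df["log2_ratio"] - df["channel"].map(offsets)

    sds: dict[str, float] = {}
    for ch in channels:
        sub = df[df["channel"] == ch]
        sds[ch] = _trimmed_sd(
            sub["log2_ratio"].to_numpy(dtype=float),
            sub["mean_reporter_intensity"].to_numpy(dtype=float),
            trim_percentiles,
        )
    median_sd = float(np.median(list(sds.values())))
    factors = {ch: (sds[ch] / median_sd if sds[ch] > 0 else 1.0) for ch in channels}
    df["log2_ratio"] = df["log2_ratio"] / df["channel"].map(factors)

    diagnostics = [
        ChannelNormalization(ch, offsets[ch], sds[ch], factors[ch], methods[ch])
        for ch in channels
    ]
    return LogRatioTable(PROTEIN_LEVEL, df, protein_table.n_dropped_zero_reference), diagnostics


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

def _invert_trigamma(y: float) -> float:
    # Newton iteration on trigamma(x) = y (limma-style), y > 0.
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to sample variances.

    Works on log variances: for s^2 ~ s0^2 * chi^2_d / d scaled-F under the
    hierarchical model, e = log(s^2) has known digamma/trigamma moments; the
    prior df solves trigamma(d0/2) = var(e) - trigamma(d/2). Zero variances
    are excluded from the fit. Returns (inf, mean s^2 on the log scale) when
    the observed spread is no larger than expected from chi-square alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _invert_trigamma(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    data: pd.DataFrame,
    group1_cols: Sequence[str],
    group2_cols: Sequence[str],
    moderated: bool = True,
    d0_override: Optional[float] = None,
) -> pd.DataFrame:
    """Per-protein two-sample test of group1 (treated) vs group2 (untreated).

    ``data`` is wide: one row per protein (index), replicate ratio columns.
    With ``moderated=True`` a pooled-variance t is shrunk toward an
    empirical-Bayes prior estimated across proteins; posterior variance is
    (d0*s0^2 + d*s^2)/(d0 + d) on d0 + d degrees of freedom. With
    ``moderated=False`` a Welch t is used. Proteins with fewer than two finite
    replicates in either group are reported with ``tested=False``.

    Returns a DataFrame with log2_fc (group1 - group2), t_statistic, p_value,
    p_adjusted (BH across tested proteins), n_per_group and tested.
    """
    g1 = data[list(group1_cols)].to_numpy(dtype=float)
    g2 = data[list(group2_cols)].to_numpy(dtype=float)
    n1 = np.isfinite(g1).sum(axis=1)
    n2 = np.isfinite(g2).sum(axis=1)
    testable = (n1 >= 2) & (n2 >= 2)

    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(np.isfinite(g1), g1, np.nan), axis=1)
        m2 = np.nanmean(np.where(np.isfinite(g2), g2, np.nan), axis=1)
        log2_fc = m1 - m2
        v1 = np.nanvar(np.where(np.isfinite(g1), g1, np.nan), axis=1, ddof=1)
        v2 = np.nanvar(np.where(np.isfinite(g2), g2, np.nan), axis=1, ddof=1)

    t_stat = np.full(len(data), np.nan)
    p_val = np.full(len(data), np.nan)

    if moderated:
        d = n1 + n2 - 2.0
        pooled = np.where(
            testable, ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(d, 1), np.nan
        )
        d_common = float(np.median(d[testable])) if testable.any() else 1.0
        if d0_override is not None:
            d0 = d0_override
            s2_pos = pooled[testable & (pooled > 0)]
            s0_sq = float(np.mean(s2_pos)) if len(s2_pos) else 1.0
        else:
            d0, s0_sq = estimate_variance_prior(pooled[testable], d_common)
        if np.isinf(d0):
            s2_post = np.full_like(pooled, s0_sq)
            df_total = np.full_like(pooled, 1e6)
        else:
            s2_post = (d0 * s0_sq + d * pooled) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        ok = testable & (se > 0)
        t_stat[ok] = log2_fc[ok] / se[ok]
        dft = df_total if np.ndim(df_total) else np.full(len(data), df_total)
        p_val[ok] = 2.0 * sps.t.sf(np.abs(t_stat[ok]), np.minimum(dft[ok], 1e6))
        # degenerate: zero posterior variance (all variances zero)
        zero = testable & (se == 0)
        t_stat[zero & (log2_fc == 0)] = 0.0
        p_val[zero & (log2_fc == 0)] = 1.0
        if (zero & (log2_fc != 0)).any():
            logger.warning(
                "%d proteins with zero shrunken variance and nonzero effect",
                int((zero & (log2_fc != 0)).sum()),
            )
            p_val[zero & (log2_fc != 0)] = 0.0
            t_stat[zero & (log2_fc != 0)] = np.sign(log2_fc[zero & (log2_fc != 0)]) * np.inf
    else:
        for i in np.flatnonzero(testable):
            a = g1[i][np.isfinite(g1[i])]
            b = g2[i][np.isfinite(g2[i])]
            if np.var(a) == 0 and np.var(b) == 0:
                if np.mean(a) == np.mean(b):
                    t_stat[i], p_val[i] = 0.0, 1.0
                else:
                    t_stat[i], p_val[i] = np.sign(np.mean(a) - np.mean(b)) * np.inf, 0.0
                continue
            t_stat[i], p_val[i] = sps.ttest_ind(a, b, equal_var=False)

    p_adj = np.full(len(data), np.nan)
    tested_idx = np.flatnonzero(np.isfinite(p_val))
    if len(tested_idx):
        p_adj[tested_idx] = bh_adjust(p_val[tested_idx])

    return pd.DataFrame(
        {
            "protein": data.index,
            "log2_fc": log2_fc,
            "t_statistic": t_stat,
            "p_value": p_val,
            "p_adjusted": p_adj,
            "n_group1": n1,
            "n_group2": n2,
            "tested": np.isfinite(p_val),
        }
    ).set_index("protein")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
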