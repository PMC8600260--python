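"""Per-gene compensation coefficients and related summaries.

For a gene differentially expressed between the derived strain (KM) and
its progenitor (W), the compensation coefficient measures how far the
back-selected strain ("0"/ZERO) has returned toward the progenitor level,
on the logCPM scale:

    coefficient = 100 * (mean_KM - mean_ZERO) / (mean_KM - mean_W)

100% means the back-selected strain is fully restored to the progenitor
level; values <= 0 mean no compensation (or enhancement of the derived
phenotype); values > 100 mean overcompensation. The coefficient is
undefined when the denominator is within ``eps`` of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COMP_CLASSES = ("compensated", "overcompensated", "uncompensated", "undefined")


@dataclass
class ConcordanceSummary:
    spearman_rho: float
    p_value: float
    n_genes: int
    opposite_fraction: float
    subset_descriptor: str = ""


def compensation_coefficient(
    mean_km: float, mean_zero: float, mean_w: float, eps: float = 1e-6
) -> float:
    """The compensation coefficient in percent; NaN when |KM - W| <= eps."""
    denom = mean_km - mean_w
    if abs(denom) <= eps:
        return math.nan
    return 100.0 * (mean_km - mean_zero) / denom


def coefficient_vector(
    mean_km: np.ndarray, mean_zero: np.ndarray, mean_w: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    denom = np.asarray(mean_km, dtype=float) - np.asarray(mean_w, dtype=float)
    num = np.asarray(mean_km, dtype=float) - np.asarray(mean_zero, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = 100.0 * num / denom
    return np.where(np.abs(denom) > eps, coef, np.nan)


def classify_compensation(coefficient: float) -> str:
    """compensated (0, 100], overcompensated > 100, uncompensated <= 0."""
    if coefficient is None or (isinstance(coefficient, float) and math.isnan(coefficient)):
        return "undefined"
    if coefficient > 100.0:
        return "overcompensated"
    if coefficient > 0.0:
        return "compensated"
    return "uncompensated"


def compensation_table(
    group_means: pd.DataFrame,
    de_km_w: pd.DataFrame,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene compensation records.

    ``group_means`` carries mean_W/mean_KM/mean_ZERO indexed by gene id
    (see normalization.group_mean_logcpm); ``de_km_w`` is the KM-vs-W
    DE result whose p-values tag each record. Coefficients are computed
    for all genes; thresholding happens at analysis time.
    """
    de = de_km_w.set_index("gene_id")
    genes = group_means.index
    coef = coefficient_vector(
        group_means["mean_KM"].to_numpy(),
        group_means["mean_ZERO"].to_numpy(),
        group_means["mean_W"].to_numpy(),
        eps=eps,
    )
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_w": group_means["mean_W"].to_numpy(),
            "mean_km": group_means["mean_KM"].to_numpy(),
            "mean_zero": group_means["mean_ZERO"].to_numpy(),
            "coefficient": coef,
            "comp_class": [classify_compensation(c) for c in coef],
            "de_p_km_w": de["p"].reindex(genes).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def fraction_compensated(
    records: pd.DataFrame,
    p_threshold: float = 0.01,
    interval: str = "open",
) -> tuple[float, int, bool]:
    """Proportion of DEGs whose coefficient lies in the compensated band.

    ``interval`` = 'open' counts coefficients in (0, 100]; 'paper' counts
    the literal [1, 100] band. Returns (fraction, n_qualifying, defined);
    defined is False when no gene qualifies (fraction then NaN).
    """
    qual = records[
        (records["de_p_km_w"] < p_threshold) & records["coefficient"].notna()
    ]
    n = len(qual)
    if n == 0:
        return math.nan, 0, False
    c = qual["coefficient"]
    if interval == "open":
        hits = (c > 0.0) & (c <= 100.0)
    elif interval == "paper":
        hits = (c >= 1.0) & (c <= 100.0)
    else:
        raise ValueError(f"unknown interval {interval!r}")
    return float(hits.mean()), n, True


def concordance(
    fc_a: pd.Series | np.ndarray,
    fc_b: pd.Series | np.ndarray,
    subset: list[str] | None = None,
    subset_descriptor: str = "",
) -> ConcordanceSummary:
    """Spearman correlation and opposite-sign fraction of two logFC vectors.

    When ``subset`` is given, both inputs must be Series indexed by gene id
    and are restricted to it. Exact-zero logFCs count as non-opposite.
    """
    if subset is not None:
        fc_a = pd.Series(fc_a).loc[subset]
        fc_b = pd.Series(fc_b).loc[subset]
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.size != b.size:
        raise ValueError("logFC vectors differ in length")
    if a.size < 3:
        raise ValueError("concordance needs at least 3 genes")
    rho, p = stats.spearmanr(a, b)
    if abs(abs(rho) - 1.0) < 1e-12:  # clamp float noise on perfect rankings
        rho = math.copysign(1.0, rho)
    opposite = float(np.mean((np.sign(a) != np.sign(b)) & (a != 0) & (b != 0)))
    return ConcordanceSummary(float(rho), float(p), int(a.size), opposite, subset_descriptor)


def coefficient_density(
    coefficients, bandwidth: str | float = "silverman", n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of the coefficient distribution.

    Grid spans [min - 4h, max + 4h] (four bandwidths of margin so the
    trapezoid integral captures the kernel tails to better than 1e-3 even
    for tightly clustered data); default bandwidth by Silverman's rule
    h = 0.9 * min(sd, IQR/1.34) * n^(-1/5), with a floor of 1e-6 * data
    range (or 1e-6 absolute for constant data) so degenerate inputs stay
    finite.
    """
    x = np.asarray(pd.Series(coefficients).dropna(), dtype=float)
    if x.size < 2:
        raise ValueError("kernel density needs >= 2 defined coefficients")
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        spread_candidates = [v for v in (sd, iqr / 1.34) if v > 0]
        spread = min(spread_candidates) if spread_candidates else 0.0
        h = 0.9 * spread * x.size ** (-0.2)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    rng_x = float(np.ptp(x))
    h = max(h, 1e-6 * rng_x if rng_x > 0 else 1e-6)
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return grid, density


def top_partition(
    records: pd.DataFrame,
    de_result: pd.DataFrame,
    k: int = 50,
    cutoff: float = 50.0,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k compensated (> cutoff) and least-compensated (<= cutoff) DEGs.

    Candidates are KM-vs-W DEGs with a defined coefficient; within each
    partition the k most significant genes by KM-vs-W p-value are kept and
    ordered from the highest p-value at the top to the lowest at the bottom.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    del de_result  # p-values already joined onto the records
    degs = records[
        (records["de_p_km_w"] < p_threshold) & records["coefficient"].notna()
    ]
    top = degs[degs["coefficient"] > cutoff].nsmallest(k, "de_p_km_w")
    bottom = degs[degs["coefficient"] <= cutoff].nsmallest(k, "de_p_km_w")
    return (
        top.sort_values("de_p_km_w", ascending=False).reset_index(drop=True),
        bottom.sort_values("de_p_km_w", ascending=False).reset_index(drop=True),
    )


def zscore_rows(
    norm, genes: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-transform of logCPM for heat-map display.

    Uses the sample standard deviation (n-1). Constant rows become all
    zeros and are flagged. ``norm`` is a NormalizedTable or a DataFrame
    (genes x samples).
    """
    frame = norm.to_frame() if hasattr(norm, "to_frame") else pd.DataFrame(norm)
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise KeyError(f"genes not in the normalized table: {missing[:5]}")
    sub = frame.loc[genes]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    constant = sd <= 0
    safe_sd = sd.mask(constant, 1.0)
    z = sub.sub(mean, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    return z, constant
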