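"""Effective library sizes (TMM) and log2 counts-per-million.

The trimmed-mean-of-M-values factors and the prior-count logCPM transform
feed both the differential-expression test and the compensation statistic,
so the exact formulas used here are normative for the whole pipeline:

* reference sample: the one whose upper-quartile count fraction is closest
  to the mean upper-quartile fraction across samples;
* per sample, the TMM log2 factor is the precision-weighted mean of
  gene-wise M-values after trimming 30% from each tail of the M
  distribution and 5% from each tail of the A distribution (genes with a
  zero in either sample excluded); factors are rescaled to geometric
  mean 1;
* logcpm[g, s] = log2((count + prior_s) / (eff_lib_s + 2 * prior_s) * 1e6)
  with prior_s = prior * eff_lib_s / mean(eff_lib), prior = 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ROLES, CountTable, SampleSheet


@dataclass
class NormalizedTable:
    gene_ids: list[str]
    sample_ids: list[str]
    logcpm: np.ndarray
    norm_factors: np.ndarray
    effective_lib_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.logcpm, index=self.gene_ids, columns=self.sample_ids)


def tmm_factors(
    counts: CountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: int | None = None,
) -> np.ndarray:
    """Per-sample TMM normalization factors, geometric mean 1."""
    y = counts.counts.astype(float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")

    if ref_sample is None:
        uq = np.array([np.quantile(y[:, s], 0.75) for s in range(y.shape[1])]) / lib
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))

    log2_factors = np.array(
        [
            _tmm_pair(y[:, s], y[:, ref_sample], lib[s], lib[ref_sample], trim_m, trim_a)
            for s in range(y.shape[1])
        ]
    )
    factors = 2.0 ** log2_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    p_obs, p_ref = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M from the binomial count model
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if np.allclose(m, m[0], atol=1e-10):
        return float(m[0])

    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def log_cpm(
    counts: CountTable,
    factors: np.ndarray | None = None,
    prior: float = 0.5,
) -> NormalizedTable:
    """Prior-count log2 CPM on effective (TMM-scaled) library sizes."""
    if prior <= 0:
        raise ValueError("prior count must be positive")
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,) or (factors <= 0).any():
        raise ValueError("factors must be positive, one per sample")
    lib = counts.library_sizes()
    eff = lib * factors
    prior_s = prior * eff / eff.mean()
    logcpm = np.log2(
        (counts.counts + prior_s[None, :]) / (eff + 2 * prior_s)[None, :] * 1e6
    )
    return NormalizedTable(
        list(counts.gene_ids), list(counts.sample_ids), logcpm, factors, eff
    )


def group_mean_logcpm(norm: NormalizedTable, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene mean logCPM of each strain role (columns mean_W/mean_KM/mean_ZERO)."""
    frame = norm.to_frame()
    out = {}
    for role in ROLES:
        samples = [s for s in norm.sample_ids if sheet.assignments.get(s) == role]
        if not samples:
            raise ValueError(f"no samples assigned to role {role}")
        out[f"mean_{role}"] = frame[samples].mean(axis=1)
    result = pd.DataFrame(out)
    result.index.name = "gene_id"
    return result
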