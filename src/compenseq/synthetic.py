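"""Synthetic three-strain count data with known compensation structure.

The generator emulates the study design that motivates this package: a
progenitor outbred strain (W), a derived seizure-prone strain (KM) and a
strain back-selected from KM x W hybrids for absence of the phenotype
("0"/ZERO). Counts are negative-binomial with a mean model

    mu[g, s] = L_s * q[g, s] / sum_g q[g, s],
    q[g, s]  = exp(b_g) * 2 ** (beta_g * I[s in KM] + delta_g * I[s in ZERO])

where ``b_g`` is a per-gene natural-log baseline abundance, ``beta_g`` the
true KM-vs-W log2 effect and ``delta_g`` the true ZERO-vs-W log2 effect.
The NB parameterisation is variance = mu + phi * mu**2 throughout.

Each differentially expressed gene carries a compensation class that fixes
``delta`` relative to ``beta``:

* compensated:     delta = u * beta, u ~ U[0, 0.3)   -> coefficient in (70, 100]
* uncompensated:   delta = v * beta, v ~ U[1.0, 1.5] -> coefficient in [-50, 0]
* overcompensated: delta = -w * beta, w ~ U(0, 0.5]  -> coefficient in (100, 150]

with the true compensation coefficient defined as 100 * (beta - delta) / beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountTable, SampleSheet

CLASSES = ("compensated", "uncompensated", "overcompensated")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design of the motivating study: ~20,000 genes,
    W n=4 / KM n=3 / ZERO n=4 biological replicates, library sizes of
    15-22 million reads, a minority of genes differentially expressed
    between KM and W, and a compensated majority (~70%) among those in the
    back-selected strain. Tests and quick runs override ``n_genes`` and
    ``lib_size_range`` downwards.
    """

    n_genes: int = 20_000
    replicates: dict[str, int] = field(
        default_factory=lambda: {"W": 4, "KM": 3, "ZERO": 4}
    )
    baseline_logmean_range: tuple[float, float] = (math.log(2.0), math.log(4000.0))
    dispersion_params: tuple[float, float] = (0.05, 2.0)
    lib_size_range: tuple[int, int] = (15_000_000, 22_000_000)
    de_fraction: float = 0.08
    effect_size_logfc: float = 1.0
    class_proportions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 2021

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for role in ("W", "KM", "ZERO"):
            if self.replicates.get(role, 0) < 2:
                raise ValueError(
                    f"group {role} needs >= 2 replicates "
                    f"(got {self.replicates.get(role, 0)})"
                )
        lo, hi = self.baseline_logmean_range
        if not lo <= hi:
            raise ValueError("invalid baseline_logmean_range")
        phi0, scale = self.dispersion_params
        if phi0 < 0 or scale < 0:
            raise ValueError("dispersion parameters must be >= 0")
        llo, lhi = self.lib_size_range
        if not (0 < llo <= lhi):
            raise ValueError("invalid lib_size_range")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_size_logfc <= 0:
            raise ValueError("effect_size_logfc must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be non-negative")


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountTable, SampleSheet, pd.DataFrame]:
    """Draw a count matrix, its sample sheet and the per-gene truth table.

    The truth table has columns gene_id, baseline, dispersion, beta, delta,
    is_de, true_class and true_coefficient (NaN for null genes). Output is
    a deterministic function of the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    lo, hi = config.baseline_logmean_range
    baseline = rng.uniform(lo, hi, size=n)
    phi0, scale = config.dispersion_params
    dispersion = phi0 + scale / np.exp(baseline)

    is_de = rng.random(n) < config.de_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    beta = np.where(is_de, sign * config.effect_size_logfc, 0.0)

    true_class = np.full(n, "null", dtype=object)
    delta = np.zeros(n)
    de_idx = np.flatnonzero(is_de)
    if de_idx.size:
        draws = rng.choice(len(CLASSES), size=de_idx.size, p=config.class_proportions)
        u = rng.uniform(0.0, 0.3, size=de_idx.size)
        v = rng.uniform(1.0, 1.5, size=de_idx.size)
        w = rng.uniform(0.0, 0.5, size=de_idx.size)
        w[w == 0.0] = 0.25  # open interval (0, 0.5]
        ratio = np.choose(draws, [u, v, -w])
        delta[de_idx] = ratio * beta[de_idx]
        true_class[de_idx] = np.array(CLASSES, dtype=object)[draws]

    with np.errstate(divide="ignore", invalid="ignore"):
        true_coefficient = np.where(
            is_de, 100.0 * (beta - delta) / np.where(beta == 0, np.nan, beta), np.nan
        )

    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "baseline": baseline,
            "dispersion": dispersion,
            "beta": beta,
            "delta": delta,
            "is_de": is_de,
            "true_class": true_class,
            "true_coefficient": true_coefficient,
        }
    )
    table, sheet = counts_from_truth(truth, config, rng)
    return table, sheet, truth


def counts_from_truth(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[CountTable, SampleSheet]:
    """Draw NB counts for a given truth table under the config's design.

    Useful for counterfactual draws (e.g. forcing delta = 0 to study full
    compensation) while keeping the mean model and design identical.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    roles, sample_ids = [], []
    for role in ("W", "KM", "ZERO"):
        for i in range(config.replicates[role]):
            roles.append(role)
            sample_ids.append(f"{role}_{i + 1}")
    roles = np.array(roles)
    n_samples = len(sample_ids)

    lib_sizes = rng.integers(
        config.lib_size_range[0], config.lib_size_range[1] + 1, size=n_samples
    ).astype(float)

    baseline = truth["baseline"].to_numpy(dtype=float)
    beta = truth["beta"].to_numpy(dtype=float)
    delta = truth["delta"].to_numpy(dtype=float)
    dispersion = truth["dispersion"].to_numpy(dtype=float)

    log2fc = np.zeros((len(truth), n_samples))
    log2fc[:, roles == "KM"] = beta[:, None]
    log2fc[:, roles == "ZERO"] = delta[:, None]
    q = np.exp(baseline[:, None] + math.log(2.0) * log2fc)
    proportions = q / q.sum(axis=0, keepdims=True)
    mu = lib_sizes[None, :] * proportions

    counts = _nb_draw(rng, mu, dispersion[:, None])
    table = CountTable(list(truth["gene_id"]), sample_ids, counts)
    sheet = SampleSheet(dict(zip(sample_ids, roles)))
    return table, sheet


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) deviates; Poisson where phi == 0."""
    mu = np.broadcast_to(mu, np.broadcast_shapes(mu.shape, phi.shape)).astype(float)
    phi = np.broadcast_to(phi, mu.shape).astype(float)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def truth_recovery_report(
    truth: pd.DataFrame, estimated: pd.DataFrame
) -> dict:
    """Compare estimated compensation classes against the simulation truth.

    ``estimated`` is a compensation table (columns gene_id, comp_class,
    coefficient, de_p_km_w) restricted to the detected DEGs of interest.
    Returns the class confusion matrix over detected genes plus the true
    and estimated compensated fractions among them.
    """
    if len(estimated) == 0:
        return {
            "n_detected": 0,
            "confusion": pd.DataFrame(),
            "true_fraction_compensated": float("nan"),
            "estimated_fraction_compensated": float("nan"),
            "empty": True,
        }
    unknown = set(estimated["gene_id"]) - set(truth["gene_id"])
    if unknown:
        raise ValueError(f"estimated genes absent from truth: {sorted(unknown)[:5]}")
    merged = estimated.merge(
        truth[["gene_id", "true_class", "true_coefficient"]], on="gene_id"
    )
    confusion = pd.crosstab(
        merged["true_class"], merged["comp_class"], dropna=False
    )
    defined = merged["coefficient"].notna()
    est_frac = float(
        ((merged["coefficient"] > 0) & (merged["coefficient"] <= 100) & defined).sum()
        / max(defined.sum(), 1)
    )
    true_de = merged["true_class"] != "null"
    true_frac = float(
        (merged.loc[true_de, "true_class"] == "compensated").mean()
        if true_de.any()
        else float("nan")
    )
    return {
        "n_detected": int(len(merged)),
        "confusion": confusion,
        "true_fraction_compensated": true_frac,
        "estimated_fraction_compensated": est_frac,
        "empty": False,
    }
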