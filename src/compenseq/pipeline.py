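"""End-to-end orchestration: counts -> DE -> compensation -> enrichment.

Each stage is a pure function of files on disk plus thresholds, so any
stage can be re-run individually from the intermediate TSVs with
identical results. ``run_pipeline`` wires them together from a single
config and writes a machine-readable run summary.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import pandas as pd
import yaml

from . import __version__
from .compensation import (
    coefficient_density,
    compensation_table,
    concordance,
    fraction_compensated,
    top_partition,
    zscore_rows,
)
from .de import qlf_test, select_degs
from .enrichment import deg_gsea_lite, venn
from .io_formats import (
    read_counts,
    read_gmt,
    read_sample_sheet,
    write_counts,
    write_results,
    write_sample_sheet,
)
from .normalization import group_mean_logcpm, log_cpm, tmm_factors
from .synthetic import SimulationConfig, simulate_counts

log = logging.getLogger("compenseq")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and reproducibility controls for a full run.

    Exactly one of (counts+samples paths) or ``simulation`` must be set.
    Threshold defaults follow the analysis this package implements:
    DEG selection at p < 0.05 with a 1.5-fold change, compensation
    summaries on DEGs at p < 0.01, and a coefficient cutoff of 50 for the
    top compensated / least-compensated partitions.
    """

    out_dir: str = "results"
    counts: str | None = None
    samples: str | None = None
    gmt: str | None = None
    simulation: SimulationConfig | None = None
    de_p: float = 0.05
    comp_p: float = 0.01
    min_fold: float = 1.5
    comp_cutoff: float = 50.0
    top_k: int = 50
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.counts is not None or self.samples is not None
        if has_paths and self.simulation is not None:
            raise ValueError("config must set input paths OR a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("config needs input paths or a simulation block")
        if has_paths and (self.counts is None or self.samples is None):
            raise ValueError("both counts and samples paths are required")
        for name, val, lo, hi in (
            ("de_p", self.de_p, 0.0, 1.0),
            ("comp_p", self.comp_p, 0.0, 1.0),
        ):
            if not lo < val <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")
        if self.min_fold is not None and self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    # --- input ------------------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            counts, sheet, truth = simulate_counts(sim)
            write_counts(counts, out("counts.tsv"))
            write_sample_sheet(sheet, out("samples.tsv"))
            truth_out = truth.set_index("gene_id")
            write_results(truth_out, out("truth.tsv"))
        else:
            counts = read_counts(config.counts)
            sheet = read_sample_sheet(config.samples)
            truth = None
        sheet.validate_against(counts)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("input", exc) from exc
    log.info(
        "input: %d genes x %d samples, groups %s",
        counts.n_genes,
        counts.n_samples,
        sheet.group_sizes(),
    )

    # --- normalization ------------------------------------------------------
    try:
        factors = tmm_factors(counts)
        norm = log_cpm(counts, factors)
        norm_df = norm.to_frame()
        norm_df.index.name = "gene_id"
        write_results(norm_df, out("logcpm.tsv"))
        means = group_mean_logcpm(norm, sheet)
        write_results(means, out("group_means.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalization", exc) from exc

    # --- differential expression -------------------------------------------
    try:
        de_km_w = qlf_test(counts, sheet, "W", "KM")
        de_zero_km = qlf_test(counts, sheet, "KM", "ZERO")
        write_results(de_km_w.set_index("gene_id"), out("de_km_w.tsv"))
        write_results(de_zero_km.set_index("gene_id"), out("de_zero_km.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", exc) from exc
    degs_km_w = select_degs(de_km_w, config.de_p, config.min_fold)
    degs_zero_km = select_degs(de_zero_km, config.de_p, config.min_fold)
    log.info(
        "DE (p<%g, fold>%s): KM-vs-W %d DEGs, ZERO-vs-KM %d DEGs",
        config.de_p,
        config.min_fold,
        len(degs_km_w),
        len(degs_zero_km),
    )

    # --- compensation --------------------------------------------------------
    try:
        records = compensation_table(means, de_km_w)
        write_results(records.set_index("gene_id"), out("compensation.tsv"))
        frac, n_frac, frac_defined = fraction_compensated(records, config.comp_p)
        deg_coefs = records.loc[
            (records["de_p_km_w"] < config.comp_p) & records["coefficient"].notna(),
            "coefficient",
        ]
        if len(deg_coefs) >= 2:
            grid, density = coefficient_density(deg_coefs)
            write_results(
                pd.DataFrame({"coefficient": grid, "density": density}).set_index(
                    pd.Index(range(len(grid)), name="i")
                ),
                out("density.tsv"),
            )
        top, bottom = top_partition(
            records, de_km_w, k=config.top_k, cutoff=config.comp_cutoff,
            p_threshold=config.de_p,
        )
        for name, part in (("top_compensated", top), ("top_uncompensated", bottom)):
            if len(part):
                write_results(part.set_index("gene_id"), out(f"{name}.tsv"))
                z, _ = zscore_rows(norm, list(part["gene_id"]))
                z.index.name = "gene_id"
                write_results(z, out(f"{name}_zscores.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("compensation", exc) from exc

    # --- concordance -----------------------------------------------------------
    try:
        sig_a = set(select_degs(de_km_w, config.comp_p)["gene_id"])
        sig_b = set(select_degs(de_zero_km, config.comp_p)["gene_id"])
        subset = sorted(sig_a | sig_b)
        fc_a = de_km_w.set_index("gene_id")["logFC"]
        fc_b = de_zero_km.set_index("gene_id")["logFC"]
        subset = [g for g in subset if pd.notna(fc_a.get(g)) and pd.notna(fc_b.get(g))]
        if len(subset) >= 3:
            conc = concordance(
                fc_a, fc_b, subset=subset,
                subset_descriptor=f"union of DEGs at p<{config.comp_p}",
            )
            write_results(
                pd.DataFrame(
                    [
                        {
                            "spearman_rho": conc.spearman_rho,
                            "p_value": conc.p_value,
                            "n_genes": conc.n_genes,
                            "opposite_fraction": conc.opposite_fraction,
                            "subset": conc.subset_descriptor,
                        }
                    ]
                ).set_index(pd.Index([0], name="i")),
                out("concordance.tsv"),
            )
        else:
            conc = None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("concordance", exc) from exc

    # --- enrichment ---------------------------------------------------------
    enrich_result = None
    try:
        if config.gmt is not None:
            if not os.path.exists(config.gmt):
                raise FileNotFoundError(config.gmt)
            sets = read_gmt(config.gmt)
            enrich_result = deg_gsea_lite(
                de_km_w, sets, p_threshold=config.de_p, min_fold=config.min_fold
            )
            if len(enrich_result):
                write_results(
                    enrich_result.set_index("set_name"), out("enrichment_km_w.tsv")
                )
        regions = venn(
            {
                "KM_vs_W": list(degs_km_w["gene_id"]),
                "ZERO_vs_KM": list(degs_zero_km["gene_id"]),
            }
        )
        write_results(
            pd.DataFrame(
                {"region": list(regions), "n_genes": list(regions.values())}
            ).set_index("region"),
            out("venn.tsv"),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrichment", exc) from exc

    summary = {
        "version": __version__,
        "seed": config.seed
        if config.seed is not None
        else (config.simulation.seed if config.simulation else None),
        "thresholds": {
            "de_p": config.de_p,
            "comp_p": config.comp_p,
            "min_fold": config.min_fold,
            "comp_cutoff": config.comp_cutoff,
        },
        "n_genes": counts.n_genes,
        "n_samples": counts.n_samples,
        "group_sizes": sheet.group_sizes(),
        "n_tested": int(de_km_w["tested"].sum()),
        "deg_count_km_vs_w": int(len(degs_km_w)),
        "deg_count_zero_vs_km": int(len(degs_zero_km)),
        "fraction_compensated": None if not frac_defined else round(frac, 6),
        "n_compensation_degs": n_frac,
        "spearman_rho": None if conc is None else round(conc.spearman_rho, 6),
        "opposite_fraction": None if conc is None else round(conc.opposite_fraction, 6),
        "venn": regions,
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    make_report(config.out_dir)
    return summary


def make_report(out_dir: str) -> str:
    """Render report.md from the saved stage outputs; idempotent."""
    summary_path = os.path.join(out_dir, "summary.json")
    if not os.path.exists(summary_path):
        raise FileNotFoundError(f"missing stage output: {summary_path}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    comp_path = os.path.join(out_dir, "compensation.tsv")
    top_path = os.path.join(out_dir, "top_compensated.tsv")
    lines = [
        "# Compensation analysis report",
        "",
        f"- package version: {summary['version']}, seed: {summary['seed']}",
        f"- thresholds: {summary['thresholds']}",
        f"- genes: {summary['n_genes']} ({summary['n_tested']} tested), "
        f"samples: {summary['n_samples']} {summary['group_sizes']}",
        "",
        "## Headline quantities",
        "",
        f"- DEGs KM vs W: **{summary['deg_count_km_vs_w']}**",
        f"- DEGs ZERO vs KM: **{summary['deg_count_zero_vs_km']}**",
        f"- fraction compensated (coefficient in (0,100], DEGs at "
        f"p<{summary['thresholds']['comp_p']}): **{summary['fraction_compensated']}** "
        f"of {summary['n_compensation_degs']} genes",
        f"- logFC concordance (Spearman rho): **{summary['spearman_rho']}** "
        f"(opposite-direction fraction {summary['opposite_fraction']})",
    ]
    if os.path.exists(top_path):
        top = pd.read_csv(top_path, sep="\t")
        lines += [
            "",
            "## Top compensated genes",
            "",
            ", ".join(top["gene_id"].astype(str).head(10)),
        ]
    elif not os.path.exists(comp_path):
        raise FileNotFoundError(f"missing stage output: {comp_path}")
    text = "\n".join(lines) + "\n"
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(text)
    return text
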