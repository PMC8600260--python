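"""Gene-set over-representation and Venn partitions.

Per set and per direction (up/down DEG lists) a two-sided Fisher's exact
test is computed on the 2x2 table

    [[set & list, set \\ list], [list \\ set, neither]]

over a user-chosen universe (default: all tested genes). Two-sided
p-values follow the point-probability convention: the sum of
hypergeometric table probabilities no larger than the observed one.
BH correction is applied across sets within each direction.

The "GSEA on DEGs" variant restricts the universe to the DEGs themselves
before testing, mirroring workflows that feed only significant genes into
set-level analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


def fisher_set_test(
    set_genes,
    direction_list,
    universe,
    alternative: str = "two-sided",
) -> tuple[tuple[int, int, int, int], float]:
    """Fisher's exact test of a gene set against one DEG direction list.

    Returns ((in-set&in-list, in-set-only, in-list-only, neither), p).
    The set is intersected with the universe first; the list must be a
    subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = set(direction_list)
    if not lst <= uni:
        raise ValueError("direction list contains genes outside the universe")
    s = set(set_genes) & uni
    a = len(s & lst)
    b = len(s - lst)
    c = len(lst - s)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return (a, b, c, d), float(p)


def enrich_all(
    sets: GeneSetCollection,
    up,
    down,
    universe,
    logfc: pd.Series | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Both-direction Fisher tests for every set, BH within direction.

    ``logfc`` (Series indexed by gene id), when given, is used to return
    each set's in-universe members sorted by decreasing log2 fold change
    for display. direction_call names the direction with the smaller
    significant FDR ('none' if neither reaches 0.05).
    """
    up, down = set(up), set(down)
    if up & down:
        raise ValueError("up and down DEG lists overlap")
    uni = set(universe)
    rows = []
    members_sorted = {}
    for name in sets.names():
        members = [g for g in sets.members(name) if g in uni]
        (a_up, *_), p_up = fisher_set_test(members, up, uni, alternative)
        (a_dn, *_), p_dn = fisher_set_test(members, down, uni, alternative)
        if logfc is not None:
            present = [g for g in members if g in logfc.index]
            members_sorted[name] = sorted(
                present, key=lambda g: -float(logfc.loc[g])
            )
        rows.append(
            {
                "set_name": name,
                "n_set_in_universe": len(members),
                "n_up_overlap": a_up,
                "n_down_overlap": a_dn,
                "p_up": p_up,
                "p_down": p_dn,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_up"] = multipletests(out["p_up"], method="fdr_bh")[1]
        out["fdr_down"] = multipletests(out["p_down"], method="fdr_bh")[1]
        call = np.full(len(out), "none", dtype=object)
        up_sig = (out["fdr_up"] < 0.05) & (out["fdr_up"] <= out["fdr_down"])
        dn_sig = (out["fdr_down"] < 0.05) & (out["fdr_down"] < out["fdr_up"])
        call[up_sig.to_numpy()] = "up"
        call[dn_sig.to_numpy()] = "down"
        out["direction_call"] = call
        if logfc is not None:
            out["members_by_logfc"] = [
                ",".join(members_sorted[n]) for n in out["set_name"]
            ]
    return out


def deg_gsea_lite(
    de_result: pd.DataFrame,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
    min_fold: float | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Set enrichment restricted to the DEGs themselves.

    The universe is the DEG list at ``p_threshold`` (and optional fold
    cutoff); up and down partitions are tested against it. Returns an
    empty flagged frame when there are no DEGs.
    """
    from .de import select_degs

    degs = select_degs(de_result, p_threshold=p_threshold, min_fold=min_fold)
    if len(degs) == 0:
        out = pd.DataFrame(
            columns=[
                "set_name",
                "n_set_in_universe",
                "n_up_overlap",
                "n_down_overlap",
                "p_up",
                "p_down",
            ]
        )
        out.attrs["empty_deg_list"] = True
        return out
    universe = list(degs["gene_id"])
    up = list(degs.loc[degs["direction"] == "up", "gene_id"])
    down = list(degs.loc[degs["direction"] == "down", "gene_id"])
    logfc = degs.set_index("gene_id")["logFC"]
    result = enrich_all(sets, up, down, universe, logfc=logfc, alternative=alternative)
    result.attrs["empty_deg_list"] = False
    return result


def venn(sets: dict[str, list]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 labelled gene lists.

    Region keys join labels with '&' (e.g. 'A', 'A&B', 'A&B&C'); each
    count is the number of genes in exactly that combination of sets.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("venn supports exactly 2 or 3 sets")
    as_sets = {lab: set(v) for lab, v in sets.items()}
    universe = set().union(*as_sets.values())
    regions: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set(universe)
            for lab in combo:
                inside &= as_sets[lab]
            for lab in labels:
                if lab not in combo:
                    inside -= as_sets[lab]
            regions["&".join(combo)] = len(inside)
    return regions
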