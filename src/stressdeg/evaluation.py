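"""Scoring pipeline output against the simulator's truth ledger.

The simulator plants trajectories in AR semantics; the pooled (AR + TC)
per-genotype ground-truth class of a planted gene follows from the union
of its AR code and the TC code derived from the same shifts.  A gene
planted e.g. ``dnn`` is genuinely up-regulated at the TC 15/5 recovery
step, so its pooled truth class is i_deg — recovery of pure u/d classes
is scored only on genes whose pooled truth class is u_deg or d_deg.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de_consensus import de_analysis
from .go_enrichment import sharing
from .synthetic_data import SimConfig, simulate_experiment
from .trajectory import build_records, build_sets


def pooled_truth_class(code_ar: str, code_tc: str) -> str:
    joined = code_ar + code_tc
    has_u, has_d = "u" in joined, "d" in joined
    if has_u and has_d:
        return "i_deg"
    if has_u:
        return "u_deg"
    if has_d:
        return "d_deg"
    return "non_deg"


def evaluate_seed(config: SimConfig) -> dict:
    """Simulate one experiment, run the DE + classification pipeline and
    score recovery of the planted structure (single-tissue configs).

    Returns per-seed statistics: sensitivity and false-direction rate of
    planted u/d classes, core concordant/mixed accuracy (AR-scheme sets),
    recovered and planted 4-way sharing percentages, and the consensus
    call rate (the false-call rate when nothing is planted).
    """
    if len(config.tissues) != 1:
        raise ValueError("evaluate_seed expects a single-tissue config")
    tissue = config.tissues[0]
    cm, truth = simulate_experiment(config)
    _, calls = de_analysis(cm)
    records = build_records(calls)
    out: dict = {"seed": config.seed,
                 "consensus_call_rate": float((calls["direction"] != "ns").mean())}

    tr = truth[truth["tissue"] == tissue].copy()
    tr["pooled_class"] = [
        pooled_truth_class(r.planted_code_AR, r.planted_code_TC)
        for r in tr.itertuples()
    ]
    planted_ud = tr[tr["pooled_class"].isin(["u_deg", "d_deg"])]
    if len(planted_ud) == 0:
        return out

    sets_all = build_sets(records)
    net = sets_all["net_class"]
    recovered = np.array([
        net.get((r.gene_id, r.genotype), "non_deg")
        for r in planted_ud.itertuples()
    ])
    pclass = planted_ud["pooled_class"].to_numpy()
    opposite = np.where(pclass == "u_deg", "d_deg", "u_deg")
    out["n_planted_ud"] = int(len(planted_ud))
    out["ud_sensitivity"] = float((recovered == pclass).mean())
    out["false_direction_rate"] = float((recovered == opposite).mean())

    # concordance on AR-scheme core genes (planting is AR-semantics)
    sets_ar = build_sets(records[records["scheme"] == "AR"])
    flag = tr.groupby("gene_id")["concordance"].agg(
        lambda x: "mixed" if (x == "mixed").any()
        else ("concordant" if (x == "concordant").any() else "none"))
    core = sets_ar["core"]
    if core:
        hits = [
            ("mixed" if sets_ar["core_class"][g] == "m" else "concordant")
            == flag.get(g, "none")
            for g in core
        ]
        out["n_core"] = len(core)
        out["concordance_accuracy"] = float(np.mean(hits))

    # 4-way sharing: recovered trend sets vs planted carrier sets
    res = sharing(sets_all["trend"])
    n_geno = tr.groupby("gene_id")["n_genotypes"].max()
    planted_any = int((n_geno >= 1).sum())
    if planted_any:
        out["sharing4_recovered"] = res["all4"]
        out["sharing4_planted"] = 100.0 * int((n_geno == len(config.genotypes)).sum()) / planted_any
        out["sharing4_abs_error"] = abs(out["sharing4_recovered"]
                                        - out["sharing4_planted"])
    return out


def evaluate_recovery(seeds: Sequence[int], **config_overrides) -> pd.DataFrame:
    """evaluate_seed over several seeds; one row per seed."""
    base = SimConfig(tissues=("leaf",), **config_overrides)
    rows = [evaluate_seed(replace(base, seed=int(s))) for s in seeds]
    return pd.DataFrame(rows)


def records_realizing_counts(
    class_counts: Mapping[tuple[str, str, str], tuple[int, int, int]],
    union_counts: Mapping[tuple[str, str], int],
) -> pd.DataFrame:
    """Construct a synthetic trajectory-record table realizing given
    per-stratum DEG class counts and across-scheme union sizes.

    ``class_counts`` maps (scheme, tissue, genotype) -> (n_d, n_u, n_i);
    ``union_counts`` maps (tissue, genotype) -> |AR-DEGs union TC-DEGs|.
    Gene identities are synthetic: for each tissue x genotype, exactly
    overlap = |AR| + |TC| - union genes are shared between the two
    schemes, the rest are scheme-specific.  Used to drive the summary
    bookkeeping from published per-class counts.
    """
    rep_code = {"d_deg": "nnd", "u_deg": "nnu", "i_deg": "und"}
    rows = []
    cells = sorted({(t, g) for (_, t, g) in class_counts})
    for tissue, genotype in cells:
        per_scheme = {}
        for scheme in ("AR", "TC"):
            d, u, i = class_counts.get((scheme, tissue, genotype), (0, 0, 0))
            per_scheme[scheme] = ["d_deg"] * d + ["u_deg"] * u + ["i_deg"] * i
        n_ar, n_tc = len(per_scheme["AR"]), len(per_scheme["TC"])
        union = union_counts.get((tissue, genotype), n_ar + n_tc)
        overlap = n_ar + n_tc - union
        if not 0 <= overlap <= min(n_ar, n_tc):
            raise ValueError(
                f"inconsistent union for {tissue}/{genotype}: "
                f"|AR|={n_ar}, |TC|={n_tc}, union={union}"
            )
        prefix = f"{tissue}_{genotype}"
        ar_genes = [f"{prefix}_shared{k}" for k in range(overlap)] + \
                   [f"{prefix}_ar{k}" for k in range(n_ar - overlap)]
        tc_genes = [f"{prefix}_shared{k}" for k in range(overlap)] + \
                   [f"{prefix}_tc{k}" for k in range(n_tc - overlap)]
        for scheme, genes in (("AR", ar_genes), ("TC", tc_genes)):
            for gene, cls in zip(genes, per_scheme[scheme]):
                rows.append({
                    "gene_id": gene, "genotype": genotype, "tissue": tissue,
                    "scheme": scheme, "code": rep_code[cls],
                    "genotype_class": cls,
                })
    return pd.DataFrame(rows)
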