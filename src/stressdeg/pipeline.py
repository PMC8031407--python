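"""End-to-end orchestration: simulate -> DE -> classify -> enrich -> stats.

One seeded, configurable run produces the report tables shaped like the
study's summaries: the per-genotype DEG bookkeeping table, expression-
category proportions, core-vs-trend class-proportion tables with their
chi-square statistics, direction-partitioned GO-enrichment roll-ups, and
cross-genotype sharing percentages.  Every output directory carries a
manifest recording the seed, thresholds and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de_consensus import (FDR_THRESHOLD_DEFAULT, LFC_THRESHOLD_DEFAULT,
                           de_analysis)
from .go_enrichment import (GO_FDR_DEFAULT, partitioned_enrichment,
                            sharing_table)
from .io_model import (CountMatrix, GOAnnotationMap, read_count_matrix,
                       read_go_annotation, read_group_map, write_count_matrix)
from .synthetic_data import SimConfig, simulate_experiment
from .trajectory import (build_records, build_sets,
                         expression_category_proportions, sets_to_frame,
                         summarize_counts)
from .comparative_stats import posthoc_pairwise


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (YAML-mirrorable)."""

    out_dir: str = "stressdeg_run"
    counts: str | None = None          # None -> simulate
    samples: str | None = None
    annotation: str | None = None
    annotation_format: str = "two_column_tsv"
    groups: str | None = None
    obo: str | None = None
    schemes: tuple[str, ...] = ("AR", "TC")
    callers: tuple[str, ...] = ("nb_wald", "lm_moderated")
    lfc: float = LFC_THRESHOLD_DEFAULT
    de_fdr: float = FDR_THRESHOLD_DEFAULT
    go_fdr: float = GO_FDR_DEFAULT
    posthoc_alpha: float = 0.05
    sharing_denominator: str = "mean_size"
    min_category_degs: int = 21
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("schemes", "callers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    # --- input counts -----------------------------------------------------
    truth = None
    if config.counts is not None:
        if config.samples is None:
            raise ValueError("counts supplied without a sample sheet")
        cm = read_count_matrix(config.counts, config.samples)
        stage(f"loaded counts: {cm.n_genes} genes x {cm.n_samples} samples")
    else:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        cm, truth = simulate_experiment(sim_cfg)
        write_count_matrix(cm, out / "counts.tsv", out / "samples.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        stage(f"simulated counts: {cm.n_genes} genes x {cm.n_samples} samples")

    annotation: GOAnnotationMap | None = None
    if config.annotation is not None:
        annotation = read_go_annotation(config.annotation, config.annotation_format)
        if config.obo is not None:
            from .go_enrichment import propagate_annotations
            annotation = propagate_annotations(annotation, config.obo)
        stage(f"annotation: {len(annotation.gene_to_terms)} genes")
    groups = read_group_map(config.groups) if config.groups else None

    # --- differential expression -----------------------------------------
    results, calls = de_analysis(
        cm, schemes=config.schemes, callers=config.callers,
        lfc_threshold=config.lfc, fdr_threshold=config.de_fdr)
    _write(results, out / "de_results.tsv")
    _write(calls, out / "consensus.tsv")
    n_deg_calls = int((calls["direction"] != "ns").sum())
    stage(f"consensus: {len(calls)} calls, {n_deg_calls} significant")

    # --- trajectory classification ----------------------------------------
    records = build_records(calls)
    _write(records, out / "trajectories.tsv")
    table1 = summarize_counts(records)
    _write(table1, out / "table1.tsv")
    cats = expression_category_proportions(records, config.min_category_degs)
    _write(cats["fractions"], out / "fig2_categories.tsv")
    stage(f"classification: {len(records)} records; "
          f"{len(cats['excluded'])} strata excluded from categories")

    tissues = sorted(records["tissue"].unique())
    sets_by_tissue = {}
    set_frames = []
    for tissue in tissues:
        s = build_sets(records[records["tissue"] == tissue])
        sets_by_tissue[tissue] = s
        set_frames.append(sets_to_frame(s, tissue))
    _write(pd.concat(set_frames, ignore_index=True), out / "sets.tsv")

    # --- class-proportion tables and chi-square stats (Fig 3 shape) -------
    fig3_rows, stats_rows = [], []
    for tissue in tissues:
        for scheme in config.schemes:
            sub = records[(records["tissue"] == tissue)
                          & (records["scheme"] == scheme)]
            s = build_sets(sub)
            core = s["core"]
            if not core:
                continue
            genotypes = sorted(s["trend"])
            tab = {}
            for g in genotypes:
                counts = {"u": 0, "d": 0, "i_or_m": 0}
                for gene in core:
                    cls = s["net_class"][(gene, g)]
                    counts[{"u_deg": "u", "d_deg": "d", "i_deg": "i_or_m"}[cls]] += 1
                tab[g] = counts
            tab["core"] = {
                "u": sum(1 for v in s["core_class"].values() if v == "u"),
                "d": sum(1 for v in s["core_class"].values() if v == "d"),
                "i_or_m": sum(1 for v in s["core_class"].values() if v == "m"),
            }
            table = pd.DataFrame(tab).T[["u", "d", "i_or_m"]]
            for grp_name, row in table.iterrows():
                fig3_rows.append({"tissue": tissue, "scheme": scheme,
                                  "group": grp_name, **row.to_dict()})
            nonzero = table.loc[:, table.sum(axis=0) > 0]
            if nonzero.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
                res = posthoc_pairwise(nonzero, fdr=config.posthoc_alpha,
                                       omnibus_alpha=config.posthoc_alpha)
                stats_rows.append({
                    "test": "chi_square_classes", "scope": f"{tissue}:{scheme}",
                    "statistic": res.omnibus_stat, "df": res.omnibus_df,
                    "pvalue": res.omnibus_p,
                    "letters": ";".join(f"{g}={l}" for g, l in res.letters.items()),
                })
    _write(pd.DataFrame(fig3_rows), out / "fig3_classes.tsv")
    _write(pd.DataFrame(stats_rows), out / "stats_report.tsv")
    stage(f"stats: {len(stats_rows)} omnibus tests")

    # --- GO enrichment and sharing ----------------------------------------
    enr_frames, rollup_frames, sharing_frames = [], [], []
    for tissue in tissues:
        s = sets_by_tissue[tissue]
        enriching: dict[str, set[str]] | None = None
        if annotation is not None:
            background = set(
                records.loc[records["tissue"] == tissue, "gene_id"].unique()
            ) & set(annotation.annotated_genes)
            enriching = {}
            scopes = ["core"] + [f"trend:{g}" for g in sorted(s["trend"])]
            for scope in scopes:
                enr, rollup = partitioned_enrichment(
                    s, records, annotation, background, scope,
                    fdr_threshold=config.go_fdr, groups=groups)
                if not enr.empty:
                    enr.insert(0, "tissue", tissue)
                    enr_frames.append(enr)
                if not rollup.empty:
                    rollup.insert(0, "tissue", tissue)
                    rollup_frames.append(rollup)
                if scope.startswith("trend:"):
                    g = scope.split(":", 1)[1]
                    sig = enr[enr["fdr"] <= config.go_fdr] if not enr.empty else enr
                    genes: set[str] = set()
                    if not sig.empty:
                        for cell in sig["contributing_genes"]:
                            genes.update(cell.split(","))
                    enriching[g] = genes
        sharing_frames.append(
            sharing_table(s, tissue, enriching, config.sharing_denominator))
    empty_enr = pd.DataFrame(columns=["tissue", "scope", "direction", "term_id",
                                      "namespace", "a", "b", "c", "d", "pvalue",
                                      "fdr", "contributing_genes"])
    _write(pd.concat(enr_frames, ignore_index=True) if enr_frames else empty_enr,
           out / "enrichment.tsv")
    _write(pd.concat(rollup_frames, ignore_index=True) if rollup_frames
           else pd.DataFrame(columns=["tissue", "group", "scope", "direction",
                                      "n_terms", "n_degs"]),
           out / "tables23_go.tsv")
    _write(pd.concat(sharing_frames, ignore_index=True),
           out / "fig4_sharing.tsv")
    stage("enrichment + sharing written")

    manifest = {
        "package": "stressdeg",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "log": log,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return {
        "count_matrix": cm, "truth": truth, "results": results, "calls": calls,
        "records": records, "table1": table1, "categories": cats,
        "sets_by_tissue": sets_by_tissue, "manifest": manifest,
    }
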