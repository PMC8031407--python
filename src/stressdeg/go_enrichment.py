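"""Direction-partitioned GO over-representation and cross-genotype sharing.

Over-representation of a GO term in a study set against a background
universe is scored with the one-sided Fisher exact test, i.e. the upper
hypergeometric tail P(X >= a) for the 2x2 table

              term    no term
    study       a        b
    rest        c        d

with BH FDR control per (scope x direction x namespace) family and
significance at FDR <= 0.05.  Study sets are the direction partitions of
the trend sets (d / u / i per genotype) and of the core set (d / u / m).

Sharing statistics quantify how far the same genes drive the same
response in different genotypes: for two gene sets A, B the pairwise
percentage is 100*|A n B| / mean(|A|, |B|) (denominator convention
selectable among mean_size, union and min_size), and the 4-way percentage
is 100*|intersection of all 4| / |union of all 4|.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .de_consensus import benjamini_hochberg
from .io_model import GOAnnotationMap, ValidationError

GO_FDR_DEFAULT = 0.05
SHARING_DENOMINATORS = ("mean_size", "union", "min_size")


def fisher_enrich(study: Iterable[str], background: Iterable[str],
                  annotation: GOAnnotationMap) -> pd.DataFrame:
    """One-sided Fisher over-representation of each term hit by the study set.

    Terms with zero study hits are skipped.  Columns: term_id, namespace,
    a, b, c, d, pvalue, fdr, contributing_genes.  FDR families are per
    namespace (terms lacking namespace metadata form their own family).
    """
    study = frozenset(study)
    background = frozenset(background)
    if not study:
        raise ValidationError("empty study set")
    if not study <= background:
        raise ValidationError("study set must be a subset of the background")
    term_to_bg: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.terms_for(gene):
            term_to_bg.setdefault(term, set()).add(gene)
    N = len(background)
    n = len(study)
    rows = []
    for term in sorted(term_to_bg):
        bg_genes = term_to_bg[term]
        hits = study & bg_genes
        a = len(hits)
        if a == 0:
            continue
        K = len(bg_genes)
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        rows.append({
            "term_id": term,
            "namespace": annotation.term_meta.get(term, {}).get("namespace", "NA"),
            "a": a, "b": n - a, "c": K - a, "d": N - K - (n - a),
            "pvalue": min(p, 1.0),
            "contributing_genes": ",".join(sorted(hits)),
        })
    df = pd.DataFrame(rows, columns=["term_id", "namespace", "a", "b", "c", "d",
                                     "pvalue", "contributing_genes"])
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        return df
    df["fdr"] = np.nan
    for ns, grp in df.groupby("namespace"):
        df.loc[grp.index, "fdr"] = benjamini_hochberg(grp["pvalue"].to_numpy())
    return df[["term_id", "namespace", "a", "b", "c", "d", "pvalue", "fdr",
               "contributing_genes"]]


def _direction_sets(sets: dict, records: pd.DataFrame, scope: str) -> dict[str, set[str]]:
    """Study sets per direction letter for one scope (core or trend:<genotype>)."""
    if scope == "core":
        out: dict[str, set[str]] = {"D": set(), "U": set(), "M": set()}
        for gene, cls in sets["core_class"].items():
            out[cls.upper()].add(gene)
        return out
    if scope.startswith("trend:"):
        genotype = scope.split(":", 1)[1]
        if genotype not in sets["trend"]:
            raise ValidationError(f"unknown genotype in scope {scope!r}")
        out = {"D": set(), "U": set(), "I": set()}
        lut = {"d_deg": "D", "u_deg": "U", "i_deg": "I"}
        for gene in sets["trend"][genotype]:
            cls = sets["net_class"][(gene, genotype)]
            out[lut[cls]].add(gene)
        return out
    raise ValidationError(f"unknown scope {scope!r}")


def partitioned_enrichment(sets: dict, records: pd.DataFrame,
                           annotation: GOAnnotationMap,
                           background: Iterable[str],
                           scope: str,
                           fdr_threshold: float = GO_FDR_DEFAULT,
                           groups: Mapping[str, str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run fisher_enrich per direction partition of one scope.

    For trend scopes the partitions are the genotype's d- / u- / i-sets;
    for the core scope, d- / u- / m-sets.  A term may be significant in
    several partitions.  When a term -> functional-group map is supplied a
    roll-up is also returned: per (group, direction), the number of
    significant terms and the size of the *union* of their contributing
    genes.  Returns (enrichment table, group roll-up).
    """
    background = frozenset(background) & annotation.annotated_genes
    parts = _direction_sets(sets, records, scope)
    frames = []
    for direction in sorted(parts):
        genes = parts[direction] & background
        if not genes:
            continue
        df = fisher_enrich(genes, background, annotation)
        df.insert(0, "scope", scope)
        df.insert(1, "direction", direction)
        frames.append(df)
    if frames:
        enr = pd.concat(frames, ignore_index=True)
    else:
        enr = pd.DataFrame(columns=["scope", "direction", "term_id", "namespace",
                                    "a", "b", "c", "d", "pvalue", "fdr",
                                    "contributing_genes"])
    rollup_rows = []
    if groups is not None and not enr.empty:
        sig = enr[enr["fdr"] <= fdr_threshold]
        sig = sig[sig["term_id"].isin(groups)]
        for (grp_name, direction), g in sig.groupby(
                [sig["term_id"].map(groups), "direction"], sort=True):
            contributing: set[str] = set()
            for cell in g["contributing_genes"]:
                contributing.update(cell.split(","))
            rollup_rows.append({
                "group": grp_name, "scope": scope, "direction": direction,
                "n_terms": g["term_id"].nunique(),
                "n_degs": len(contributing),
            })
    rollup = pd.DataFrame(rollup_rows, columns=["group", "scope", "direction",
                                                "n_terms", "n_degs"])
    return enr, rollup


def propagate_annotations(annotation: GOAnnotationMap,
                          obo_path: str) -> GOAnnotationMap:
    """Propagate each gene's terms to their is_a / part_of ancestors."""
    import obonet
    import networkx as nx

    graph = obonet.read_obo(obo_path)
    keep = {"is_a", "part_of"}
    anc_cache: dict[str, frozenset[str]] = {}

    def ancestors(term: str) -> frozenset[str]:
        if term in anc_cache:
            return anc_cache[term]
        found: set[str] = set()
        stack = [term]
        while stack:
            cur = stack.pop()
            if cur not in graph:
                continue
            for _, parent, key in graph.out_edges(cur, keys=True):
                if key in keep and parent not in found:
                    found.add(parent)
                    stack.append(parent)
        anc_cache[term] = frozenset(found)
        return anc_cache[term]

    ns_lut = {"biological_process": "BP", "molecular_function": "MF",
              "cellular_component": "CC"}
    new_map = {}
    meta = dict(annotation.term_meta)
    for gene, terms in annotation.gene_to_terms.items():
        full = set(terms)
        for t in terms:
            full |= ancestors(t)
        new_map[gene] = frozenset(full)
        for t in full:
            if t in graph:
                node = graph.nodes[t]
                entry = meta.setdefault(t, {})
                entry.setdefault("name", node.get("name", ""))
                if "namespace" in node:
                    entry.setdefault("namespace", ns_lut.get(node["namespace"], "NA"))
    return GOAnnotationMap(new_map, meta)


def _pairwise_pct(a: frozenset, b: frozenset, denominator: str) -> float:
    inter = len(a & b)
    if denominator == "mean_size":
        denom = (len(a) + len(b)) / 2.0
    elif denominator == "union":
        denom = float(len(a | b))
    elif denominator == "min_size":
        denom = float(min(len(a), len(b)))
    else:
        raise ValidationError(f"unknown sharing denominator {denominator!r}")
    return 100.0 * inter / denom if denom > 0 else 0.0


def sharing(sets_by_genotype: Mapping[str, Iterable[str]],
            restrict_to: Mapping[str, Iterable[str]] | None = None,
            denominator: str = "mean_size") -> dict:
    """Pairwise and 4-way shared-gene percentages across genotypes.

    Optionally first restricts each genotype's set to its GO-enriching
    genes.  Returns {"pairwise": {(g1, g2): pct}, "mean": float,
    "se": float, "all4": float} where all4 = 100 * |intersection| /
    |union| over all genotypes.
    """
    sets = {g: frozenset(v) for g, v in sets_by_genotype.items()}
    if restrict_to is not None:
        sets = {g: sets[g] & frozenset(restrict_to.get(g, ())) for g in sets}
    if all(len(s) == 0 for s in sets.values()):
        raise ValidationError("all genotype sets are empty")
    names = sorted(sets)
    pairwise = {
        (g1, g2): _pairwise_pct(sets[g1], sets[g2], denominator)
        for g1, g2 in itertools.combinations(names, 2)
    }
    vals = np.array(list(pairwise.values()))
    union_all = frozenset().union(*sets.values())
    inter_all = frozenset.intersection(*sets.values())
    return {
        "pairwise": pairwise,
        "mean": float(vals.mean()),
        "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        "all4": 100.0 * len(inter_all) / len(union_all),
    }


def sharing_table(sets: dict, tissue: str,
                  enriching: Mapping[str, Iterable[str]] | None = None,
                  denominator: str = "mean_size") -> pd.DataFrame:
    """Fig-4-shaped table: per direction (U, D), pairwise and 4-way sharing,
    for all trend DEGs and (when given) restricted to GO-enriching DEGs."""
    rows = []
    genotypes = sorted(sets["trend"])
    for direction, cls in (("U", "u_deg"), ("D", "d_deg")):
        dir_sets = {
            g: {gene for gene in sets["trend"][g]
                if sets["net_class"][(gene, g)] == cls}
            for g in genotypes
        }
        for restricted, restrict in ((False, None), (True, enriching)):
            if restricted and enriching is None:
                continue
            try:
                res = sharing(dir_sets, restrict, denominator)
            except ValidationError:
                continue
            for (g1, g2), pct in res["pairwise"].items():
                rows.append({"tissue": tissue, "direction": direction,
                             "restricted": restricted, "pair": f"{g1}-{g2}",
                             "percentage": pct})
            rows.append({"tissue": tissue, "direction": direction,
                         "restricted": restricted, "pair": "mean",
                         "percentage": res["mean"]})
            rows.append({"tissue": tissue, "direction": direction,
                         "restricted": restricted, "pair": "all4",
                         "percentage": res["all4"]})
    return pd.DataFrame(rows, columns=["tissue", "direction", "restricted",
                                       "pair", "percentage"])
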