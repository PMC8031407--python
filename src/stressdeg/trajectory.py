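"""Trajectory codes and the u-/d-/i-DEG, m-DEG, trend and core classifications.

Each gene's behaviour within one genotype, tissue and contrast scheme is a
3-letter code over {n, u, d}: position k gives the consensus direction at
the scheme's k-th comparison (AR: 35/15, 35/5, 35/1; TC: 35/15, 15/5,
5/1).  Within a genotype a gene is a u-DEG (up at >=1 comparison, never
down), d-DEG (mirror image), i-DEG (both directions at different
comparisons) or not a DEG.  Per tissue, the *trend* set of a genotype is
every gene that is a DEG under AR or TC; the *core* set is the
intersection of all four trend sets, each core gene labelled u, d, or m
(mixed — direction varies across genotypes).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_model import ValidationError, expand_scheme

_DIR_TO_LETTER = {"ns": "n", "up": "u", "down": "d"}
CLASSES = ("u_deg", "d_deg", "i_deg", "non_deg")


def encode(directions: Iterable[str]) -> str:
    """Collapse the 3 per-comparison consensus directions into a code."""
    dirs = list(directions)
    if len(dirs) != 3:
        raise ValidationError(f"need exactly 3 directions, got {len(dirs)}")
    try:
        return "".join(_DIR_TO_LETTER[d] for d in dirs)
    except KeyError as e:
        raise ValidationError(f"unknown direction {e.args[0]!r}") from None


def classify_genotype(code: str) -> str:
    """Map a 3-letter code to u_deg / d_deg / i_deg / non_deg."""
    if len(code) != 3 or any(c not in "nud" for c in code):
        raise ValidationError(f"invalid code {code!r}")
    has_u, has_d = "u" in code, "d" in code
    if has_u and has_d:
        return "i_deg"
    if has_u:
        return "u_deg"
    if has_d:
        return "d_deg"
    return "non_deg"


def build_records(calls: pd.DataFrame) -> pd.DataFrame:
    """Turn consensus calls into one trajectory record per
    gene x genotype x tissue x scheme.

    A comparison absent from the calls (e.g. the gene failed the
    expression pre-filter there) counts as not significant.  Output
    columns: gene_id, genotype, tissue, scheme, code, genotype_class.
    """
    rows = []
    for (g, t, scheme_name), grp in calls.groupby(
            ["genotype", "tissue", "scheme"], sort=True):
        comps = [f"{r}/{te}" for r, te in expand_scheme(scheme_name).comparisons]
        pivot = grp.pivot_table(index="gene_id", columns="comparison",
                                values="direction", aggfunc="first")
        for comp in comps:
            if comp not in pivot.columns:
                pivot[comp] = "ns"
        pivot = pivot[comps].fillna("ns")
        codes = pivot.apply(lambda r: encode(r.tolist()), axis=1)
        rows.append(pd.DataFrame({
            "gene_id": pivot.index,
            "genotype": g,
            "tissue": t,
            "scheme": scheme_name,
            "code": codes.to_numpy(),
        }))
    rec = pd.concat(rows, ignore_index=True)
    rec["genotype_class"] = rec["code"].map(classify_genotype)
    return rec


def _net_class(codes: Iterable[str]) -> str:
    """Per-genotype class pooling the AR and TC codes (union of evidence)."""
    joined = "".join(codes)
    has_u, has_d = "u" in joined, "d" in joined
    if has_u and has_d:
        return "i_deg"
    if has_u:
        return "u_deg"
    if has_d:
        return "d_deg"
    return "non_deg"


def build_sets(records: pd.DataFrame) -> dict:
    """Trend and core sets for one tissue.

    Returns {"trend": {genotype: set}, "core": set,
    "core_class": {gene: u|d|m}, "net_class": {(gene, genotype): class}}.
    The trend set pools AR and TC evidence (a gene qualifies if it is a
    DEG under at least one scheme); a core gene is m when at least one
    genotype is net-up and another net-down, or any genotype is i_deg.
    """
    tissues = records["tissue"].unique()
    if len(tissues) != 1:
        raise ValidationError("build_sets expects records from exactly one tissue")
    genotypes = sorted(records["genotype"].unique())
    net = records.groupby(["gene_id", "genotype"], sort=True)["code"].agg(_net_class)
    net_class = net.to_dict()
    trend: dict[str, set[str]] = {g: set() for g in genotypes}
    for (gene, g), cls in net_class.items():
        if cls != "non_deg":
            trend[g].add(gene)
    core = set.intersection(*trend.values()) if trend else set()
    core_class: dict[str, str] = {}
    for gene in core:
        classes = {net_class[(gene, g)] for g in genotypes}
        if classes == {"u_deg"}:
            core_class[gene] = "u"
        elif classes == {"d_deg"}:
            core_class[gene] = "d"
        else:
            core_class[gene] = "m"
    return {"trend": trend, "core": core, "core_class": core_class,
            "net_class": net_class}


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summarize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype d-/u-/i-DEG bookkeeping with totals, cross-genotype
    averages, and the deduplicated across-scheme union row.

    One output row per (comparison, tissue, direction) where comparison is
    AR, TC or "Across AR and TC" and direction is d-DEGs / u-DEGs /
    i-DEGs / Total / Any; columns are the genotypes plus Average
    (arithmetic mean over genotypes, rounded half away from zero).  The
    union row counts a gene once per genotype even when it is a DEG under
    both schemes.
    """
    genotypes = sorted(records["genotype"].unique())
    tissues = sorted(records["tissue"].unique())
    rows = []

    def emit(comparison: str, tissue: str, direction: str,
             counts: Mapping[str, int]) -> None:
        vals = [int(counts.get(g, 0)) for g in genotypes]
        rows.append({
            "comparison": comparison, "tissue": tissue, "direction": direction,
            **{g: v for g, v in zip(genotypes, vals)},
            "Average": _round_half_away(float(np.mean(vals))) if vals else 0,
        })

    class_to_dir = {"d_deg": "d-DEGs", "u_deg": "u-DEGs", "i_deg": "i-DEGs"}
    for tissue in tissues:
        sub_t = records[records["tissue"] == tissue]
        union_counts = {
            g: sub_t[(sub_t["genotype"] == g)
                     & (sub_t["genotype_class"] != "non_deg")]["gene_id"].nunique()
            for g in genotypes
        }
        emit("Across AR and TC", tissue, "Any", union_counts)
    for scheme in ("AR", "TC"):
        for tissue in tissues:
            sub = records[(records["scheme"] == scheme)
                          & (records["tissue"] == tissue)]
            totals = {g: 0 for g in genotypes}
            for cls, dir_name in class_to_dir.items():
                counts = {
                    g: int(((sub["genotype"] == g)
                            & (sub["genotype_class"] == cls)).sum())
                    for g in genotypes
                }
                for g in genotypes:
                    totals[g] += counts[g]
                emit(scheme, tissue, dir_name, counts)
            emit(scheme, tissue, "Total", totals)
    return pd.DataFrame(rows)


def _mirror(code: str) -> str:
    return code.translate(str.maketrans("ud", "du"))


def category_pair(code: str) -> str:
    """Canonical mirrored-pair label for a code, e.g. nnd and nnu -> 'nnd/nnu'."""
    a, b = sorted({code, _mirror(code)})
    return f"{a}/{b}" if a != b else a


def expression_category_proportions(records: pd.DataFrame,
                                    min_degs: int = 21) -> dict:
    """Fractions of DEGs per mirrored expression-category pair.

    Per genotype x tissue x scheme the DEGs (code != nnn) are binned by
    mirrored code pair; fractions sum to 1 within each stratum.  Strata
    with fewer than ``min_degs`` DEGs are flagged and excluded from the
    cross-genotype mean +/- standard error (sd / sqrt(n genotypes)).
    Returns {"fractions": DataFrame, "summary": DataFrame,
    "excluded": list of (genotype, tissue, scheme, n_degs)}.
    """
    degs = records[records["code"] != "nnn"].copy()
    degs["category"] = degs["code"].map(category_pair)
    frac_rows = []
    excluded = []
    for (g, t, s), grp in degs.groupby(["genotype", "tissue", "scheme"], sort=True):
        n = len(grp)
        if n < min_degs:
            excluded.append((g, t, s, n))
            continue
        fr = grp["category"].value_counts(normalize=True)
        for cat, f in fr.items():
            frac_rows.append({"genotype": g, "tissue": t, "scheme": s,
                              "category": cat, "fraction": float(f), "n_degs": n})
    fractions = pd.DataFrame(
        frac_rows,
        columns=["genotype", "tissue", "scheme", "category", "fraction", "n_degs"],
    )
    sum_rows = []
    if not fractions.empty:
        for (t, s, cat), grp in fractions.groupby(["tissue", "scheme", "category"],
                                                  sort=True):
            n_geno = fractions[(fractions["tissue"] == t)
                               & (fractions["scheme"] == s)]["genotype"].nunique()
            vals = np.zeros(n_geno)
            vals[: len(grp)] = grp["fraction"].to_numpy()  # absent genotype -> 0
            sum_rows.append({
                "tissue": t, "scheme": s, "category": cat,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n_geno)) if n_geno > 1 else 0.0,
            })
    summary = pd.DataFrame(sum_rows,
                           columns=["tissue", "scheme", "category", "mean", "se"])
    return {"fractions": fractions, "summary": summary, "excluded": excluded}


def sets_to_frame(sets: dict, tissue: str) -> pd.DataFrame:
    """Serialize build_sets output to the tidy sets table."""
    rows = []
    for g, genes in sorted(sets["trend"].items()):
        for gene in sorted(genes):
            rows.append({"gene_id": gene, "tissue": tissue,
                         "membership": f"trend:{g}", "core_class": ""})
    for gene in sorted(sets["core"]):
        rows.append({"gene_id": gene, "tissue": tissue, "membership": "core",
                     "core_class": sets["core_class"][gene]})
    return pd.DataFrame(rows,
                        columns=["gene_id", "tissue", "membership", "core_class"])
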