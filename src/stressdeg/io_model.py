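"""Data model and readers/writers shared by every pipeline stage.

The pipeline starts from a gene x sample raw-count matrix plus a sample
sheet describing the drying time-course design: four genotypes, two
tissues (leaf, root), four growing-medium water-content (EWC) sampling
points (35, 15, 5, 1 %), four replicates.  Two contrast schemes are
defined over the EWC points: *against reference* (AR) compares the 35 %
baseline with every later point, *time course* (TC) compares consecutive
points; the 35/15 comparison is shared by both schemes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

EWC_POINTS = (35, 15, 5, 1)
TISSUES = ("leaf", "root")
SCHEMES = ("AR", "TC")

_GO_ID_RE = re.compile(r"^GO:\d{7}$")
_GAF_ASPECT_TO_NS = {"P": "BP", "F": "MF", "C": "CC"}


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class MissingSampleError(ValidationError):
    """A count-matrix column has no row in the sample sheet (or vice versa)."""


class NegativeCountError(ValidationError):
    """A count cell is negative."""


class NonIntegerCountError(ValidationError):
    """A count cell is not an integer."""


class DuplicateGeneError(ValidationError):
    """A gene id appears more than once in the count matrix."""


class MalformedTermError(ValidationError):
    """A GO term id does not match GO:\\d{7}."""


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one RNA-seq library."""

    sample_id: str
    genotype: str
    tissue: str
    ewc: int
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.ewc not in EWC_POINTS:
            raise ValidationError(f"EWC {self.ewc!r} not one of {EWC_POINTS}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts plus sample metadata.

    Column order of ``counts`` matches ``samples``; gene ids are unique.
    """

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: pd.DataFrame  # genes x samples, int dtype

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DuplicateGeneError(f"duplicate gene ids: {dupes[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        keys = [(s.genotype, s.tissue, s.ewc, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (genotype, tissue, ewc, replicate) tuples")
        if list(self.counts.columns) != ids:
            raise MissingSampleError(
                "count-matrix columns do not match sample sheet order"
            )
        if list(self.counts.index) != list(self.gene_ids):
            raise ValidationError("count-matrix index does not match gene_ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)][0]
            raise NegativeCountError(f"negative count for gene {bad!r}")
        if not pd.api.types.is_integer_dtype(self.counts.dtypes.iloc[0]):
            raise NonIntegerCountError("counts must have integer dtype")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_table(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame (one row per library)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "ewc": [s.ewc for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def subset(self, genotype: str, tissue: str, ewcs: Iterable[int]) -> "CountMatrix":
        """Restrict to one genotype x tissue cell at the given EWC points."""
        ewcs = set(ewcs)
        keep = [
            s for s in self.samples
            if s.genotype == genotype and s.tissue == tissue and s.ewc in ewcs
        ]
        cols = [s.sample_id for s in keep]
        return CountMatrix(list(self.gene_ids), keep, self.counts[cols])


@dataclass(frozen=True)
class ContrastScheme:
    """Ordered list of (reference_ewc, test_ewc) comparisons for AR or TC."""

    name: str
    comparisons: tuple[tuple[int, int], ...]


_SCHEME_TABLE: dict[str, tuple[tuple[int, int], ...]] = {
    "AR": ((35, 15), (35, 5), (35, 1)),
    "TC": ((35, 15), (15, 5), (5, 1)),
}


def expand_scheme(name: str) -> ContrastScheme:
    """Expand a scheme name into its fixed, ordered comparison list.

    AR compares the 35 % EWC baseline against each later sampling point
    (35/15, 35/5, 35/1); TC compares consecutive points (35/15, 15/5,
    5/1).  The first comparison is identical for both.
    """
    try:
        return ContrastScheme(name, _SCHEME_TABLE[name])
    except KeyError:
        raise ValidationError(f"unknown contrast scheme {name!r}") from None


@dataclass
class GOAnnotationMap:
    """gene -> set of GO term ids, with per-term metadata."""

    gene_to_terms: dict[str, frozenset[str]]
    term_meta: dict[str, dict] = field(default_factory=dict)  # term_id -> {name, namespace}

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            if not terms:
                raise ValidationError(f"gene {gene!r} annotated with zero terms")
            for t in terms:
                if not _GO_ID_RE.match(t):
                    raise MalformedTermError(f"malformed GO id {t!r}")

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def genes_for_term(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_to_terms.items() if term in ts)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    required = {"sample_id", "genotype", "tissue", "ewc", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            genotype=row.genotype,
            tissue=row.tissue,
            ewc=int(row.ewc),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_count_matrix(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene_id) and reconcile with its sheet.

    Raises a named validation failure for a sample missing from the sheet,
    a non-integer or negative count, or a duplicated gene id.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in raw.columns:
        raise ValidationError("counts file must have a 'gene_id' first column")
    raw = raw.set_index("gene_id")
    samples = read_sample_sheet(sample_sheet)
    by_id = {s.sample_id: s for s in samples}
    for col in raw.columns:
        if col not in by_id:
            raise MissingSampleError(f"sample {col!r} absent from sample sheet")
    for sid in by_id:
        if sid not in raw.columns:
            raise MissingSampleError(f"sample {sid!r} absent from count matrix")
    ordered = [by_id[c] for c in raw.columns]
    for col in raw.columns:
        series = raw[col]
        if not pd.api.types.is_numeric_dtype(series):
            raise NonIntegerCountError(f"non-numeric count in column {col!r}")
        if (series < 0).any():
            raise NegativeCountError(f"negative count in column {col!r}")
        if not (series == series.round()).all():
            raise NonIntegerCountError(f"non-integer count in column {col!r}")
    counts = raw.astype("int64")
    return CountMatrix(list(counts.index), ordered, counts)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path,
                       sheet_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    cm.sample_table().to_csv(sheet_path, sep="\t", index=False)


def read_go_annotation(path: str | Path, format: str = "two_column_tsv") -> GOAnnotationMap:
    """Read a gene->GO map from a two-column TSV or GAF 2.x lines.

    Duplicate (gene, term) pairs are collapsed; GAF column 2 is the gene,
    column 5 the term, and aspect column 9 maps P/F/C -> BP/MF/CC.
    """
    path = Path(path)
    gene_to_terms: dict[str, set[str]] = {}
    term_meta: dict[str, dict] = {}
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("!")
    ]
    if not lines:
        raise ValidationError(f"empty annotation file {path}")
    if format == "two_column_tsv":
        start = 0
        first = lines[0].split("\t")
        if len(first) >= 2 and first[1].lower() in {"go_id", "term", "term_id"}:
            start = 1  # tolerate a header row
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"annotation line has <2 columns: {ln!r}")
            gene, term = parts[0].strip(), parts[1].strip()
            if not _GO_ID_RE.match(term):
                raise MalformedTermError(f"malformed GO id {term!r}")
            gene_to_terms.setdefault(gene, set()).add(term)
    elif format == "gaf":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 9:
                raise ValidationError(f"GAF line has <9 columns: {ln!r}")
            gene, term, aspect = parts[1], parts[4], parts[8]
            if not _GO_ID_RE.match(term):
                raise MalformedTermError(f"malformed GO id {term!r}")
            gene_to_terms.setdefault(gene, set()).add(term)
            ns = _GAF_ASPECT_TO_NS.get(aspect)
            if ns is not None:
                term_meta.setdefault(term, {})["namespace"] = ns
    else:
        raise ValidationError(f"unknown annotation format {format!r}")
    return GOAnnotationMap(
        {g: frozenset(ts) for g, ts in gene_to_terms.items()}, term_meta
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    """Optional GO term -> functional-group map (columns go_id, group_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"go_id", "group_name"} <= set(df.columns):
        raise ValidationError("group map needs columns go_id, group_name")
    return dict(zip(df["go_id"], df["group_name"]))
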