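"""sgRNA-bEXOmiR library representation and on-disk formats.

A library is a flat list of elements, each pairing one sgRNA with one
barcode. Targeting elements carry a gene; controls are either non-targeting
(guides matching nothing in the genome) or safe-targeting (guides cutting a
phenotypically neutral locus). Controls define the null enrichment
distribution during scoring.

On disk a library is a tab-delimited table with header
``element_id  sublibrary  gene  category  sgrna_seq  barcode_seq``
(empty gene field for controls). FASTA references of barcodes and sgRNAs
can be exported for external aligners.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._encoding import BASES
from .errors import FeasibilityError, ParseError
from .sequence_design import DesignConstraints, design_barcodes

CATEGORIES = ("targeting", "nontargeting", "safe_targeting")
TSV_COLUMNS = ["element_id", "sublibrary", "gene", "category", "sgrna_seq", "barcode_seq"]


@dataclass(frozen=True)
class LibraryElement:
    """One sgRNA-bEXOmiR pairing."""

    element_id: str
    gene: str | None
    category: str
    sgrna_seq: str
    barcode_seq: str
    sublibrary: str = "sub1"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "targeting") != (self.gene is not None):
            raise ValueError(
                f"element {self.element_id}: targeting elements (and only those) carry a gene"
            )


class Library:
    """An ordered collection of library elements with uniqueness guarantees."""

    def __init__(self, elements: Sequence[LibraryElement], guides_per_gene: int = 10,
                 validate: bool = True):
        self.elements = list(elements)
        self.guides_per_gene = guides_per_gene
        if validate:
            self._validate()

    def _validate(self) -> None:
        seen_ids, seen_bc, seen_sg = set(), set(), set()
        for el in self.elements:
            if el.element_id in seen_ids:
                raise ValueError(f"duplicate element_id {el.element_id}")
            if el.barcode_seq in seen_bc:
                raise ValueError(f"duplicate barcode {el.barcode_seq}")
            if el.sgrna_seq in seen_sg:
                raise ValueError(f"duplicate sgRNA {el.sgrna_seq}")
            seen_ids.add(el.element_id)
            seen_bc.add(el.barcode_seq)
            seen_sg.add(el.sgrna_seq)

    # -- views -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def element_ids(self) -> list[str]:
        return [el.element_id for el in self.elements]

    @property
    def barcodes(self) -> list[str]:
        return [el.barcode_seq for el in self.elements]

    @property
    def genes(self) -> list[str]:
        out, seen = [], set()
        for el in self.elements:
            if el.gene is not None and el.gene not in seen:
                seen.add(el.gene)
                out.append(el.gene)
        return out

    def targeting(self) -> list[LibraryElement]:
        return [el for el in self.elements if el.category == "targeting"]

    def controls(self) -> list[LibraryElement]:
        return [el for el in self.elements if el.category != "targeting"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "element_id": el.element_id, "sublibrary": el.sublibrary,
                    "gene": el.gene, "category": el.category,
                    "sgrna_seq": el.sgrna_seq, "barcode_seq": el.barcode_seq,
                }
                for el in self.elements
            ],
            columns=TSV_COLUMNS,
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, guides_per_gene: int = 10) -> "Library":
        elements = [
            LibraryElement(
                element_id=str(r.element_id), sublibrary=str(r.sublibrary),
                gene=None if (pd.isna(r.gene) or r.gene == "") else str(r.gene),
                category=str(r.category), sgrna_seq=str(r.sgrna_seq),
                barcode_seq=str(r.barcode_seq),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(elements, guides_per_gene=guides_per_gene)

    def subset(self, element_ids: Iterable[str]) -> "Library":
        keep = set(element_ids)
        return Library([el for el in self.elements if el.element_id in keep],
                       guides_per_gene=self.guides_per_gene, validate=False)


def _random_sgrnas(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    """Distinct random protospacers standing in for a published guide set."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        idx = rng.integers(0, 4, size=(n - len(out) + 16, length))
        for row in idx:
            s = "".join(BASES[i] for i in row)
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def build_library(genes: Sequence[str], n_controls: int,
                  constraints: DesignConstraints | None = None,
                  guides_per_gene: int = 10, sublibrary: str = "sub1") -> Library:
    """Build a library with ``guides_per_gene`` elements per gene plus controls.

    Controls are split half non-targeting, half safe-targeting (the extra one
    goes to non-targeting when ``n_controls`` is odd). Barcodes come from
    :func:`evscreen.sequence_design.design_barcodes`; an exhausted candidate
    budget raises :class:`FeasibilityError`.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names")
    c = constraints or DesignConstraints()
    n_total = len(genes) * guides_per_gene + n_controls
    bcs = design_barcodes(n_total, c)
    if len(bcs) < n_total:
        raise FeasibilityError(
            f"designed only {len(bcs)}/{n_total} barcodes within budget "
            f"{c.candidate_budget}; raise the budget or relax constraints"
        )
    rng = np.random.default_rng(np.random.SeedSequence([c.rng_seed, 0x5345515d]))
    sgrnas = _random_sgrnas(n_total, rng)

    elements: list[LibraryElement] = []
    i = 0
    for gene in genes:
        for g in range(1, guides_per_gene + 1):
            elements.append(LibraryElement(
                element_id=f"{gene}_g{g}", gene=gene, category="targeting",
                sgrna_seq=sgrnas[i], barcode_seq=bcs[i], sublibrary=sublibrary))
            i += 1
    n_nt = (n_controls + 1) // 2
    for j in range(n_controls):
        cat = "nontargeting" if j < n_nt else "safe_targeting"
        prefix = "nt" if j < n_nt else "st"
        num = j + 1 if j < n_nt else j - n_nt + 1
        elements.append(LibraryElement(
            element_id=f"{prefix}_{num:05d}", gene=None, category=cat,
            sgrna_seq=sgrnas[i], barcode_seq=bcs[i], sublibrary=sublibrary))
        i += 1
    return Library(elements, guides_per_gene=guides_per_gene)


def refine_sublibrary(lib: Library, wt_counts, low: int = 10, high: int = 10_000,
                      sample: str | None = None) -> Library:
    """Drop elements undetected or over-represented in WT EV sequencing.

    Elements with WT EV count strictly below ``low`` (undetected) or strictly
    above ``high`` (dominating sequencing depth) are removed. ``wt_counts``
    may be a mapping/Series keyed by element_id or a CountMatrix (then
    ``sample`` selects the WT EV column, defaulting to the single column).
    """
    counts = _as_count_series(wt_counts, sample)
    missing = [eid for eid in lib.element_ids if eid not in counts.index]
    if missing:
        raise ValueError(f"wt_counts does not cover {len(missing)} library elements "
                         f"(first: {missing[0]})")
    keep = [el.element_id for el in lib.elements
            if low <= counts[el.element_id] <= high]
    return lib.subset(keep)


def _as_count_series(wt_counts, sample: str | None) -> pd.Series:
    if hasattr(wt_counts, "counts"):  # CountMatrix
        df = wt_counts.counts
        if sample is None:
            if df.shape[1] != 1:
                raise ValueError("multiple samples present; pass sample=")
            return df.iloc[:, 0]
        return df[sample]
    if isinstance(wt_counts, pd.Series):
        return wt_counts
    return pd.Series(dict(wt_counts))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_library(lib: Library, path) -> None:
    df = lib.to_frame()
    df["gene"] = df["gene"].fillna("")
    df.to_csv(path, sep="\t", index=False)


def read_library(path, guides_per_gene: int = 10) -> Library:
    """Read a library TSV, reporting the offending line on malformed rows."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ParseError(f"expected header {TSV_COLUMNS}, got {header}", line=1)
        elements: list[LibraryElement] = []
        seen_bc: dict[str, int] = {}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise ParseError(f"expected {len(TSV_COLUMNS)} fields, got {len(fields)}",
                                 line=lineno)
            eid, sub, gene, cat, sg, bc = fields
            if bc in seen_bc:
                raise ParseError(f"duplicate barcode {bc} (first seen line {seen_bc[bc]})",
                                 line=lineno)
            seen_bc[bc] = lineno
            try:
                elements.append(LibraryElement(
                    element_id=eid, sublibrary=sub, gene=gene or None,
                    category=cat, sgrna_seq=sg, barcode_seq=bc))
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    try:
        return Library(elements, guides_per_gene=guides_per_gene)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_fasta_references(lib: Library, barcode_fasta=None, sgrna_fasta=None) -> None:
    """FASTA references for aligners: one file of barcodes, one of sgRNAs."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if barcode_fasta is not None:
        SeqIO.write(
            [SeqRecord(Seq(el.barcode_seq), id=el.element_id, description="")
             for el in lib.elements], str(barcode_fasta), "fasta")
    if sgrna_fasta is not None:
        SeqIO.write(
            [SeqRecord(Seq(el.sgrna_seq), id=el.element_id, description="")
             for el in lib.elements], str(sgrna_fasta), "fasta")
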