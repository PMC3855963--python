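"""Amino acid substitutions: parsing, application and region annotation.

A variant is a single-residue substitution written ``L149Q`` or
``p.L149Q`` (1-based position, one-letter codes).  Variants carry an
optional class label — ``SNP`` for neutral germline/population
polymorphisms, ``MUT`` for somatic disease-associated mutations — and an
optional region flag saying whether the position falls inside a conserved
functional domain (``CFD``) or outside all of them (``nCFD``).

Domain intervals are 1-based and inclusive on both ends.  Intervals for
the four epigenetic regulators studied with this method (ASXL1, EZH2,
DNMT3A, TET2) ship as a packaged fixture, loadable with
:func:`load_packaged_domains`.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .encoding import CANONICAL_RESIDUES
from .errors import (
    AnnotationError,
    IngestionError,
    VariantApplicationError,
    VariantParseError,
)

logger = logging.getLogger(__name__)

SNP = "SNP"
MUT = "MUT"
CFD = "CFD"
NCFD = "nCFD"

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class Variant:
    """One amino acid substitution.

    ``position`` is 1-based; ``wt_residue`` and ``alt_residue`` are
    canonical one-letter codes and must differ.
    """

    position: int
    wt_residue: str
    alt_residue: str
    gene_id: str | None = None
    label: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        for res in (self.wt_residue, self.alt_residue):
            if res not in CANONICAL_RESIDUES:
                raise VariantParseError(f"non-canonical residue {res!r}")
        if self.wt_residue == self.alt_residue:
            raise VariantParseError(
                f"substitution {self.short()} does not change the residue"
            )
        if self.label is not None and self.label not in (SNP, MUT):
            raise VariantParseError(f"unknown label {self.label!r}")
        if self.region is not None and self.region not in (CFD, NCFD):
            raise VariantParseError(f"unknown region {self.region!r}")

    def short(self) -> str:
        """The ``X123Y`` form."""
        return f"{self.wt_residue}{self.position}{self.alt_residue}"

    def reverse(self) -> "Variant":
        """The substitution that undoes this one."""
        return replace(self, wt_residue=self.alt_residue, alt_residue=self.wt_residue)


@dataclass(frozen=True)
class DomainAnnotation:
    """Conserved-domain intervals of one gene, 1-based inclusive."""

    gene_id: str
    intervals: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        spans = []
        for name, start, end in self.intervals:
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{self.gene_id}/{name}: invalid interval {start}-{end}"
                )
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.gene_id}: domains {n1} and {n2} overlap"
                )


def parse_variant(text: str, gene_id: str | None = None, label: str | None = None) -> Variant:
    """Parse ``X123Y`` / ``p.X123Y`` into a :class:`Variant`.

    The optional ``p.`` prefix is stripped; residue letters are upper-cased.
    """
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise VariantParseError(f"cannot parse substitution {text!r}")
    wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Variant(position=pos, wt_residue=wt, alt_residue=alt,
                   gene_id=gene_id, label=label)


def apply_variant(sequence: str, variant: Variant) -> str:
    """Return the sequence with the substitution applied.

    Raises :class:`VariantApplicationError` if the position is out of range
    or the sequence does not carry the expected wild-type residue there.
    """
    if variant.position > len(sequence):
        raise VariantApplicationError(
            f"{variant.short()}: position {variant.position} beyond sequence "
            f"length {len(sequence)}"
        )
    idx = variant.position - 1
    found = sequence[idx].upper()
    if found != variant.wt_residue:
        raise VariantApplicationError(
            f"{variant.short()}: expected {variant.wt_residue} at position "
            f"{variant.position}, found {found}"
        )
    return sequence[:idx] + variant.alt_residue + sequence[idx + 1 :]


def classify_region(variant: Variant, annotation: DomainAnnotation) -> str:
    """``CFD`` if the position falls in any interval (inclusive), else ``nCFD``."""
    if variant.gene_id is not None and variant.gene_id != annotation.gene_id:
        raise AnnotationError(
            f"variant gene {variant.gene_id!r} does not match annotation "
            f"{annotation.gene_id!r}"
        )
    for _name, start, end in annotation.intervals:
        if start <= variant.position <= end:
            return CFD
    return NCFD


def annotate_regions(
    variants: Iterable[Variant],
    annotations: Mapping[str, DomainAnnotation],
) -> list[Variant]:
    """Attach region flags; genes absent from the annotation map are nCFD
    throughout (no declared domains)."""
    out = []
    for v in variants:
        ann = annotations.get(v.gene_id) if v.gene_id else None
        if ann is None:
            ann = DomainAnnotation(gene_id=v.gene_id or "", intervals=())
        out.append(replace(v, region=classify_region(v, ann)))
    return out


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise IngestionError(f"cannot read table {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_variant_table(path: str | Path) -> list[Variant]:
    """Read a variant table (TSV/CSV with ``gene``, ``substitution``, ``label``).

    The ``label`` column is optional.  Duplicate (gene, substitution) rows
    with a consistent label collapse to one variant with a warning;
    a substitution listed with both labels is conflicting and excluded,
    also with a warning.
    """
    df = _read_delimited(path)
    required = {"gene", "substitution"}
    if not required.issubset(df.columns):
        raise IngestionError(
            f"variant table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    has_label = "label" in df.columns
    seen: dict[tuple[str, str], set[str | None]] = {}
    order: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        gene = str(row["gene"]).strip()
        sub = str(row["substitution"]).strip()
        label = None
        if has_label and not pd.isna(row["label"]):
            label = str(row["label"]).strip().upper()
            if label not in (SNP, MUT):
                raise IngestionError(
                    f"unknown label {label!r} for {gene} {sub}"
                )
        key = (gene, sub)
        if key not in seen:
            seen[key] = set()
            order.append(key)
        else:
            logger.warning("duplicate variant row %s %s", gene, sub)
        seen[key].add(label)
    variants: list[Variant] = []
    for key in order:
        gene, sub = key
        labels = {l for l in seen[key] if l is not None}
        if len(labels) > 1:
            logger.warning(
                "conflicting labels for %s %s (%s); variant excluded",
                gene, sub, ",".join(sorted(labels)),
            )
            continue
        label = labels.pop() if labels else None
        variants.append(parse_variant(sub, gene_id=gene, label=label))
    return variants


def read_domain_table(path: str | Path) -> dict[str, DomainAnnotation]:
    """Read domain intervals (TSV/CSV with ``gene``, ``domain``, ``start``, ``end``)."""
    df = _read_delimited(path)
    required = {"gene", "domain", "start", "end"}
    if not required.issubset(df.columns):
        raise IngestionError(
            f"domain table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    per_gene: dict[str, list[tuple[str, int, int]]] = {}
    for _, row in df.iterrows():
        per_gene.setdefault(str(row["gene"]).strip(), []).append(
            (str(row["domain"]).strip(), int(row["start"]), int(row["end"]))
        )
    return {
        gene: DomainAnnotation(gene_id=gene, intervals=tuple(ivals))
        for gene, ivals in per_gene.items()
    }


def load_packaged_domains() -> dict[str, DomainAnnotation]:
    """Conserved-domain intervals for ASXL1, EZH2, DNMT3A and TET2."""
    path = importlib.resources.files("ismvar.data") / "cfd_domains.tsv"
    return read_domain_table(Path(path))


def summarize_dataset(
    variants: Sequence[Variant],
    annotations: Mapping[str, DomainAnnotation] | None = None,
) -> pd.DataFrame:
    """Counts by gene x label x region, partitioning the input exactly.

    Variants without a region flag are annotated first (using ``annotations``
    when given).  Returns a tidy frame with one row per gene and columns
    ``SNP_nCFD``, ``SNP_CFD``, ``MUT_nCFD``, ``MUT_CFD`` plus a ``Total`` row.
    """
    if annotations is not None:
        variants = annotate_regions(variants, annotations)
    cols = [f"{lab}_{reg}" for lab in (SNP, MUT) for reg in (NCFD, CFD)]
    counts: dict[str, dict[str, int]] = {}
    for v in variants:
        gene = v.gene_id or "?"
        label = v.label or "unlabeled"
        region = v.region or "unannotated"
        row = counts.setdefault(gene, {c: 0 for c in cols})
        key = f"{label}_{region}"
        row[key] = row.get(key, 0) + 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df.index.name = "gene"
    if len(df):
        df.loc["Total"] = df.sum()
    return df
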