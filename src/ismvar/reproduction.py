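"""Gene-level study driver: dataset summary, per-gene fits, evaluation.

Ties the modules together the way the method is meant to be used on real
proteins: read wild-type sequences from FASTA, read a labelled variant
table, annotate each variant's region against conserved-domain intervals,
fit one classifier per gene on all of its labelled variants, and evaluate
the cutoff classification (optionally restricted to the variants outside
conserved domains, where phylogeny-based predictors are weakest and this
method is aimed).

Real inputs are not bundled: wild-type sequences come from UniProt (for
the four epigenetic regulators: ASXL1 Q8IXJ9, EZH2 Q15910, DNMT3A Q9Y6K1,
TET2 Q6N021) and the labelled substitutions from the study's supplementary
material.  Point :func:`run_study` at those files to reproduce the
published gene-level analysis; any FASTA + variant table in the same
layout works.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import GeneFit, fit_gene
from .errors import InvalidInputError
from .stats import EvaluationReport, evaluate_predictions
from .variants import (
    CFD,
    MUT,
    NCFD,
    SNP,
    DomainAnnotation,
    Variant,
    annotate_regions,
    load_packaged_domains,
    read_variant_table,
    summarize_dataset,
)
from .encoding import read_fasta


@dataclass(frozen=True)
class StudyResult:
    """Everything produced by one end-to-end run."""

    summary: pd.DataFrame
    fits: dict[str, GeneFit]
    evaluation: EvaluationReport | None
    evaluated_subset: str


def _subset_mask(variants: Sequence[Variant], subset: str) -> list[bool]:
    if subset == "all":
        return [True] * len(variants)
    if subset in (CFD, NCFD):
        return [v.region == subset for v in variants]
    raise InvalidInputError(f"subset must be all, {CFD} or {NCFD}; got {subset!r}")


def evaluate_fits(
    fits: Mapping[str, GeneFit], subset: str = NCFD
) -> EvaluationReport | None:
    """Pooled evaluation of per-gene cutoff calls on a region subset.

    Oriented scores from all genes share a scale (higher = mutation), so
    they are pooled for a single ROC; Fisher's exact test is run on the
    pooled predicted-vs-true crosstab.  Returns ``None`` if the subset
    ends up single-class or empty.
    """
    truths: list[str] = []
    preds: list[str] = []
    scores: list[float] = []
    for fit in fits.values():
        if fit.model is None:
            continue
        mask = _subset_mask(fit.variants, subset)
        predicted = fit.predicted_labels()
        oriented = fit.oriented_scores()
        for keep, v, p, s in zip(mask, fit.variants, predicted, oriented):
            if keep:
                truths.append(v.label or "")
                preds.append(p)
                scores.append(float(s))
    if not truths or len(set(truths)) < 2:
        return None
    return evaluate_predictions(truths, preds, scores)


def run_study(
    sequences: Mapping[str, str] | str | Path,
    variants: Sequence[Variant] | str | Path,
    annotations: Mapping[str, DomainAnnotation] | None = None,
    alpha: float = 0.05,
    subset: str = NCFD,
) -> StudyResult:
    """Summarise the dataset, fit each gene, and evaluate the calls.

    Parameters
    ----------
    sequences
        ``{gene_id: sequence}`` or a FASTA path.  Gene identifiers must
        match the ``gene`` column of the variant table.
    variants
        Parsed variants or a TSV/CSV path (``gene``, ``substitution``,
        ``label`` columns).
    annotations
        Conserved-domain intervals per gene; defaults to the packaged
        intervals for ASXL1/EZH2/DNMT3A/TET2.
    subset
        Region subset for the evaluation: ``all``, ``CFD`` or ``nCFD``
        (default — the regime the method targets).  Frequency selection
        always uses all labelled variants of a gene.
    """
    if isinstance(sequences, (str, Path)):
        sequences = read_fasta(sequences)
    if isinstance(variants, (str, Path)):
        variants = read_variant_table(variants)
    if annotations is None:
        annotations = load_packaged_domains()

    annotated = annotate_regions(variants, annotations)
    summary = summarize_dataset(annotated)

    fits: dict[str, GeneFit] = {}
    for gene in sorted({v.gene_id for v in annotated if v.gene_id}):
        if gene not in sequences:
            raise InvalidInputError(f"no wild-type sequence supplied for {gene}")
        gene_variants = [
            v for v in annotated if v.gene_id == gene and v.label in (SNP, MUT)
        ]
        labels = {v.label for v in gene_variants}
        if not {SNP, MUT} <= labels:
            continue  # cannot fit a single-class gene
        fits[gene] = fit_gene(sequences[gene], gene_variants,
                              alpha=alpha, gene_id=gene)

    evaluation = evaluate_fits(fits, subset=subset)
    return StudyResult(
        summary=summary,
        fits=fits,
        evaluation=evaluation,
        evaluated_subset=subset,
    )


def selection_table(result: StudyResult) -> pd.DataFrame:
    """Per-gene classifier frequencies as a tidy frame."""
    rows = []
    for gene, fit in result.fits.items():
        model = fit.model
        rows.append({
            "gene": gene,
            "n_variants": len(fit.variants),
            "frequency": np.nan if model is None else model.frequency,
            "frequency_index": np.nan if model is None else model.frequency_index,
            "p_value": np.nan if model is None else model.p_value,
            "orientation": np.nan if model is None else model.orientation,
            "frequencies_tested": len(fit.selection.trace),
        })
    return pd.DataFrame(rows)
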