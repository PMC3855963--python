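"""ISM classification of amino acid substitutions.

The method fits one model per protein.  Given the wild-type informational
spectrum and the spectra of all single-substitution variants, each variant
is scored at every frequency by its amplitude deviation from wild type,

    S(i, j) = A(f_j)_var_i - A(f_j)_wt,

giving an N_variants x M_frequencies score matrix.  Frequencies are then
visited in descending order of wild-type amplitude and, at each, a
two-sided Mann-Whitney U test compares the scores of labelled mutations
against those of labelled SNPs.  The first frequency with p below alpha
becomes the classifier frequency; the wild-type amplitude there is the
decision cutoff, and an orientation sign (+1 if mutation scores sit above
SNP scores by median, else -1) makes higher oriented scores mean
"mutation" regardless of which side of the wild type the mutated spectra
fall on.  A variant is called MUT when its oriented amplitude deviation at
the classifier frequency is strictly positive; a deviation of exactly zero
is called SNP (benign by default).

No correction for the sequential multiple testing is applied — the search
depth is reported as ``frequencies_tested`` instead, and the inflation of
the family-wise discovery rate under the null is characterised by
simulation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .encoding import encode_sequence
from .errors import DimensionError, InvalidInputError
from .spectrum import InformationalSpectrum, informational_spectrum
from .stats import mann_whitney_u
from .variants import MUT, SNP, Variant, apply_variant

DEGENERATE = "degenerate split"


@dataclass(frozen=True)
class ISMScoreMatrix:
    """Per-variant, per-frequency deviation scores S(i, j)."""

    scores: np.ndarray
    variant_ids: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.variant_ids), len(self.frequencies)):
            raise DimensionError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.frequencies)} "
                "frequencies"
            )

    @property
    def n_variants(self) -> int:
        return self.scores.shape[0]

    @property
    def n_frequencies(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class ClassifierModel:
    """A fitted per-gene ISM classifier.

    Attributes
    ----------
    frequency_index
        1-based spectral bin n of the classifier frequency.
    frequency
        n/N, dimensionless.
    cutoff_amplitude
        Wild-type amplitude S(n) at the classifier frequency.
    orientation
        +1 when mutation scores exceed SNP scores at the classifier
        frequency, -1 otherwise; multiplies raw deviations so that higher
        oriented scores always mean "mutation".
    p_value
        Mann-Whitney p at selection (below ``alpha`` by construction).
    frequencies_tested
        Number of sequential tests run before selection.
    """

    frequency_index: int
    frequency: float
    cutoff_amplitude: float
    orientation: int
    p_value: float
    alpha: float
    frequencies_tested: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (+1, -1):
            raise InvalidInputError("orientation must be +1 or -1")
        if not self.p_value < self.alpha:
            raise InvalidInputError("model p-value must be below alpha")
        if self.cutoff_amplitude < 0:
            raise InvalidInputError("cutoff amplitude must be non-negative")

    def save(self, path: str | Path) -> None:
        """Serialise as a small key=value text file."""
        lines = [
            f"gene\t{self.gene_id or ''}",
            f"frequency_index\t{self.frequency_index}",
            f"frequency\t{self.frequency!r}",
            # full precision: the cutoff participates in an exact tie rule
            f"cutoff_amplitude\t{self.cutoff_amplitude!r}",
            f"orientation\t{self.orientation:+d}",
            f"p_value\t{self.p_value!r}",
            f"alpha\t{self.alpha!r}",
            f"frequencies_tested\t{self.frequencies_tested}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, _, value = line.partition("\t")
                kv[key.strip()] = value.strip()
        try:
            return cls(
                gene_id=kv.get("gene") or None,
                frequency_index=int(kv["frequency_index"]),
                frequency=float(kv["frequency"]),
                cutoff_amplitude=float(kv["cutoff_amplitude"]),
                orientation=int(kv["orientation"]),
                p_value=float(kv["p_value"]),
                alpha=float(kv["alpha"]),
                frequencies_tested=int(kv["frequencies_tested"]),
            )
        except KeyError as exc:
            raise InvalidInputError(f"model file {path} missing field {exc}") from exc


@dataclass(frozen=True)
class TraceEntry:
    """One step of the sequential frequency search."""

    frequency_index: int
    frequency: float
    wt_amplitude: float
    p_value: float


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the sequential frequency search.

    ``model`` is ``None`` when no frequency reached significance ("no
    classifier found"); the full search trace is retained either way.
    """

    model: ClassifierModel | None
    trace: tuple[TraceEntry, ...] = field(default_factory=tuple)

    @property
    def found(self) -> bool:
        return self.model is not None


def ism_scores(
    wt: InformationalSpectrum,
    variant_spectra: Sequence[InformationalSpectrum],
    variant_ids: Sequence[str] | None = None,
) -> ISMScoreMatrix:
    """Amplitude deviations of each variant spectrum from the wild type.

    All spectra must share ``source_length`` (single substitutions
    preserve sequence length).  No normalisation is applied.
    """
    for i, vs in enumerate(variant_spectra):
        if vs.source_length != wt.source_length:
            raise DimensionError(
                f"variant spectrum {i} has source length {vs.source_length}; "
                f"wild type has {wt.source_length}"
            )
    if variant_ids is None:
        variant_ids = tuple(f"var{i + 1}" for i in range(len(variant_spectra)))
    rows = (
        np.vstack([vs.amplitudes for vs in variant_spectra]) - wt.amplitudes
        if variant_spectra
        else np.empty((0, wt.n_bins))
    )
    return ISMScoreMatrix(
        scores=rows, variant_ids=tuple(variant_ids), frequencies=wt.frequencies
    )


def _search_order(wt_amplitudes: np.ndarray) -> np.ndarray:
    # Descending wild-type amplitude; equal amplitudes in ascending
    # frequency order (stable sort on the negated amplitudes).
    return np.argsort(-wt_amplitudes, kind="stable")


def select_frequency(
    matrix: ISMScoreMatrix,
    wt: InformationalSpectrum,
    labels: Sequence[str],
    alpha: float = 0.05,
    mwu_method: str = "auto",
) -> SelectionResult:
    """Sequential Mann-Whitney search for the classifier frequency.

    Frequencies are visited in strictly descending order of wild-type
    amplitude; at each one, mutation-row scores are compared with SNP-row
    scores by a two-sided Mann-Whitney U test.  The first frequency with
    p < alpha is returned, with the wild-type amplitude there as cutoff.
    """
    if not 0 < alpha <= 1:
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    if len(labels) != matrix.n_variants:
        raise DimensionError("one label per score-matrix row is required")
    y = np.asarray(labels)
    mut_rows = y == MUT
    snp_rows = y == SNP
    if not mut_rows.any() or not snp_rows.any():
        raise InvalidInputError("both label classes must be non-empty")

    trace: list[TraceEntry] = []
    for col in _search_order(wt.amplitudes):
        mut_scores = matrix.scores[mut_rows, col]
        snp_scores = matrix.scores[snp_rows, col]
        _, p = mann_whitney_u(mut_scores, snp_scores, method=mwu_method)
        entry = TraceEntry(
            frequency_index=int(col) + 1,
            frequency=float(wt.frequencies[col]),
            wt_amplitude=float(wt.amplitudes[col]),
            p_value=float(p),
        )
        trace.append(entry)
        if p < alpha:
            orientation = (
                +1 if np.median(mut_scores) >= np.median(snp_scores) else -1
            )
            model = ClassifierModel(
                frequency_index=entry.frequency_index,
                frequency=entry.frequency,
                cutoff_amplitude=entry.wt_amplitude,
                orientation=orientation,
                p_value=entry.p_value,
                alpha=alpha,
                frequencies_tested=len(trace),
            )
            return SelectionResult(model=model, trace=tuple(trace))
    return SelectionResult(model=None, trace=tuple(trace))


def classify(variant_amplitude: float, model: ClassifierModel) -> str:
    """SNP/MUT call from the variant's amplitude at the classifier frequency.

    MUT iff orientation * (amplitude - cutoff) > 0; exact equality with the
    cutoff is called SNP.
    """
    return MUT if model.orientation * (variant_amplitude - model.cutoff_amplitude) > 0 else SNP


def oriented_score(score: float | np.ndarray, model: ClassifierModel) -> float | np.ndarray:
    """Orientation-adjusted deviation score(s): orientation * S(i, j_selected).

    Used as the continuous score for ROC analysis so that, across genes,
    higher always means "mutation".
    """
    return model.orientation * score


# ---------------------------------------------------------------------------
# Convenience fitting on sequences + variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFit:
    """Everything produced by fitting one gene: spectra, scores, selection."""

    wild_type_spectrum: InformationalSpectrum
    score_matrix: ISMScoreMatrix
    labels: tuple[str, ...]
    selection: SelectionResult
    variants: tuple[Variant, ...]

    @property
    def model(self) -> ClassifierModel | None:
        return self.selection.model

    def predicted_labels(self) -> list[str]:
        """Cutoff calls for the fitted variants (requires a found model)."""
        if self.model is None:
            raise InvalidInputError("no classifier frequency was found")
        col = self.model.frequency_index - 1
        amplitudes = (
            self.score_matrix.scores[:, col]
            + self.wild_type_spectrum.amplitudes[col]
        )
        return [classify(a, self.model) for a in amplitudes]

    def oriented_scores(self) -> np.ndarray:
        if self.model is None:
            raise InvalidInputError("no classifier frequency was found")
        col = self.model.frequency_index - 1
        return np.asarray(oriented_score(self.score_matrix.scores[:, col], self.model))


def variant_spectra(
    wild_type: str, variants: Sequence[Variant]
) -> list[InformationalSpectrum]:
    """Informational spectra of the mutated sequences, in input order."""
    return [
        informational_spectrum(encode_sequence(apply_variant(wild_type, v)))
        for v in variants
    ]


def fit_gene(
    wild_type: str,
    variants: Sequence[Variant],
    alpha: float = 0.05,
    gene_id: str | None = None,
    mwu_method: str = "auto",
) -> GeneFit:
    """Fit the ISM classifier for one protein.

    ``variants`` must all carry SNP/MUT labels and be consistent with the
    wild-type sequence.
    """
    labels = tuple(v.label or "" for v in variants)
    if any(l not in (SNP, MUT) for l in labels):
        raise InvalidInputError("every variant must be labelled SNP or MUT")
    wt_spec = informational_spectrum(encode_sequence(wild_type))
    spectra = variant_spectra(wild_type, variants)
    matrix = ism_scores(wt_spec, spectra, [v.short() for v in variants])
    selection = select_frequency(matrix, wt_spec, labels, alpha=alpha,
                                 mwu_method=mwu_method)
    if selection.model is not None and gene_id is not None:
        selection = SelectionResult(
            model=replace(selection.model, gene_id=gene_id),
            trace=selection.trace,
        )
    return GeneFit(
        wild_type_spectrum=wt_spec,
        score_matrix=matrix,
        labels=labels,
        selection=selection,
        variants=tuple(variants),
    )


def cross_validate_frequency(
    wild_type: str,
    variants: Sequence[Variant],
    k: int = 5,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[int | str | None]:
    """Stability check: k-fold frequency selection.

    Variants are shuffled (seeded) and split into k groups; each fold's
    classifier frequency is selected from the other k-1 groups.  Returns
    one entry per fold: the selected 1-based frequency index, ``None`` when
    no frequency reached significance, or ``"degenerate split"`` when a
    training portion lost one of the classes.
    """
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(variants))
    folds = np.array_split(order, k)
    results: list[int | str | None] = []
    for held_out in folds:
        train_idx = np.setdiff1d(order, held_out, assume_unique=True)
        train = [variants[i] for i in train_idx]
        train_labels = {v.label for v in train}
        if not {SNP, MUT} <= train_labels:
            results.append(DEGENERATE)
            continue
        fit = fit_gene(wild_type, train, alpha=alpha)
        results.append(
            fit.model.frequency_index if fit.model is not None else None
        )
    return results
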