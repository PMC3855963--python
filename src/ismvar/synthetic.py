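"""Synthetic wild-type sequences and labelled substitutions with a planted
spectral signal.

The generator makes the full classification pipeline testable without any
real protein data.  It emulates the situation the method assumes: a
protein whose EIIP profile carries a strong periodicity at one spectral
bin n*, a set of "mutations" that perturb the amplitude at that bin in a
sign-consistent way, and a set of "SNPs" that barely touch it.

Construction:

* The wild type is drawn residue-wise; at a fixed fraction of positions
  the residue whose EIIP value best tracks a cosine of frequency n*/N is
  taken, the rest are uniform over the alphabet.  This plants a strong
  periodic component, so the bin n* ranks at or near the top of the
  wild-type amplitudes — mirroring the premise that the classifier
  frequency is a prominent informational-spectrum peak.
* A substitution at position p changing the EIIP value by delta shifts the
  Fourier coefficient at bin n by delta * exp(-i 2 pi n (p-1)/N); the
  amplitude change is evaluated in closed form for every candidate
  (position, alternate residue) pair, capped at ``max_candidates``
  seeded draws per dataset for speed.
* MUT substitutions are the candidates with the largest positive amplitude
  shift at n*; SNP substitutions come from the smallest decile of
  |shift at n*| and additionally have minimal shift over the 3 bins either
  side of n*, so recovery tests are not confounded by leakage into
  neighbouring bins.

The realised standardised separation between the groups at n* (difference
of means over pooled SD) is recorded and must reach the requested effect
size, otherwise generation fails with a hint to increase the length.
``effect_size=0`` is the exchangeable null: both classes are drawn
uniformly from the same candidate pool.

No attempt is made to mimic real mutational spectra, codon structure or
disease prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import CANONICAL_RESIDUES, default_scale, encode_sequence
from .errors import GenerationError, InvalidInputError
from .spectrum import fourier_coefficients
from .variants import MUT, SNP, Variant

#: Fraction of wild-type positions that track the planted cosine.
PLANT_MIXING = 0.5
#: Cap on candidate (position, alternate-residue) evaluations per dataset.
MAX_CANDIDATES = 5000
#: Bins either side of the planted one that SNP substitutions must also
#: leave quiet.
SNP_GUARD_BINS = 3

_ALPHABET = np.array(list(CANONICAL_RESIDUES))


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated wild type plus labelled substitutions.

    ``planted_frequency_index`` is ``None`` for null datasets;
    ``realized_separation`` is the standardised MUT-vs-SNP separation of
    the amplitude shifts at the planted bin (0.0 for null datasets).
    """

    wild_type: str
    variants: tuple[Variant, ...]
    planted_frequency_index: int | None
    effect_size: float
    realized_separation: float
    seed: int

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label or "" for v in self.variants)

    def write_fasta(self, path: str | Path, gene_id: str = "SYNTH") -> None:
        seq = self.wild_type
        lines = [f">{gene_id} synthetic wild type"]
        lines += [seq[i : i + 60] for i in range(0, len(seq), 60)]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_variants(self, path: str | Path, gene_id: str = "SYNTH") -> None:
        lines = ["gene\tsubstitution\tlabel"]
        lines += [f"{gene_id}\t{v.short()}\t{v.label}" for v in self.variants]
        Path(path).write_text("\n".join(lines) + "\n")


def _eiip_values() -> np.ndarray:
    scale = default_scale()
    return np.array([scale[ch] for ch in _ALPHABET])


def _planted_wild_type(
    length: int, planted_index: int, rng: np.random.Generator
) -> str:
    values = _eiip_values()
    lo, hi = values.min(), values.max()
    mid, amp = (lo + hi) / 2, (hi - lo) / 2
    m = np.arange(length)
    target = mid + amp * np.cos(2 * np.pi * planted_index * m / length)
    nearest = np.abs(values[None, :] - target[:, None]).argmin(axis=1)
    uniform = rng.integers(0, len(values), size=length)
    coherent = rng.random(length) < PLANT_MIXING
    codes = np.where(coherent, nearest, uniform)
    return "".join(_ALPHABET[codes])


def _candidates(
    series: np.ndarray, wt_codes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (position, alternate) pairs as (pos0, alt_code, delta), capped."""
    length = series.size
    values = _eiip_values()
    pos0, alt = np.meshgrid(np.arange(length), np.arange(len(values)),
                            indexing="ij")
    pos0, alt = pos0.ravel(), alt.ravel()
    keep = alt != wt_codes[pos0]
    pos0, alt = pos0[keep], alt[keep]
    if pos0.size > MAX_CANDIDATES:
        pick = rng.choice(pos0.size, size=MAX_CANDIDATES, replace=False)
        pos0, alt = pos0[pick], alt[pick]
    delta = values[alt] - series[pos0]
    return pos0, alt, delta


def _amplitude_shift(
    coeffs: np.ndarray, bins: np.ndarray, pos0: np.ndarray,
    delta: np.ndarray, length: int,
) -> np.ndarray:
    """Closed-form S(n) change per candidate; shape (n_candidates, n_bins).

    For a single substitution, X(n) gains delta * exp(-i 2 pi n pos0 / N),
    so S(n) changes by 2 Re(X(n)* dX) + |delta|^2.
    """
    phase = np.exp(-2j * np.pi * np.outer(pos0, bins) / length)
    d_x = delta[:, None] * phase
    x = coeffs[bins - 1][None, :]
    return 2 * np.real(np.conj(x) * d_x) + np.abs(delta[:, None]) ** 2


def _make_variant(
    wild_type: str, pos0: int, alt_code: int, label: str, gene_id: str
) -> Variant:
    return Variant(
        position=pos0 + 1,
        wt_residue=wild_type[pos0],
        alt_residue=str(_ALPHABET[alt_code]),
        label=label,
        gene_id=gene_id,
    )


def generate_planted_dataset(
    length: int = 300,
    planted_frequency_index: int = 143,
    n_mut: int = 20,
    n_snp: int = 20,
    effect_size: float = 3.0,
    seed: int = 0,
    gene_id: str = "SYNTH",
) -> SyntheticDataset:
    """Generate a wild type and labelled substitutions with a planted signal.

    Parameters
    ----------
    length
        Wild-type length N (at least 50).
    planted_frequency_index
        Target spectral bin n* in [1, floor(N/2)].
    n_mut, n_snp
        Class sizes (at least 3 each).
    effect_size
        Minimum standardised separation (pooled-SD units) the generated
        groups must show at n*; 0 gives the exchangeable null in which
        both classes are uniform random substitutions.
    seed
        Seeds every random draw; identical arguments and seed give a
        byte-identical dataset.
    """
    if length < 50:
        raise InvalidInputError("length must be at least 50")
    max_bin = length // 2
    if not 1 <= planted_frequency_index <= max_bin:
        raise InvalidInputError(
            f"planted index must be in [1, {max_bin}], got {planted_frequency_index}"
        )
    if min(n_mut, n_snp) < 3:
        raise InvalidInputError("need at least 3 variants per class")
    if effect_size < 0:
        raise InvalidInputError("effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    n_star = planted_frequency_index
    wild_type = _planted_wild_type(length, n_star, rng)
    series = encode_sequence(wild_type)
    code_of = {ch: i for i, ch in enumerate(_ALPHABET)}
    wt_codes = np.array([code_of[ch] for ch in wild_type])
    coeffs = fourier_coefficients(series)
    pos0, alt, delta = _candidates(series, wt_codes, rng)

    if effect_size == 0:
        pick = rng.choice(pos0.size, size=n_mut + n_snp, replace=False)
        variants = [
            _make_variant(wild_type, pos0[i], alt[i],
                          MUT if k < n_mut else SNP, gene_id)
            for k, i in enumerate(pick)
        ]
        return SyntheticDataset(
            wild_type=wild_type,
            variants=tuple(variants),
            planted_frequency_index=n_star,
            effect_size=0.0,
            realized_separation=0.0,
            seed=seed,
        )

    shift_at_star = _amplitude_shift(
        coeffs, np.array([n_star]), pos0, delta, length
    )[:, 0]

    # MUT: largest positive shifts at the planted bin (sign-consistent).
    mut_order = np.argsort(-shift_at_star, kind="stable")[:n_mut]
    if shift_at_star[mut_order[-1]] <= 0:
        raise GenerationError(
            "could not find enough sign-consistent amplitude shifts; "
            "try a larger sequence length"
        )

    # SNP: smallest decile of |shift at n*| among remaining candidates,
    # quietest over the guard window around n*.
    remaining = np.setdiff1d(np.arange(pos0.size), mut_order)
    abs_shift = np.abs(shift_at_star)
    decile = np.quantile(abs_shift, 0.1)
    quiet = remaining[abs_shift[remaining] <= decile]
    if quiet.size < n_snp:
        raise GenerationError(
            "not enough quiet substitutions for the SNP class; "
            "try a larger sequence length"
        )
    window = np.arange(max(1, n_star - SNP_GUARD_BINS),
                       min(max_bin, n_star + SNP_GUARD_BINS) + 1)
    quiet = quiet[rng.permutation(quiet.size)]  # seeded tie-break
    window_shift = np.abs(
        _amplitude_shift(coeffs, window, pos0[quiet], delta[quiet], length)
    ).max(axis=1)
    snp_pick = quiet[np.argsort(window_shift, kind="stable")[:n_snp]]

    mut_scores = shift_at_star[mut_order]
    snp_scores = shift_at_star[snp_pick]
    pooled_sd = np.sqrt(
        ((n_mut - 1) * mut_scores.var(ddof=1)
         + (n_snp - 1) * snp_scores.var(ddof=1)) / (n_mut + n_snp - 2)
    )
    separation = (
        float("inf") if pooled_sd == 0
        else (mut_scores.mean() - snp_scores.mean()) / pooled_sd
    )
    if separation < effect_size:
        raise GenerationError(
            f"realized separation {separation:.2f} below requested "
            f"{effect_size}; try a larger sequence length"
        )

    variants = [
        _make_variant(wild_type, pos0[i], alt[i], MUT, gene_id)
        for i in mut_order
    ] + [
        _make_variant(wild_type, pos0[i], alt[i], SNP, gene_id)
        for i in snp_pick
    ]
    return SyntheticDataset(
        wild_type=wild_type,
        variants=tuple(variants),
        planted_frequency_index=n_star,
        effect_size=effect_size,
        realized_separation=float(separation),
        seed=seed,
    )


def generate_null_dataset(
    length: int = 200,
    n_per_class: int = 15,
    seed: int = 0,
    gene_id: str = "SYNTH",
) -> SyntheticDataset:
    """Uniform random substitutions for both classes (no planted signal).

    Used to characterise the sequential frequency search's family-wise
    discovery behaviour under the null.
    """
    if length < 50:
        raise InvalidInputError("length must be at least 50")
    if n_per_class < 1:
        raise InvalidInputError("need at least 1 variant per class")
    rng = np.random.default_rng(seed)
    wild_type = "".join(_ALPHABET[rng.integers(0, len(_ALPHABET), size=length)])
    series = encode_sequence(wild_type)
    code_of = {ch: i for i, ch in enumerate(_ALPHABET)}
    wt_codes = np.array([code_of[ch] for ch in wild_type])
    pos0, alt, _delta = _candidates(series, wt_codes, rng)
    pick = rng.choice(pos0.size, size=2 * n_per_class, replace=False)
    variants = [
        _make_variant(wild_type, pos0[i], alt[i],
                      MUT if k < n_per_class else SNP, gene_id)
        for k, i in enumerate(pick)
    ]
    return SyntheticDataset(
        wild_type=wild_type,
        variants=tuple(variants),
        planted_frequency_index=None,
        effect_size=0.0,
        realized_separation=0.0,
        seed=seed,
    )
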