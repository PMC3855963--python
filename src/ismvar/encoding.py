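"""EIIP encoding of protein sequences.

Each of the 20 canonical residues carries an electron-ion interaction
potential (EIIP, in Rydberg units), a physicochemical constant that
approximates the average energy of its valence electrons.  A protein
sequence becomes a numeric series by position-wise lookup; the series is
the input to the spectral analysis in :mod:`ismvar.spectrum`.

The packaged scale is the standard EIIP table used throughout the ISM
literature.  Leucine and isoleucine share the value 0.0, and serine and
cysteine share 0.0829, so encoding is injective only up to those pairs.
Alternative per-residue scales can be loaded from a two-column delimited
file with :meth:`EIIPScale.from_file`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .errors import EncodingError, InvalidInputError

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: EIIP values (Ry) for the 20 canonical amino acids.
EIIP_VALUES: Mapping[str, float] = {
    "L": 0.0000,
    "I": 0.0000,
    "N": 0.0036,
    "G": 0.0050,
    "V": 0.0057,
    "E": 0.0058,
    "P": 0.0198,
    "H": 0.0242,
    "K": 0.0371,
    "A": 0.0373,
    "Y": 0.0516,
    "W": 0.0548,
    "Q": 0.0761,
    "M": 0.0823,
    "S": 0.0829,
    "C": 0.0829,
    "T": 0.0941,
    "F": 0.0954,
    "R": 0.0956,
    "D": 0.1263,
}


@dataclass(frozen=True)
class EIIPScale:
    """A residue -> EIIP value map (the numerical encoding alphabet).

    Parameters
    ----------
    values
        Mapping from one-letter residue code to EIIP value in Rydbergs.
        Must cover exactly the 20 canonical residues.
    """

    values: Mapping[str, float] = field(default_factory=lambda: dict(EIIP_VALUES))

    def __post_init__(self) -> None:
        keys = set(self.values)
        expected = set(CANONICAL_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise InvalidInputError(
                f"scale must cover exactly the 20 canonical residues; "
                f"missing={missing} extra={extra}"
            )
        for residue, value in self.values.items():
            if not (0.0 <= value <= 0.13):
                raise InvalidInputError(
                    f"EIIP value for {residue} is {value}; expected within [0, 0.13]"
                )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    @classmethod
    def from_file(cls, path: str | Path) -> "EIIPScale":
        """Load a scale from a two-column delimited file (residue, value).

        A header line is permitted and detected by a non-numeric second
        column.  Both tab and comma separators are accepted.
        """
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) < 2:
                raise InvalidInputError(f"malformed scale line: {line!r}")
            try:
                value = float(parts[1])
            except ValueError:
                continue  # header
            values[parts[0].strip().upper()] = value
        return cls(values=values)

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        lines = ["residue" + sep + "value"]
        for residue in sorted(self.values):
            lines.append(f"{residue}{sep}{self.values[residue]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def default_scale() -> EIIPScale:
    """The packaged EIIP scale."""
    return EIIPScale()


def packaged_scale_path() -> Path:
    """Path of the packaged two-column EIIP scale file."""
    return Path(importlib.resources.files("ismvar.data") / "eiip_scale.tsv")


def encode_sequence(
    sequence: str,
    scale: EIIPScale | None = None,
    *,
    impute_noncanonical: bool = False,
) -> np.ndarray:
    """Map a protein sequence to its EIIP numeric series.

    Parameters
    ----------
    sequence
        Protein sequence over the canonical one-letter alphabet
        (case-insensitive).
    scale
        Encoding alphabet; defaults to the packaged EIIP table.
    impute_noncanonical
        Off by default.  When enabled, residues outside the canonical
        alphabet are mapped to the mean EIIP of the canonical positions in
        the same sequence instead of raising.  Intended only for quick
        exploration of sequences with ambiguity codes.

    Returns
    -------
    numpy.ndarray
        Series of EIIP values (Ry), same length as ``sequence``.

    Raises
    ------
    InvalidInputError
        If the sequence is empty.
    EncodingError
        On the first non-canonical residue (1-based position reported),
        unless ``impute_noncanonical`` is set.
    """
    if not sequence:
        raise InvalidInputError("cannot encode an empty sequence")
    if scale is None:
        scale = default_scale()
    seq = sequence.upper()
    bad = [i for i, ch in enumerate(seq) if ch not in scale.values]
    if bad and not impute_noncanonical:
        pos = bad[0] + 1
        raise EncodingError(
            f"non-canonical residue {seq[bad[0]]!r} at position {pos}"
        )
    out = np.empty(len(seq), dtype=float)
    for i, ch in enumerate(seq):
        out[i] = scale.values.get(ch, np.nan)
    if bad:
        canonical = np.delete(out, bad)
        if canonical.size == 0:
            raise EncodingError("sequence has no canonical residues to impute from")
        out[bad] = canonical.mean()
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a single- or multi-record FASTA into ``{identifier: sequence}``.

    The record identifier is the first whitespace-delimited token of the
    description line; UniProt-style ``db|ACC|NAME`` headers are reduced to
    the accession.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            if len(parts) >= 2 and parts[1]:
                ident = parts[1]
        records[ident] = str(rec.seq).upper()
    if not records:
        raise InvalidInputError(f"no FASTA records found in {path}")
    return records


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    yield from read_fasta(path).items()
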