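"""Position matrices over the DNA alphabet.

A :class:`PositionMatrix` plays two roles in the pipeline: as a scanning
PWM (log-odds scoring of promoter windows against a background model) and
as a group PFM (per-position base frequencies estimated from aligned
binding sites).  Matrices are read and written in the JASPAR, TRANSFAC and
MEME-minimal text dialects via :mod:`Bio.motifs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import motifs as _bio_motifs

__all__ = [
    "BASES",
    "PositionMatrix",
    "read_position_matrix",
    "write_position_matrix",
    "canonical_isre_matrix",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: uniform background over {A, C, G, T}
UNIFORM_BG = np.full(4, 0.25)


class MatrixFormatError(ValueError):
    """Raised when a matrix file or matrix content is malformed."""


@dataclass(frozen=True)
class PositionMatrix:
    """Counts or probabilities over {A, C, G, T} per motif position.

    Parameters
    ----------
    values
        Array of shape ``(length, 4)``; rows are positions, columns follow
        the alphabet order ``A, C, G, T``.
    kind
        ``"counts"`` or ``"probability"``.
    pseudocount
        Per-cell pseudocount applied when converting counts to
        probabilities; ignored for probability matrices.
    background
        Background base probabilities (length 4, summing to 1) attached to
        the matrix for log-odds scoring.  Defaults to uniform.
    name
        Free-text identifier carried through serialization.
    """

    values: np.ndarray
    kind: str = "counts"
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if vals.ndim != 2 or vals.shape[1] != 4:
            raise MatrixFormatError("matrix must have shape (length, 4)")
        if vals.shape[0] < 4:
            raise MatrixFormatError("motif length must be >= 4")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise MatrixFormatError("matrix entries must be finite and non-negative")
        if self.kind not in ("counts", "probability"):
            raise MatrixFormatError(f"unknown matrix kind {self.kind!r}")
        if self.kind == "probability":
            sums = vals.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise MatrixFormatError("probability columns must each sum to 1")
        if self.pseudocount < 0:
            raise MatrixFormatError("pseudocount must be non-negative")
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise MatrixFormatError("background must be 4 positive probabilities summing to 1")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def probabilities(self, pseudocount: float | None = None) -> np.ndarray:
        """Per-position base probabilities.

        Counts are converted as ``(count + pc) / (total + 4 * pc)``; a
        probability matrix is returned as stored.
        """
        if self.kind == "probability":
            return self.values.copy()
        pc = self.pseudocount if pseudocount is None else pseudocount
        totals = self.values.sum(axis=1, keepdims=True)
        if pc == 0 and np.any(totals == 0):
            raise MatrixFormatError(
                "column of all-zero counts with pseudocount 0; raise the pseudocount"
            )
        return (self.values + pc) / (totals + 4.0 * pc)

    def as_probability(self, pseudocount: float | None = None) -> "PositionMatrix":
        return PositionMatrix(
            self.probabilities(pseudocount),
            kind="probability",
            pseudocount=0.0,
            background=self.background,
            name=self.name,
        )

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Log2 likelihood-ratio scores ``log2(p_i(b) / q(b))``, shape (L, 4).

        Requires strictly positive probabilities; zero cells are a numeric
        error whose remedy is a positive pseudocount.
        """
        probs = self.probabilities()
        if np.any(probs <= 0):
            raise MatrixFormatError(
                "zero probability in matrix; use a positive pseudocount before scoring"
            )
        q = np.asarray(self.background if background is None else background, dtype=float)
        return np.log2(probs / q)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities().argmax(axis=1))


def _from_bio_motif(m, pseudocount: float, kind: str = "counts") -> PositionMatrix:
    arr = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
    if kind == "probability":
        arr = arr / arr.sum(axis=1, keepdims=True)
    name = m.name or getattr(m, "matrix_id", "") or ""
    return PositionMatrix(arr, kind=kind, pseudocount=pseudocount, name=str(name))


def read_position_matrix(
    path: str | Path, format: str = "jaspar", pseudocount: float = 0.01
) -> PositionMatrix:
    """Read a position matrix in TRANSFAC, JASPAR or MEME(-minimal) text format.

    Count matrices keep their counts and carry ``pseudocount`` for later
    probability conversion; MEME files, which store probabilities, are
    converted back to counts using the recorded ``nsites``.
    """
    fmt = format.lower()
    path = Path(path)
    try:
        with open(path) as handle:
            if fmt == "jaspar":
                m = _bio_motifs.read(handle, "jaspar")
            elif fmt == "transfac":
                parsed = _bio_motifs.parse(handle, "transfac")
                if not parsed:
                    raise MatrixFormatError(f"no motif found in {path}")
                m = parsed[0]
            elif fmt == "meme":
                parsed = _bio_motifs.parse(handle, "minimal")
                if not parsed:
                    raise MatrixFormatError(f"no motif found in {path}")
                m = parsed[0]
            else:
                raise MatrixFormatError(f"unknown matrix format {format!r}")
    except MatrixFormatError:
        raise
    except Exception as exc:  # Bio raises assorted exceptions on bad input
        raise MatrixFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _from_bio_motif(m, pseudocount)


def write_position_matrix(pm: PositionMatrix, path: str | Path, format: str = "jaspar") -> None:
    """Write a matrix in the JASPAR or TRANSFAC text dialect (counts)."""
    fmt = format.lower()
    counts = pm.values if pm.kind == "counts" else pm.probabilities() * 100.0
    m = _bio_motifs.Motif(
        counts={b: list(counts[:, i]) for i, b in enumerate(BASES)}
    )
    m.name = pm.name or "motif"
    m.matrix_id = pm.name or "motif"
    if fmt == "jaspar":
        text = _bio_motifs.write([m], "jaspar")
    elif fmt == "transfac":
        text = _bio_motifs.write([m], "transfac")
    else:
        raise MatrixFormatError(f"unsupported output format {format!r}")
    Path(path).write_text(text)


def canonical_isre_matrix(pseudocount: float = 0.01) -> PositionMatrix:
    """The packaged stand-in canonical ISRE matrix.

    A synthetic 13-bp count matrix built around the field's consensus ISRE
    core (``NGAAANTGAAACT``).  It is shipped because curated commercial
    motif collections cannot be redistributed; any JASPAR/TRANSFAC/MEME
    matrix file may be substituted via :func:`read_position_matrix`.
    """
    ref = resources.files("isrekit.data").joinpath("isre_synthetic.jaspar")
    with resources.as_file(ref) as path:
        return read_position_matrix(path, "jaspar", pseudocount=pseudocount)


def sequence_composition(sequences: Iterable[str]) -> np.ndarray:
    """Base composition of a sequence collection (A, C, G, T), ignoring N."""
    counts = np.zeros(4)
    for seq in sequences:
        s = seq.upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases in sequence set")
    return counts / total
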