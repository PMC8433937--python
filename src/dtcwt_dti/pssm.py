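"""Position-specific scoring matrices (PSSMs) and the PSI-BLAST ASCII format.

A PSSM summarises the evolutionary profile of a protein as a P x 20 matrix
of integer log-odds scores, one row per residue and one column per standard
amino acid.  PSI-BLAST emits these with ``-out_ascii_pssm``: a couple of
header lines, a column-letter line (the 20 letters printed twice — log-odds
block then weighted-percentage block), one line per residue with the
position index, the residue letter and at least 40 integers, and trailer
statistics.  Only the first 20 integer columns (the log-odds block) are
retained here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_ALPHABET", "PSSM", "PSSMParseError",
    "parse_pssm", "validate_pssm", "load_pssm_dir", "sigmoid",
]

#: PSI-BLAST header column order; every parsed matrix is aligned to it.
CANONICAL_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Raised for malformed PSI-BLAST ASCII PSSM content."""


@dataclass
class PSSM:
    """A protein's P x 20 log-odds profile.

    ``column_order`` records the amino-acid letter of each matrix column;
    after parsing it always equals :data:`CANONICAL_ALPHABET`.
    """

    protein_id: str
    matrix: np.ndarray
    residues: str
    column_order: str = CANONICAL_ALPHABET

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def normalized(self, method: str = "none") -> "PSSM":
        """Return a copy with elementwise normalisation applied.

        ``"none"`` keeps raw log-odds; ``"sigmoid"`` maps each score
        through 1 / (1 + exp(-x)).
        """
        if method == "none":
            return self
        if method == "sigmoid":
            return replace(self, matrix=sigmoid(self.matrix))
        raise ValueError(f"unknown normalisation {method!r}; use 'none' or 'sigmoid'")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _is_row_line(tokens: list[str]) -> bool:
    return len(tokens) >= 22 and tokens[0].lstrip("-").isdigit() and len(tokens[1]) == 1


def parse_pssm(text: str, protein_id: str = "") -> PSSM:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content into a :class:`PSSM`.

    The first 20 numeric columns of each residue row are kept; the
    percentage block and the information-content/K/Lambda trailer are
    discarded.  Column order is taken from the letter header line and the
    matrix is re-ordered to :data:`CANONICAL_ALPHABET`.
    """
    header_order: str | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if header_order is None:
            letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
            if len(letters) >= 20 and len(letters) == len(tokens):
                order = "".join(letters[:20])
                if sorted(order) != sorted(CANONICAL_ALPHABET):
                    raise PSSMParseError(
                        f"line {lineno}: column letters are not the 20 standard amino acids"
                    )
                header_order = order
            continue
        if _is_row_line(tokens):
            expected = int(tokens[0])
            if expected != len(rows) + 1:
                raise PSSMParseError(
                    f"line {lineno}: position index {expected} out of order "
                    f"(expected {len(rows) + 1})"
                )
            scores = tokens[2:]
            n_int = 0
            for tok in scores:
                if tok.lstrip("-").isdigit():
                    n_int += 1
                else:
                    break
            if n_int != 20 and n_int < 40:
                raise PSSMParseError(
                    f"line {lineno}: expected 20 (or 40) integer score columns, "
                    f"found {n_int}"
                )
            try:
                values = [float(int(tok)) for tok in scores[:20]]
            except ValueError as exc:
                raise PSSMParseError(f"line {lineno}: non-integer score ({exc})") from None
            rows.append(values)
            residues.append(tokens[1])
        elif rows:
            break   # trailer (K, Lambda, statistics) reached
        elif header_order is not None and len(tokens) > 2:
            raise PSSMParseError(f"line {lineno}: malformed PSSM row {raw!r}")
    if not rows:
        raise PSSMParseError("no PSSM rows")
    matrix = np.array(rows, dtype=float)
    order = header_order or CANONICAL_ALPHABET
    if order != CANONICAL_ALPHABET:
        perm = [order.index(a) for a in CANONICAL_ALPHABET]
        matrix = matrix[:, perm]
    return PSSM(protein_id=protein_id, matrix=matrix, residues="".join(residues))


def validate_pssm(p: PSSM) -> list[str]:
    """Return human-readable invariant violations (empty list if valid)."""
    problems: list[str] = []
    m = np.asarray(p.matrix)
    if m.ndim != 2 or m.shape[1] != 20:
        problems.append(
            f"matrix must have exactly 20 columns, found shape {m.shape}"
        )
    if m.ndim == 2 and m.shape[0] < 1:
        problems.append("matrix must have at least one row")
    if m.ndim == 2 and len(p.residues) != m.shape[0]:
        problems.append(
            f"residue string length {len(p.residues)} != row count {m.shape[0]}"
        )
    if sorted(p.column_order) != sorted(CANONICAL_ALPHABET):
        problems.append("column_order is not a permutation of the 20 amino-acid letters")
    bad = np.argwhere(~np.isfinite(m)) if m.ndim == 2 else []
    for r, c in bad[:5]:
        problems.append(f"non-finite entry at row {r}, column {c}")
    return problems


def load_pssm_dir(path: str | Path, pattern: str = "*.pssm") -> dict[str, PSSM]:
    """Load every PSSM file in a directory; filename stem becomes protein_id."""
    path = Path(path)
    out: dict[str, PSSM] = {}
    for f in sorted(path.glob(pattern)):
        out[f.stem] = parse_pssm(f.read_text(), protein_id=f.stem)
    if not out:
        raise FileNotFoundError(f"no {pattern} files in {path}")
    return out
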