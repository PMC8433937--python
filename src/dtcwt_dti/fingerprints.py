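"""881-bit substructure fingerprints for drug molecules.

Each drug is a binary vector over the 881 predefined chemical
substructure keys of the PubChem fingerprint system.  Fingerprints are
consumed precomputed; which substructure a bit denotes is opaque here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["N_BITS", "DrugFingerprint", "load_fingerprints", "render_fingerprints"]

N_BITS = 881


@dataclass
class DrugFingerprint:
    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits)
        if b.shape != (N_BITS,):
            raise ValueError(
                f"fingerprint for {self.drug_id!r} must have {N_BITS} bits, got {b.size}"
            )
        if not np.isin(b, (0, 1)).all():
            raise ValueError(f"fingerprint for {self.drug_id!r} has non-binary entries")
        self.bits = b.astype(np.uint8)


def _parse_row(drug_id: str, fields: list[str], lineno: int) -> DrugFingerprint:
    if len(fields) == 1:
        s = fields[0]
        if len(s) != N_BITS:
            raise ValueError(
                f"line {lineno}: drug {drug_id!r} has {len(s)} bits, expected {N_BITS}"
            )
        if set(s) - {"0", "1"}:
            raise ValueError(f"line {lineno}: drug {drug_id!r} has non-binary characters")
        bits = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    else:
        if len(fields) != N_BITS:
            raise ValueError(
                f"line {lineno}: drug {drug_id!r} has {len(fields)} bit columns, "
                f"expected {N_BITS}"
            )
        if any(f not in ("0", "1") for f in fields):
            raise ValueError(f"line {lineno}: drug {drug_id!r} has non-binary tokens")
        bits = np.array([int(f) for f in fields], dtype=np.uint8)
    return DrugFingerprint(drug_id, bits)


def load_fingerprints(source: str | Path) -> dict[str, DrugFingerprint]:
    """Read a fingerprint table (text content or path to a TSV/CSV file).

    Each row is a drug id followed by either one 881-character 0/1 string
    or 881 delimited 0/1 tokens; tab and comma delimiters are detected
    automatically.  Input order is preserved; duplicate ids are an error.
    """
    looks_like_path = isinstance(source, Path) or (
        len(str(source)) < 500 and "\n" not in str(source) and "\t" not in str(source)
    )
    if looks_like_path and Path(source).is_file():
        text = Path(source).read_text()
    else:
        text = str(source)
    out: dict[str, DrugFingerprint] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        fields = [f.strip() for f in fields if f.strip() != ""]
        if lineno == 1 and fields and fields[0].lower() in ("drug_id", "drug", "id"):
            continue
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected drug id and bits")
        drug_id = fields[0]
        if drug_id in out:
            raise ValueError(f"line {lineno}: duplicate drug_id {drug_id!r}")
        out[drug_id] = _parse_row(drug_id, fields[1:], lineno)
    if not out:
        raise ValueError("no fingerprint rows found")
    return out


def render_fingerprints(fps: dict[str, DrugFingerprint]) -> str:
    """Serialise fingerprints as drug_id<TAB>bitstring lines (load round-trip)."""
    lines = []
    for drug_id, fp in fps.items():
        lines.append(f"{drug_id}\t{''.join(map(str, fp.bits.tolist()))}")
    return "\n".join(lines) + "\n"
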