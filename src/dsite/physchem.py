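"""Dinucleotide physicochemical property table for the PseDNC coupling factor.

The pseudo dinucleotide composition weighs sequence-order correlation by the
physicochemical similarity of dinucleotide steps.  Three RNA nearest-neighbor
thermodynamic properties are used (mu = 3): enthalpy (kcal/mol), entropy
(cal/mol/K) and free energy at 37 C (kcal/mol).  Each property column is
standardized to mean 0 / sd 1 over the 16 dinucleotides before use, which
makes every downstream feature invariant to affine rescaling of the raw
column (unit changes, reference-state shifts).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGU" for b in "ACGU")
PROPERTY_NAMES: tuple[str, ...] = ("enthalpy", "entropy", "free_energy")

_PACKAGED = "dinucleotide_properties.tsv"


class PropertyTableError(ValueError):
    """The property table violates its contract."""


@dataclass(frozen=True)
class DinucleotidePropertyTable:
    """16 dinucleotides x mu properties, raw and standardized.

    ``standardized[d]`` holds P_g(d): per property, (raw - mean) / sd over
    the 16 dinucleotides (sample sd by default, see ``standardize_properties``).
    """

    properties: tuple[str, ...]
    raw: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray]

    @property
    def mu(self) -> int:
        return len(self.properties)

    def values_matrix(self, standardized: bool = True) -> np.ndarray:
        src = self.standardized if standardized else self.raw
        return np.array([src[d] for d in DINUCLEOTIDES])

    def content_hash(self) -> str:
        """Hash of the raw values, used for model provenance checks."""
        import hashlib

        m = hashlib.sha256()
        m.update(",".join(self.properties).encode())
        for d in DINUCLEOTIDES:
            m.update(d.encode() + np.asarray(self.raw[d], dtype=float).tobytes())
        return m.hexdigest()


def standardize_properties(raw: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize each property column over the 16 dinucleotides.

    ``ddof=1`` (sample standard deviation) is the PseKNC-literature
    convention; pass ``ddof=0`` for the population version.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != 16:
        raise PropertyTableError(f"expected 16 rows, got {raw.shape[0]}")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=ddof)
    # relative tolerance: a constant column leaves sd at float round-off
    zero = np.nonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))[0]
    if zero.size:
        raise PropertyTableError(
            f"property column(s) {zero.tolist()} have zero variance"
        )
    return (raw - mean) / sd


def load_property_table(
    source: Optional[str | Path] = None, ddof: int = 1
) -> DinucleotidePropertyTable:
    """Load the packaged default table, or a user TSV with the same layout.

    The TSV has header ``dinucleotide<TAB>enthalpy<TAB>entropy<TAB>free_energy``
    and one row per dinucleotide; ``#`` lines are comments.
    """
    if source is None:
        text = (resources.files("dsite") / "data" / _PACKAGED).read_text()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[0] != "dinucleotide":
        raise PropertyTableError("first column must be 'dinucleotide'")
    properties = tuple(header[1:])
    if len(properties) != len(PROPERTY_NAMES):
        raise PropertyTableError(
            f"expected {len(PROPERTY_NAMES)} property columns, got {len(properties)}"
        )
    raw: dict[str, np.ndarray] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise PropertyTableError(f"malformed row: {ln!r}")
        d = fields[0].upper().replace("T", "U")
        raw[d] = np.array([float(x) for x in fields[1:]])
    missing = [d for d in DINUCLEOTIDES if d not in raw]
    if missing:
        raise PropertyTableError(f"missing dinucleotide(s): {missing}")
    extra = set(raw) - set(DINUCLEOTIDES)
    if extra:
        raise PropertyTableError(f"unknown dinucleotide(s): {sorted(extra)}")
    mat = np.array([raw[d] for d in DINUCLEOTIDES])
    std = standardize_properties(mat, ddof=ddof)
    standardized = {d: std[i] for i, d in enumerate(DINUCLEOTIDES)}
    return DinucleotidePropertyTable(properties, raw, standardized)
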