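"""Reference list of m/z differences for chemical-redundancy detection.

Isotopes, adducts and in-source fragments of one metabolite appear as separate
features whose m/z values differ by characteristic offsets.  The default table
below covers the common electrospray cases; users can supply their own TSV
(columns ``label`` and ``delta_mz``) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: (label, delta in Da) — common isotope/adduct/fragment spacings
DEFAULT_MZ_DIFFS = [
    ("isotope_13C", 1.00336),
    ("Na_minus_H", 21.98194),
    ("K_minus_H", 37.95588),
    ("NH4", 17.02655),
    ("H2O_loss", 18.01056),
    ("HCOOH", 46.00548),
    ("Cl", 34.96885),
    ("CH3COOH", 60.02113),
]


@dataclass
class MzDiffTable:
    """A list of (label, delta_mz) rows with a matching tolerance in Da."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        DEFAULT_MZ_DIFFS, columns=["label", "delta_mz"]))
    tolerance: float = 0.005

    def __post_init__(self):
        if not {"label", "delta_mz"}.issubset(self.rows.columns):
            raise ValueError("MzDiffTable rows need 'label' and 'delta_mz' columns")
        if (self.rows["delta_mz"] <= 0).any():
            raise ValueError("delta_mz entries must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def deltas(self):
        return self.rows["delta_mz"].to_numpy(dtype=float)

    def matches(self, mz_a: float, mz_b: float) -> bool:
        """True if |mz_a - mz_b| matches any reference delta within tolerance."""
        d = abs(mz_a - mz_b)
        return bool((abs(self.deltas - d) <= self.tolerance).any())

    @classmethod
    def from_tsv(cls, path, tolerance: float = 0.005) -> "MzDiffTable":
        rows = pd.read_csv(path, sep="\t")
        return cls(rows=rows[["label", "delta_mz"]], tolerance=tolerance)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)
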