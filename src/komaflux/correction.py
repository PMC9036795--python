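"""Natural-abundance correction of GC-TOFMS isotopologue measurements.

Metabolites measured by GC-(CI)-TOFMS after two-step ethoxime/trimethylsilyl
derivatization carry, besides their carbon backbone, a cloud of derivatization
atoms (H, C, N, O, Si, S) whose natural heavy isotopes shift the measured mass
isotopologue pattern.  The raw peak areas ``A_raw`` over mass shifts m+0..m+K
relate to the carbon-backbone isotopologue abundances ``x`` (length n+1 for a
backbone of n carbons) through a convolution matrix ``M``::

    A_raw ~ M @ x

where column j of ``M`` is the isotope pattern of a fragment carrying exactly
j heavy backbone carbons.  Deconvolution is performed by nonnegative least
squares (matrix inversion can produce negative isotopologue fractions on noisy
data), and relative abundances are reported as

    RA_i [%] = 100 * A_i / sum_i A_i

over the corrected backbone areas.

A quality-control helper checks 50:50 ``12C/13C`` methanol-fed reference
extracts against the binomial(n, 1/2) ("Pascal's triangle") expectation.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import scipy.optimize
import scipy.stats

# Natural isotope abundances per element as mass-shift distributions
# (index = mass shift relative to the lightest isotope).  IUPAC values.
NATURAL_ABUNDANCE: dict[str, np.ndarray] = {
    "H": np.array([0.999885, 0.000115]),
    "C": np.array([0.9893, 0.0107]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
    "P": np.array([1.0]),
}

#: Natural fraction of 13C among carbon atoms.
NATURAL_13C = float(NATURAL_ABUNDANCE["C"][1])

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C11H28NO6PSi2`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


@dataclasses.dataclass
class FragmentSpec:
    """Derivatized fragment ion evaluated for one metabolite.

    ``elements`` counts every atom of the fragment ion including the backbone
    carbons; ``n_backbone_carbons`` of the C count belong to the metabolite
    backbone, the remainder stem from derivatization and are corrected for.
    """

    metabolite: str
    elements: dict[str, int]
    n_backbone_carbons: int
    retention_time: float | None = None
    adduct: str | None = None

    def __post_init__(self) -> None:
        if self.n_backbone_carbons < 1:
            raise ValueError("fragment must contain at least one backbone carbon")
        if self.elements.get("C", 0) < self.n_backbone_carbons:
            raise ValueError(
                f"{self.metabolite}: formula has {self.elements.get('C', 0)} C "
                f"but {self.n_backbone_carbons} backbone carbons claimed"
            )
        if any(v < 0 for v in self.elements.values()):
            raise ValueError("negative element count")

    @classmethod
    def from_formula(cls, metabolite: str, formula: str, n_backbone_carbons: int,
                     **kwargs) -> "FragmentSpec":
        return cls(metabolite, parse_formula(formula), n_backbone_carbons, **kwargs)


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution of a distribution (n >= 0)."""
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, dist)
    return out


def correction_matrix(frag: FragmentSpec, table: dict[str, np.ndarray] | None = None,
                      K: int | None = None) -> np.ndarray:
    """Build the (K+1) x (n+1) natural-abundance convolution matrix.

    Column j is the mass-shift pattern of the fragment with exactly j heavy
    backbone carbons: a j-shifted delta convolved with the natural isotope
    distributions of all non-backbone atoms (H, N, O, Si, S and the
    derivatization carbons).  K defaults to n_backbone_carbons + 8: fragment
    ions carrying several silicons spread appreciable isotope-pattern mass to
    high shifts, and the wider window keeps the truncated tail below 1e-4.
    """
    if table is None:
        table = NATURAL_ABUNDANCE
    n = frag.n_backbone_carbons
    if K is None:
        K = n + 8
    if K < n:
        raise ValueError("truncation length K must be >= n_backbone_carbons")
    base = np.array([1.0])
    for elem, count in frag.elements.items():
        n_atoms = count - n if elem == "C" else count
        if n_atoms == 0:
            continue
        if elem not in table:
            raise KeyError(f"element {elem} missing from natural-abundance table")
        base = np.convolve(base, _convolve_power(table[elem], n_atoms))
    M = np.zeros((K + 1, n + 1))
    for j in range(n + 1):
        col = np.zeros(K + 1)
        upto = min(len(base), K + 1 - j)
        col[j:j + upto] = base[:upto]
        M[:, j] = col
    return M


def relative_abundance(areas: np.ndarray) -> np.ndarray:
    """RA_i [%] = 100 * A_i / sum(A); requires a nonnegative, nonzero vector."""
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("negative peak area")
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total area")
    return 100.0 * areas / total


@dataclasses.dataclass
class CorrectedCID:
    """Carbon-backbone isotopologue distribution in percent, plus fit residual."""

    metabolite: str
    ra_percent: np.ndarray           # RA_0..RA_n, sums to 100
    areas: np.ndarray                # corrected backbone areas (NNLS solution)
    residual: float                  # ||M x - A_raw||_2

    @property
    def n_carbons(self) -> int:
        return len(self.ra_percent) - 1


def correct_cid(raw: np.ndarray, frag: FragmentSpec,
                table: dict[str, np.ndarray] | None = None,
                K: int | None = None) -> CorrectedCID:
    """Deconvolve raw areas to the carbon-backbone CID by NNLS."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("negative peak area")
    if raw.sum() <= 0:
        raise ValueError("zero total area")
    if K is None:
        K = len(raw) - 1
    M = correction_matrix(frag, table=table, K=K)
    if len(raw) < K + 1:
        raw = np.concatenate([raw, np.zeros(K + 1 - len(raw))])
    x, rnorm = scipy.optimize.nnls(M, raw[:K + 1])
    return CorrectedCID(frag.metabolite, relative_abundance(x), x, float(rnorm))


def pascal_expected(n: int) -> np.ndarray:
    """Expected CID (percent) for 50:50 12C/13C feeding: binomial(n, 1/2)."""
    return 100.0 * scipy.stats.binom.pmf(np.arange(n + 1), n, 0.5)


@dataclasses.dataclass
class QCReport:
    expected_percent: np.ndarray
    max_abs_deviation: float
    threshold: float
    passed: bool


def qc_pascal(cid_percent: np.ndarray, n: int, threshold: float = 5.0) -> QCReport:
    """Compare a measured CID against the Pascal's-triangle expectation.

    ``threshold`` is the maximum tolerated absolute deviation in percentage
    points for a pass.
    """
    cid_percent = np.asarray(cid_percent, dtype=float)
    if len(cid_percent) != n + 1:
        raise ValueError(f"CID has {len(cid_percent)} entries, expected {n + 1}")
    expected = pascal_expected(n)
    dev = float(np.max(np.abs(cid_percent - expected)))
    return QCReport(expected, dev, threshold, dev <= threshold)
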