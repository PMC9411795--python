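"""¹³C isotope tracing: mass isotopologue distributions, natural-abundance
correction, and the three-route model of N-acetylaspartate (NAA) labeling.

NAA is a six-carbon brain metabolite formed by condensation of acetyl-CoA
(2 carbons) and aspartate (4 carbons).  With ¹³C₆-glucose as tracer, label
enters NAA by three routes:

1. glucose → ¹³C₂-acetyl-CoA used directly for the acetyl moiety (NAA M+2),
2. glucose → ¹³C₂-acetyl-CoA → one oxidative TCA turn → M+2 oxaloacetate
   → M+2 aspartate (NAA M+2 via the aspartate moiety),
3. glucose → ¹³C₃-pyruvate → pyruvate-carboxylase (PC) carboxylation, which
   transfers all three labeled pyruvate carbons to oxaloacetate → M+3
   aspartate (NAA M+3).

M+1 aspartate (attributed to malic enzyme activity) is carried as a free
route parameter rather than modeled mechanistically.  The aspartate MID is
parameterized directly by its M+1/M+2/M+3 fractions; the acetyl-CoA pool is
a binary mixture of unlabeled and M+2 species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: natural abundance of ¹³C used for correction
P_C13: float = 0.0107

#: carbon counts of the metabolites handled by the route model
N_CARBON = {"glucose": 6, "aspartate": 4, "naa": 6, "acetyl": 2}

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MID:
    """Mass isotopologue distribution: fractions of M+0 … M+n species.

    M denotes the mass of the unlabeled metabolite; ``fractions[k]`` is the
    fractional abundance of the species carrying ``k`` heavy carbons.
    Fractions are validated to be non-negative and to sum to 1.
    """

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.ndim != 1 or frac.size < 2:
            raise ValueError("MID needs a 1-D vector of length n+1 >= 2")
        if np.any(frac < -1e-12):
            raise ValueError(f"negative isotopologue fraction in {self.metabolite}")
        frac = np.clip(frac, 0.0, None)
        if abs(frac.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"MID fractions of {self.metabolite} sum to {frac.sum():.6g}, not 1"
            )
        frac.setflags(write=False)
        object.__setattr__(self, "fractions", frac)

    @property
    def n(self) -> int:
        """Number of carbons (length of the vector minus one)."""
        return self.fractions.size - 1

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])


@dataclass(frozen=True)
class CorrectionMatrix:
    """Binomial ¹³C natural-abundance convolution matrix.

    ``matrix[j, i]`` is the probability that a tracer-labeled M+i species is
    observed at M+j because of natural ¹³C in its ``n - i`` unlabeled
    carbons: Binomial(n−i, p) evaluated at j−i.  Lower-triangular; p = 0
    gives the identity.
    """

    n: int
    p: float
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("carbon count n must be >= 1")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("natural abundance p must be in [0, 1)")
        size = self.n + 1
        j, i = np.indices((size, size))
        with np.errstate(divide="ignore"):
            mat = stats.binom.pmf(j - i, self.n - i, self.p)
        mat[j < i] = 0.0
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)


def correction_matrix(n: int, p: float = P_C13) -> CorrectionMatrix:
    """Build the natural-abundance correction matrix for an n-carbon metabolite."""
    return CorrectionMatrix(n=n, p=p)


def convolve_natural_abundance(true_fractions: np.ndarray, n: int,
                               p: float = P_C13) -> np.ndarray:
    """Forward model: observed pattern C·T produced by natural abundance."""
    C = correction_matrix(n, p).matrix
    return C @ np.asarray(true_fractions, dtype=float)


def correct_mid(raw_intensities: Sequence[float], n: int, p: float = P_C13,
                metabolite: str = "metabolite") -> tuple[MID, float]:
    """Remove natural-abundance ¹³C contributions from raw isotopologue intensities.

    Solves C·T = R by non-negative least squares (plain inversion can produce
    negative fractions on noisy data), clips at zero and renormalizes.

    Returns
    -------
    (MID, residual)
        The corrected distribution and the NNLS residual norm computed on the
        sum-normalized input (0 for noise-free data).
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.size != n + 1:
        raise ValueError(f"expected {n + 1} intensities for {n} carbons, got {raw.size}")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector cannot be corrected")
    observed = raw / total
    C = correction_matrix(n, p).matrix
    solution, residual = optimize.nnls(C, observed)
    solution = np.clip(solution, 0.0, None)
    if solution.sum() == 0:
        raise ValueError("natural-abundance correction produced an all-zero MID")
    solution /= solution.sum()
    return MID(metabolite, solution), float(residual)


@dataclass(frozen=True)
class RouteFractions:
    """Contributions of the labeling routes to NAA synthesis.

    acetyl_labeled
        Fraction of the acetyl-CoA pool that is M+2 (routes 1 and, through
        the TCA cycle, 2 share this precursor).
    asp_m1, asp_m2, asp_m3
        Aspartate M+1 (malic-enzyme), M+2 (oxidative TCA) and M+3
        (pyruvate-carboxylase) fractions.  The unlabeled remainder is
        ``asp_m0 = 1 - asp_m1 - asp_m2 - asp_m3``.
    """

    acetyl_labeled: float = 0.0
    asp_m1: float = 0.0
    asp_m2: float = 0.0
    asp_m3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("acetyl_labeled", "asp_m1", "asp_m2", "asp_m3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.asp_m0 < -1e-12:
            raise ValueError("aspartate route fractions sum to more than 1")

    @property
    def asp_m0(self) -> float:
        return 1.0 - self.asp_m1 - self.asp_m2 - self.asp_m3


def aspartate_mid_from_routes(rf: RouteFractions) -> MID:
    """Aspartate MID implied by the route fractions (4 carbons, M+4 unreachable).

    CO2 fixed by pyruvate carboxylase is treated as unlabeled, so no route
    produces M+4 aspartate.
    """
    return MID("aspartate",
               np.array([rf.asp_m0, rf.asp_m1, rf.asp_m2, rf.asp_m3, 0.0]))


def acetyl_mid_from_routes(rf: RouteFractions) -> MID:
    """Acetyl-CoA MID: binary mixture of unlabeled and M+2 species."""
    c2 = rf.acetyl_labeled
    return MID("acetyl-CoA", np.array([1.0 - c2, 0.0, c2]))


def simulate_naa_mid(rf: RouteFractions) -> MID:
    """NAA MID from the route model: convolution of the acetyl and aspartate MIDs.

    Because acetyl and aspartate moieties are condensed, NAA mass shifts add:
    NAA M+k = Σ acetyl M+i · aspartate M+(k−i).  With an unlabeled/M+2 acetyl
    pool and aspartate limited to M+0…M+3, NAA M+6 is unreachable.
    """
    acetyl = acetyl_mid_from_routes(rf)
    asp = aspartate_mid_from_routes(rf)
    naa = np.convolve(acetyl.fractions, asp.fractions)
    return MID("naa", naa)


def fractional_labeling(metabolite_mid: MID, serum_glucose_mid: MID) -> np.ndarray:
    """Isotopologue fractions normalized to the same animal's serum glucose M+6.

    Expressing tissue labeling relative to the circulating tracer enrichment
    makes animals with different glucose uptake comparable.
    """
    if serum_glucose_mid.n < 6:
        raise ValueError("serum glucose MID must cover M+0..M+6")
    m6 = serum_glucose_mid[6]
    if m6 <= 0:
        raise ValueError("serum glucose M+6 fraction is zero; "
                         "fractional labeling is undefined")
    return metabolite_mid.fractions / m6


def labeling_table(metabolite_mid: MID, serum_glucose_mid: MID, *,
                   group: str, fish: str | int) -> pd.DataFrame:
    """Per-isotopologue labeling results for one animal, as a tidy table."""
    fl = fractional_labeling(metabolite_mid, serum_glucose_mid)
    return pd.DataFrame({
        "metabolite": metabolite_mid.metabolite,
        "isotopologue": np.arange(metabolite_mid.n + 1),
        "corrected_fraction": metabolite_mid.fractions,
        "fractional_labeling": fl,
        "group": group,
        "fish": fish,
    })


def _naa_model_components(asp_fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NAA MID is linear in c2: (1−c2)·base + c2·shifted(base by 2)."""
    base = np.zeros(7)
    base[:5] = asp_fractions
    shifted = np.zeros(7)
    shifted[2:7] = asp_fractions
    return base, shifted


def infer_route_fractions(naa_mid: MID, aspartate_mid: MID | None = None,
                          ) -> tuple[RouteFractions, dict]:
    """Infer route contributions from corrected NAA (and aspartate) MIDs.

    With an aspartate MID, ``asp_m1..asp_m3`` are read off indices 1–3 and
    the acetyl-labeled fraction c2 is the [0, 1]-constrained least-squares
    solution of the route model against the observed NAA MID (closed form,
    since the model is linear in c2).  Without aspartate the problem is not
    identifiable — c2·a1 trades off against (1−c2)·a3 — so a best-effort
    bounded fit is returned with ``identifiable=False``.
    """
    if naa_mid.n != 6:
        raise ValueError("NAA MID must have 6 carbons")
    if aspartate_mid is not None:
        if aspartate_mid.n != 4:
            raise ValueError("aspartate MID must have 4 carbons")
        a1, a2, a3 = (aspartate_mid[1], aspartate_mid[2], aspartate_mid[3])
        asp = np.array([aspartate_mid[0], a1, a2, a3, aspartate_mid[4]])
        base, shifted = _naa_model_components(asp)
        direction = shifted - base
        # denom > 0 for any valid aspartate MID (a distribution cannot equal
        # its own 2-shift), so the closed-form projection is always defined
        denom = float(direction @ direction)
        c2 = float(np.clip((naa_mid.fractions - base) @ direction / denom, 0.0, 1.0))
        rf = RouteFractions(acetyl_labeled=c2, asp_m1=a1, asp_m2=a2, asp_m3=a3)
        residual = float(np.linalg.norm(
            simulate_naa_mid(rf).fractions - naa_mid.fractions))
        return rf, {"residual": residual, "identifiable": True}

    # aspartate missing: joint bounded fit, flagged non-identifiable
    def loss(theta: np.ndarray) -> float:
        c2, a1, a2, a3 = theta
        if a1 + a2 + a3 > 1.0:
            return 1e6 * (a1 + a2 + a3)
        rf = RouteFractions(c2, a1, a2, a3)
        return float(np.sum((simulate_naa_mid(rf).fractions
                             - naa_mid.fractions) ** 2))

    res = optimize.minimize(loss, x0=np.array([0.1, 0.05, 0.05, 0.05]),
                            bounds=[(0, 1)] * 4, method="L-BFGS-B")
    c2, a1, a2, a3 = res.x
    rf = RouteFractions(float(c2), float(a1), float(a2), float(a3))
    residual = float(np.linalg.norm(
        simulate_naa_mid(rf).fractions - naa_mid.fractions))
    warnings.warn("route inference without an aspartate MID is not identifiable "
                  "(acetyl and PC routes trade off)", stacklevel=2)
    return rf, {"residual": residual, "identifiable": False}


@dataclass(frozen=True)
class IsotopologueComparison:
    """Two-group comparison of fractional labeling for one isotopologue."""

    isotopologue: int
    mean_a: float
    mean_b: float
    direction: str          # "up" if group B exceeds group A
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_isotopologues(group_a: pd.DataFrame | Sequence[float],
                          group_b: pd.DataFrame | Sequence[float],
                          isotopologue: int,
                          value_column: str = "fractional_labeling",
                          ) -> IsotopologueComparison:
    """Two-tailed unpaired t-test on one isotopologue's fractional labeling.

    Accepts tidy labeling tables (filtered on ``isotopologue``) or plain
    per-fish value sequences.
    """
    def _values(g) -> np.ndarray:
        if isinstance(g, pd.DataFrame):
            return g.loc[g["isotopologue"] == isotopologue, value_column].to_numpy(float)
        return np.asarray(g, dtype=float)

    a, b = _values(group_a), _values(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 fish per group for a t-test")
    t, p = stats.ttest_ind(a, b)
    if np.isnan(p):  # zero variance in both groups
        t, p = 0.0, 1.0
    direction = "up" if b.mean() > a.mean() else ("down" if b.mean() < a.mean() else "none")
    return IsotopologueComparison(isotopologue, float(a.mean()), float(b.mean()),
                                  direction, float(t), float(p), a.size, b.size)
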