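"""Analytic two-state (telegraph) promoter model with CRISPRa/CRISPRi rate modulation.

The promoter toggles between an OFF state ``D_off`` and an ON state ``D_on``
with switching rates ``k_on`` and ``k_off``.  With first-order protein
turnover (lifetime ``tau``) the stationary expression mean and noise
(squared coefficient of variation) are::

    mean = C * k_on / (k_on + k_off)
    eta2 = 1/mean + (k_off/k_on) * 1 / (tau*(k_on + k_off) + 1)

``C`` is an expression-scale constant absorbing transcription, translation
and mRNA turnover.  A repressing dCas9 module lowers ``k_on`` (steric block
of RNAP assembly); an activating dCas9-omega module lowers ``k_off``
(stabilisation of assembled RNAP).  When both modules act on one promoter
their guide RNAs either compete for overlapping sites (same target strand;
competitive Michaelis-Menten inhibition) or attenuate each other through
complex-complex interaction (opposite strands).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InvalidKineticsError,
    InvalidSummaryError,
    NotMatchedError,
    ParameterDomainError,
)

__all__ = [
    "PromoterKinetics",
    "CrisprParams",
    "ContourGrid",
    "MatchedNoiseComparison",
    "mean_expression",
    "noise_expression",
    "apply_crisprar",
    "compare_noise_at_matched_mean",
    "contour_grid",
]


@dataclass(frozen=True)
class PromoterKinetics:
    """Switching rates and expression scale of one (possibly regulated) promoter.

    Parameters
    ----------
    k_on, k_off
        ON- and OFF-switching rates (per unit time).  ``k_on > 0`` and
        ``k_off >= 0``; ``k_off = 0`` is the constitutive (always-ON) limit.
    k_on_wt, k_off_wt
        Wild-type (unregulated) rates; both default to 1 so that regulated
        rates are fractions of the wild type.
    tau
        Protein lifetime (inverse first-order decay rate), in the same time
        units as the rates, so ``tau*(k_on+k_off)`` is dimensionless.
    C
        Expression scale: the mean of an always-ON promoter, in
        fluorescence-equivalent (or molecule-count) units.
    """

    k_on: float
    k_off: float
    k_on_wt: float = 1.0
    k_off_wt: float = 1.0
    tau: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_on > 0):
            raise InvalidKineticsError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise InvalidKineticsError(f"k_off must be >= 0, got {self.k_off}")
        if self.k_on + self.k_off <= 0:
            raise InvalidKineticsError("k_on + k_off must be positive")
        if not (self.tau > 0):
            raise InvalidKineticsError(f"tau must be > 0, got {self.tau}")
        if not (self.C > 0):
            raise InvalidKineticsError(f"C must be > 0, got {self.C}")

    @property
    def on_fraction(self) -> float:
        """Stationary probability of the ON state, k_on/(k_on+k_off)."""
        return self.k_on / (self.k_on + self.k_off)

    def with_rates(self, k_on: float, k_off: float) -> "PromoterKinetics":
        return replace(self, k_on=k_on, k_off=k_off)


@dataclass(frozen=True)
class CrisprParams:
    """Regulation strengths and binding/interaction constants of a CRISPRa/CRISPRi pair.

    ``k_r`` and ``k_a`` are the maximal fractional reductions of ``k_on``
    (repression) and ``k_off`` (activation); both are clamped to [0, 1]
    because larger values would drive a switching rate negative.
    ``K_ro``/``K_ao`` are half-saturation constants of the repressor and
    activator guide, ``K_i`` the competitive-inhibition constant used when
    the two guides target the same strand, and ``K_int1``/``K_int2`` the
    interaction constants (activator-on-repressor and repressor-on-activator)
    used when they target opposite strands.
    """

    k_r: float = 0.0
    k_a: float = 0.0
    K_ro: float = 0.01
    K_ao: float = 0.02
    K_i: float = 10.0
    K_int1: float = 0.5
    K_int2: float = 2.0

    def __post_init__(self) -> None:
        for name in ("K_ro", "K_ao", "K_i", "K_int1", "K_int2"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be >= 0")
        for name in ("k_r", "k_a"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterDomainError(f"{name} must be >= 0, got {v}")
            # clamp fractional strengths into the model's valid range
            object.__setattr__(self, name, min(float(v), 1.0))


def mean_expression(kin: PromoterKinetics) -> float:
    """Stationary expression mean, ``C * k_on / (k_on + k_off)``.

    Strictly increasing in ``k_on`` and strictly decreasing in ``k_off``;
    equals ``C`` for an always-ON promoter (``k_off = 0``).
    """
    total = kin.k_on + kin.k_off
    if total <= 0:
        raise InvalidKineticsError("k_on + k_off must be positive")
    return kin.C * kin.k_on / total


def noise_expression(kin: PromoterKinetics, mean: float | None = None) -> float:
    """Stationary expression noise eta^2 = sigma^2/mu^2.

    ``eta2 = 1/mean + (k_off/k_on) / (tau*(k_on+k_off) + 1)``: a Poisson-like
    term plus promoter-switching noise filtered by the protein lifetime.
    Reduces to ``1/mean`` in the constitutive limit ``k_off = 0``.

    ``mean`` defaults to :func:`mean_expression` of ``kin``.
    """
    if mean is None:
        mean = mean_expression(kin)
    if not (mean > 0):
        raise InvalidSummaryError(f"mean must be > 0, got {mean}")
    switching = (kin.k_off / kin.k_on) / (kin.tau * (kin.k_on + kin.k_off) + 1.0)
    return 1.0 / mean + switching


def _hill(conc: float, K: float) -> float:
    if conc == 0.0:
        return 0.0
    return conc / (K + conc)


def apply_crisprar(
    wt: PromoterKinetics,
    params: CrisprParams,
    conc_A: float,
    conc_R: float,
    strand_relation: str = "same",
) -> PromoterKinetics:
    """Modulate wild-type switching rates with a paired activator/repressor.

    ``k_on  = k_on_wt  * (1 - k_r * [R]/(K_r + [R]) * int1)``
    ``k_off = k_off_wt * (1 - k_a * [A]/(K_a + [A]) * int2)``

    Same-strand guides compete for overlapping binding sites
    (``K_r = K_ro*(1 + [A]/K_i)``, ``K_a = K_ao*(1 + [R]/K_i)``,
    ``int1 = int2 = 1``).  Opposite-strand guides attenuate each other
    (``int1 = 1/(1 + K_int1*[A])``, ``int2 = 1/(1 + K_int2*[R])`` with the
    unperturbed half-saturation constants).

    With both concentrations zero the wild-type kinetics are returned
    unchanged.
    """
    if conc_A < 0 or conc_R < 0:
        raise ParameterDomainError("sgRNA concentrations must be >= 0")
    if strand_relation not in ("same", "opposite"):
        raise ConfigurationError(
            f"strand_relation must be 'same' or 'opposite', got {strand_relation!r}"
        )

    if strand_relation == "same":
        K_r = params.K_ro * (1.0 + conc_A / params.K_i)
        K_a = params.K_ao * (1.0 + conc_R / params.K_i)
        int1 = int2 = 1.0
    else:
        K_r = params.K_ro
        K_a = params.K_ao
        int1 = 1.0 / (1.0 + params.K_int1 * conc_A)
        int2 = 1.0 / (1.0 + params.K_int2 * conc_R)

    k_on = wt.k_on_wt * (1.0 - params.k_r * _hill(conc_R, K_r) * int1)
    k_off = wt.k_off_wt * (1.0 - params.k_a * _hill(conc_A, K_a) * int2)
    if k_on <= 0:
        raise ParameterDomainError(f"modulated k_on = {k_on} is not positive")
    if k_off < 0:
        raise ParameterDomainError(f"modulated k_off = {k_off} is negative")
    return replace(wt, k_on=k_on, k_off=k_off)


@dataclass(frozen=True)
class MatchedNoiseComparison:
    """Noise ordering of two kinetics constrained to the same mean.

    At equal ``k_off/k_on`` ratio the means coincide and the noise
    difference is carried entirely by ``1/(tau*(k_on+k_off)+1)``:
    the promoter with the smaller total switching rate is noisier.
    ``noisier`` is 1 or 2 for the noisier input, 0 for a tie.
    """

    term1: float
    term2: float
    noisier: int
    ratio1: float = field(repr=False, default=float("nan"))
    ratio2: float = field(repr=False, default=float("nan"))


def compare_noise_at_matched_mean(
    kin1: PromoterKinetics,
    kin2: PromoterKinetics,
    ratio_tolerance: float = 1e-9,
) -> MatchedNoiseComparison:
    """Compare switching-noise terms of two mean-matched promoters.

    Requires ``k_off/k_on`` of the two inputs to agree within
    ``ratio_tolerance`` (relative); otherwise the means differ and the
    comparison is not meaningful for a pure noise ordering.
    """
    r1 = kin1.k_off / kin1.k_on
    r2 = kin2.k_off / kin2.k_on
    scale = max(abs(r1), abs(r2), 1e-300)
    if abs(r1 - r2) / scale > ratio_tolerance:
        raise NotMatchedError(
            f"k_off/k_on ratios differ ({r1:.6g} vs {r2:.6g}): means are not matched"
        )
    t1 = 1.0 / (kin1.tau * (kin1.k_on + kin1.k_off) + 1.0)
    t2 = 1.0 / (kin2.tau * (kin2.k_on + kin2.k_off) + 1.0)
    if np.isclose(t1, t2, rtol=1e-12, atol=0.0):
        noisier = 0
    else:
        noisier = 1 if t1 > t2 else 2
    return MatchedNoiseComparison(term1=t1, term2=t2, noisier=noisier, ratio1=r1, ratio2=r2)


@dataclass(frozen=True)
class ContourGrid:
    """Mean and noise surfaces over a (k_on, k_off) grid.

    ``mean_surface[i, j]`` and ``noise_surface[i, j]`` correspond to
    ``(k_on_values[i], k_off_values[j])``.  Iso-mean contours are the loci
    of constant ``k_on/k_off`` ratio.
    """

    k_on_values: np.ndarray
    k_off_values: np.ndarray
    mean_surface: np.ndarray
    noise_surface: np.ndarray
    tau: float = 1.0
    C: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns k_on, k_off, mean, noise."""
        kon, koff = np.meshgrid(self.k_on_values, self.k_off_values, indexing="ij")
        return pd.DataFrame(
            {
                "k_on": kon.ravel(),
                "k_off": koff.ravel(),
                "mean": self.mean_surface.ravel(),
                "noise": self.noise_surface.ravel(),
            }
        )

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ContourGrid":
        df = pd.read_csv(path_or_buf, sep="\t")
        k_on_values = np.unique(df["k_on"].to_numpy())
        k_off_values = np.unique(df["k_off"].to_numpy())
        shape = (k_on_values.size, k_off_values.size)
        order = df.sort_values(["k_on", "k_off"], kind="mergesort")
        return cls(
            k_on_values=k_on_values,
            k_off_values=k_off_values,
            mean_surface=order["mean"].to_numpy().reshape(shape),
            noise_surface=order["noise"].to_numpy().reshape(shape),
        )


def contour_grid(
    k_on_values,
    k_off_values,
    tau: float = 1.0,
    C: float = 1.0,
) -> ContourGrid:
    """Evaluate the analytic mean and noise surfaces on an ascending grid."""
    kon = np.asarray(k_on_values, dtype=float)
    koff = np.asarray(k_off_values, dtype=float)
    if kon.size == 0 or koff.size == 0:
        raise ConfigurationError("contour grid axes must be non-empty")
    if np.any(kon <= 0) or np.any(koff <= 0):
        raise ConfigurationError("contour grid values must be positive")
    if np.any(np.diff(kon) <= 0) or np.any(np.diff(koff) <= 0):
        raise ConfigurationError("contour grid axes must be strictly ascending")
    KON, KOFF = np.meshgrid(kon, koff, indexing="ij")
    total = KON + KOFF
    mean = C * KON / total
    noise = 1.0 / mean + (KOFF / KON) / (tau * total + 1.0)
    return ContourGrid(
        k_on_values=kon,
        k_off_values=koff,
        mean_surface=mean,
        noise_surface=noise,
        tau=tau,
        C=C,
    )
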