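"""Deterministic selection theory for a quantitative trait with a major gene.

Implements the standard truncation-selection machinery: selection intensity
``i = phi(z) / p`` for a selected proportion ``p``, expected polygenic
response ``dG = h2 * S`` from standardized selection differentials, and the
single-locus mass-selection approximation for allele-frequency change

    dp = i * p * q * alpha / sigma_P,    alpha = a + d (q - p),

iterated over generations with Hardy-Weinberg proportions re-imposed each
round.  The additive and dominance variances contributed by the locus are
``2 p q alpha^2`` and ``(2 p q d)^2``, and the response realised through the
locus is the change in its population mean genotypic value
``M(p) = p^2 v_CC + 2 p q v_CG + q^2 v_GG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocusModel",
    "TraitGenetics",
    "SelectionScheme",
    "selection_intensity",
    "expected_response",
    "delta_p",
    "allele_trajectory",
    "locus_variances",
    "mean_genotypic_value",
    "locus_response_split",
    "fold_change",
    "design_scheme",
]


@dataclass(frozen=True)
class LocusModel:
    """Biallelic locus: C-allele frequency and genotype values (GG, CG, CC)."""

    p: float
    values: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")

    @property
    def a(self) -> float:
        """Additive genotypic value, half the homozygote difference."""
        return 0.5 * (self.values[2] - self.values[0])

    @property
    def d(self) -> float:
        """Dominance deviation of the heterozygote from the homozygote mean."""
        return self.values[1] - 0.5 * (self.values[2] + self.values[0])

    @property
    def alpha(self) -> float:
        """Average effect of an allele substitution, a + d (q - p)."""
        return self.a + self.d * (1.0 - 2.0 * self.p)

    def at(self, p: float) -> "LocusModel":
        return LocusModel(p=p, values=self.values)


@dataclass(frozen=True)
class TraitGenetics:
    """Heritability and phenotypic variance of the selection criterion."""

    h2: float
    sigma2_P: float

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.sigma2_P <= 0:
            raise ValueError("sigma2_P must be positive")

    @property
    def sigma_P(self) -> float:
        return float(np.sqrt(self.sigma2_P))

    @property
    def sigma_A(self) -> float:
        return float(np.sqrt(self.h2 * self.sigma2_P))


def selection_intensity(proportion: float) -> float:
    """Standardized mean of the selected fraction under truncation, phi(z)/p."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError("selected proportion must lie in (0, 1]")
    if proportion == 1.0:
        return 0.0
    z = stats.norm.isf(proportion)
    return float(stats.norm.pdf(z) / proportion)


@dataclass(frozen=True)
class SelectionScheme:
    """Per-generation standardized selection intensities by parental sex.

    Built either from selected proportions (via :func:`selection_intensity`)
    or directly from realized standardized differentials.
    """

    i_male: tuple
    i_female: tuple

    @classmethod
    def from_proportions(cls, male, female) -> "SelectionScheme":
        return cls(
            i_male=tuple(selection_intensity(p) for p in male),
            i_female=tuple(selection_intensity(p) for p in female),
        )

    @classmethod
    def from_differentials(cls, male, female) -> "SelectionScheme":
        return cls(i_male=tuple(male), i_female=tuple(female))

    @property
    def generations(self) -> int:
        return len(self.i_male)

    def mean_intensity(self, t: int) -> float:
        """Sex-averaged intensity (both parents contribute half)."""
        return 0.5 * (self.i_male[t] + self.i_female[t])


def design_scheme(
    candidate_sizes=(4855, 946, 820, 526, 915, 1135, 707),
    sires: int = 25,
    dams: int = 50,
) -> SelectionScheme:
    """Selection intensities implied by the reference design.

    ``candidate_sizes`` are per-generation totals across both lines; each
    line and sex then contributes a quarter of the candidates, from which
    ``sires`` males and ``dams`` females are truncation-selected.
    """
    male, female = [], []
    for n in candidate_sizes:
        quarter = n / 4.0
        male.append(min(1.0, sires / quarter))
        female.append(min(1.0, dams / quarter))
    return SelectionScheme.from_proportions(male, female)


def expected_response(scheme: SelectionScheme, trait: TraitGenetics) -> pd.DataFrame:
    """Cumulative expected polygenic response per generation, dG = h2 i sigma_P."""
    rows = []
    cum = 0.0
    for t in range(scheme.generations):
        dg = trait.h2 * scheme.mean_intensity(t) * trait.sigma_P
        cum += dg
        rows.append({"generation": t + 1, "delta_G": dg, "cumulative": cum})
    return pd.DataFrame(rows)


def delta_p(locus: LocusModel, intensity: float, sigma_P: float) -> float:
    """One-generation change of the C-allele frequency under mass selection."""
    if sigma_P <= 0:
        raise ValueError("sigma_P must be positive")
    p = locus.p
    q = 1.0 - p
    dp = intensity * p * q * locus.alpha / sigma_P
    return float(np.clip(dp, -p, q))


def locus_variances(locus: LocusModel) -> tuple[float, float]:
    """(additive, dominance) variance contributed by the locus under HWE."""
    p, q = locus.p, 1.0 - locus.p
    va = 2.0 * p * q * locus.alpha**2
    vd = (2.0 * p * q * locus.d) ** 2
    return float(va), float(vd)


def mean_genotypic_value(locus: LocusModel) -> float:
    """Population mean contribution of the locus, M(p), under HWE."""
    p, q = locus.p, 1.0 - locus.p
    v_gg, v_cg, v_cc = locus.values
    return float(p * p * v_cc + 2.0 * p * q * v_cg + q * q * v_gg)


def allele_trajectory(
    locus: LocusModel,
    scheme: SelectionScheme,
    trait: TraitGenetics,
    generations: int | None = None,
    lines=("high", "low"),
) -> pd.DataFrame:
    """Expected allele-frequency path under divergent mass selection.

    Iterates :func:`delta_p` per generation (High ascending, Low descending),
    recomputing the average effect at the current frequency and re-imposing
    Hardy-Weinberg proportions; records the locus variances and the
    cumulative locus response (change in mean genotypic value) along the
    path.  ``sigma_P`` is held at its base value, as the approximation
    supplies no update rule.
    """
    generations = generations or scheme.generations
    rows = []
    for line in lines:
        sign = 1.0 if line == "high" else -1.0
        p = locus.p
        m0 = mean_genotypic_value(locus)
        cum_poly = 0.0
        for t in range(generations + 1):
            cur = locus.at(p)
            va, vd = locus_variances(cur)
            rows.append(
                {
                    "line": line,
                    "generation": t,
                    "p": p,
                    "var_a_locus": va,
                    "var_d_locus": vd,
                    "locus_response": mean_genotypic_value(cur) - m0,
                    "expected_polygenic": cum_poly,
                }
            )
            if t < generations:
                i = scheme.mean_intensity(min(t, scheme.generations - 1))
                p = p + sign * delta_p(cur, i, trait.sigma_P)
                p = float(np.clip(p, 0.0, 1.0))
                cum_poly += sign * trait.h2 * i * trait.sigma_P
    return pd.DataFrame(rows)


def locus_response_split(
    p0: float, p_t: float, locus: LocusModel, total_trend: float
) -> tuple[float, float]:
    """Split a realized genetic trend into locus and polygenic parts.

    The locus part is the change in the HWE mean genotypic value
    ``M(p_t) - M(p0)``; the polygenic part is the remainder, so the two
    always reconstruct the total exactly.
    """
    locus_part = mean_genotypic_value(locus.at(p_t)) - mean_genotypic_value(
        locus.at(p0)
    )
    return float(locus_part), float(total_trend - locus_part)


def fold_change(delta_log2_titer: float) -> float:
    """Linear-scale ratio corresponding to a log2-titer difference."""
    return float(2.0 ** delta_log2_titer)
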