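"""Closed-form population-genetic expectations for X vs autosome contrasts.

Covers Wright's effective-size formulas for X-linked and autosomal loci under
unequal breeder sex ratios, the expected piX/piA curve (optionally
standardized to an observed anchor), numeric inversion of that curve to an
operational sex ratio, the Miyata male-mutation-bias relation
k_X/k_A = (2/3)(2+alpha)/(1+alpha), and the ancestral-coalescence-time
adjustment of X/A divergence ratios.

The X0 karyotype studied here (males X1X2/0, both X chromosomes hemizygous in
males) behaves as standard X linkage, so the usual formulas apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class SexRatioModel:
    """Effective numbers of breeding males and females."""

    n_males: float
    n_females: float

    def __post_init__(self):
        if self.n_males <= 0 or self.n_females <= 0:
            raise ValueError("breeder counts must be positive")


@dataclass(frozen=True)
class CoalescenceContext:
    """Ancestral-population parameters for the divergence-time adjustment.

    n_ancestral : diploid autosomal effective size of the ancestral species
    t_gen       : species split time in generations
    ne_x_factor : Ne_X / Ne_A in the ancestor (0.75 at equal sex ratio)
    """

    n_ancestral: float
    t_gen: float
    ne_x_factor: float = 0.75

    def __post_init__(self):
        if min(self.n_ancestral, self.t_gen, self.ne_x_factor) <= 0:
            raise ValueError("all context parameters must be positive")


def ne_ratio(model: SexRatioModel) -> float:
    """Ne_X / Ne_A from Wright's formulas.

    Ne_X = 9 Nm Nf / (2 (2 Nm + Nf)), Ne_A = 4 Nm Nf / (Nm + Nf), giving
    9 (Nm + Nf) / (8 (2 Nm + Nf)): 0.75 at Nm = Nf, -> 9/8 as females
    dominate, -> 9/16 as males dominate.
    """
    nm, nf = model.n_males, model.n_females
    return 9.0 * (nm + nf) / (8.0 * (2.0 * nm + nf))


def expected_pix_pia(model: SexRatioModel, standardization: float = 1.0) -> float:
    """Expected piX/piA: the neutral Ne ratio times a standardization factor.

    The factor anchors the curve to an observed ratio in a reference species
    (e.g. observed/0.75 for a species with an equal sex ratio), absorbing
    sex-ratio-independent effects such as a lower X mutation rate or linked
    selection.
    """
    if standardization <= 0:
        raise ValueError("standardization factor must be positive")
    return ne_ratio(model) * standardization


def invert_sex_ratio(
    target_ratio: float, standardization: float = 1.0, tol: float = 1e-6
) -> float:
    """Female-to-male breeder ratio Nf/Nm at which the standardized expected
    piX/piA equals ``target_ratio``.

    The curve is strictly increasing in Nf/Nm with range
    (9/16, 9/8) x standardization; targets outside it raise ValueError.
    """
    lo_f, hi_f = 1e-9, 1e9

    def f(log_ratio: float) -> float:
        r = float(np.exp(log_ratio))
        return expected_pix_pia(SexRatioModel(1.0, r), standardization) - target_ratio

    lo = float(np.log(lo_f))
    hi = float(np.log(hi_f))
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        a = 9.0 / 16.0 * standardization
        b = 9.0 / 8.0 * standardization
        raise ValueError(
            f"target {target_ratio} outside the attainable range ({a:.6g}, {b:.6g})"
        )
    root = brentq(f, lo, hi, xtol=tol)
    return float(np.exp(root))


def miyata_alpha(k_ratio: float) -> float:
    """Male-to-female substitution-rate ratio from the X/A divergence ratio.

    Inverts k = (2/3)(2+alpha)/(1+alpha): alpha = (4 - 3k)/(3k - 2).
    Valid for k in (2/3, 4/3]; k -> 2/3 corresponds to alpha -> infinity and
    k > 4/3 would imply a negative alpha.
    """
    if k_ratio <= 2.0 / 3.0:
        raise ValueError("k must exceed 2/3 (alpha would be infinite or negative)")
    if k_ratio > 4.0 / 3.0:
        raise ValueError("k above 4/3 implies a negative male-to-female ratio")
    return (4.0 - 3.0 * k_ratio) / (3.0 * k_ratio - 2.0)


def miyata_k(alpha_mf: float) -> float:
    """Forward Miyata relation: expected k_X/k_A for male bias ``alpha_mf``."""
    if alpha_mf < 0:
        raise ValueError("alpha must be nonnegative")
    return (2.0 / 3.0) * (2.0 + alpha_mf) / (1.0 + alpha_mf)


def coalescence_time_ratio(ctx: CoalescenceContext) -> float:
    """Expected X/A ratio of total divergence time between two species.

    Total time on each compartment is split time plus the expected ancestral
    coalescence time 2 Ne (in generations); X uses 2 ne_x_factor N_A:

        (T + 2 f N_A) / (T + 2 N_A).
    """
    t, na, f = ctx.t_gen, ctx.n_ancestral, ctx.ne_x_factor
    return (t + 2.0 * f * na) / (t + 2.0 * na)


def adjust_divergence_ratio(raw_ratio: float, time_ratio: float) -> float:
    """Divide out the coalescence-time difference from a raw X/A divergence
    ratio, leaving the mutation-rate ratio k."""
    if not 0.0 < time_ratio <= 1.0:
        raise ValueError("time ratio must lie in (0, 1]")
    if raw_ratio < 0:
        raise ValueError("divergence ratio must be nonnegative")
    return raw_ratio / time_ratio


def pix_pia_curve(
    female_male_ratios: np.ndarray, standardization: float = 1.0
) -> np.ndarray:
    """Standardized expected piX/piA over a grid of Nf/Nm values."""
    r = np.asarray(female_male_ratios, dtype=float)
    return 9.0 * (1.0 + r) / (8.0 * (2.0 + r)) * standardization
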