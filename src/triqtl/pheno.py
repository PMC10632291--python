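"""Phenotype-only estimation of total three-way epistasis.

For ``n`` homozygous lines with mean phenotypes L_1..L_n, the total
additive x additive x additive (aaa) epistasis effect is estimated as

    aaa_p = (L_max + L_min) / 2  -  L_bar

i.e. the midrange of the line means minus their grand mean. In a fully
homozygous population the extreme lines accumulate, respectively, all
increasing and all decreasing alleles; under a purely additive (and
pairwise-epistatic) model the midrange equals the grand mean, so a nonzero
aaa_p indicates odd-order (three-way) epistasis.

The significance test treats aaa_p as a single-degree-of-freedom contrast
over line means (coefficients 1/2 - 1/n on the extreme lines, -1/n
elsewhere) against the pooled within-line replicate mean square. Note that
because the extreme lines are chosen from the data, this F test is
conservative under a no-signal null.

A Wright-type estimate of the number of effective factors (segregating
loci) is also provided: k = range^2 / (8 Vg) with Vg the genetic variance
of line means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import PhenotypeSet


@dataclass
class AaaPhenotypic:
    """Phenotypic total three-way epistasis estimate and its test."""

    estimate: float
    L_min: float
    L_max: float
    grand_mean: float
    n_lines: int
    F_stat: float | None = None
    p_value: float | None = None


@dataclass
class EffectiveFactors:
    k_hat: float
    k_rounded: int
    genetic_variance: float


def estimate_aaa_p(line_means) -> AaaPhenotypic:
    """Total aaa effect from line means: (max + min)/2 - mean."""
    means = np.asarray(line_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 line means")
    if np.isnan(means).any():
        raise ValueError("line means contain NaN")
    L_min, L_max = float(means.min()), float(means.max())
    grand = float(means.mean())
    return AaaPhenotypic(
        estimate=0.5 * (L_max + L_min) - grand,
        L_min=L_min, L_max=L_max, grand_mean=grand, n_lines=means.size,
    )


def _contrast(means: np.ndarray) -> np.ndarray:
    """Contrast coefficients of the aaa_p estimator.

    First line in input order wins ties for min/max; the estimate itself
    does not depend on which tied line is picked.
    """
    n = means.size
    c = np.full(n, -1.0 / n)
    c[int(means.argmax())] += 0.5
    c[int(means.argmin())] += 0.5
    return c


def test_aaa_p(pheno: PhenotypeSet) -> AaaPhenotypic:
    """aaa_p with its contrast F test against pooled within-line error.

    F = MS_aaa / MS_e with MS_aaa = est^2 / sum(c_i^2 / r_i) on 1 df and
    MS_e the pooled replicate mean square. Requires at least one line with
    >= 2 replicates.
    """
    means = pheno.line_means()
    reps = pheno.replicate_counts(means.index).to_numpy(dtype=float)
    m = means.to_numpy(dtype=float)
    result = estimate_aaa_p(m)

    ms_e, df_e = pheno.pooled_error()
    c = _contrast(m)
    ss = result.estimate ** 2 / float(np.sum(c ** 2 / reps))
    if ms_e <= 0:
        # replicates are exactly equal within every line: no error scale
        f = np.inf if ss > 0 else 0.0
    else:
        f = ss / ms_e
    result.F_stat = float(f)
    result.p_value = float(stats.f.sf(f, 1, df_e)) if np.isfinite(f) else 0.0
    if result.estimate == 0.0:
        result.F_stat, result.p_value = 0.0, 1.0
    return result


def effective_factors(line_means, error_variance: float = 0.0,
                      n_reps: float = 1.0) -> EffectiveFactors:
    """Wright-type number of effective factors: range^2 / (8 Vg).

    ``Vg`` is the variance of line means minus ``error_variance / n_reps``,
    floored at 0; ``k = 0`` when Vg is 0. Scale-free: multiplying all
    phenotypes by a constant leaves k unchanged.
    """
    means = np.asarray(line_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 line means")
    if error_variance < 0 or n_reps <= 0:
        raise ValueError("error_variance must be >= 0 and n_reps > 0")
    vg = max(float(np.var(means, ddof=1)) - error_variance / n_reps, 0.0)
    if vg == 0.0:
        return EffectiveFactors(0.0, 0, 0.0)
    rng = float(means.max() - means.min())
    k = rng ** 2 / (8.0 * vg)
    return EffectiveFactors(k, max(int(round(k)), 1) if k > 0 else 0, vg)
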