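"""Flanking-marker imputation of missing genotypes.

A doubled-haploid gamete follows a two-state (+1/-1) Markov chain along each
linkage group: between two loci at recombination fraction ``r`` the state
flips with probability ``r``. A missing genotype is replaced by the
conditional expectation of the +/-1 state given the nearest non-missing
flanking markers of the same line and linkage group:

    P(x = s | left=a, right=b)  propto  P(a -> s over r1) * P(s -> b over r2)

where r1, r2 are the recombination fractions of the left and right legs.
With a single informative flank the single-leg conditional is used, and with
no informative flank in the group the expectation is 0.

Map distances are converted to recombination fractions with the Haldane
(no-interference) map function by default; Kosambi is selectable.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import GenotypeMatrix, LinkageMap

logger = logging.getLogger("triqtl")

MAP_FUNCTIONS = ("haldane", "kosambi")


def recomb_fraction(d_cM, model: str = "haldane"):
    """Recombination fraction for a map distance ``d_cM`` (centimorgans).

    Haldane: r = (1 - exp(-2d/100)) / 2;  Kosambi: r = tanh(2d/100) / 2.
    Both satisfy r(0)=0 and r -> 0.5 as d -> infinity.
    """
    d = np.asarray(d_cM, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be nonnegative")
    m = d / 100.0  # Morgans
    if model == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * m))
    elif model == "kosambi":
        r = 0.5 * np.tanh(2.0 * m)
    else:
        raise ValueError(f"unknown map function {model!r}; choose from {MAP_FUNCTIONS}")
    return r if r.ndim else float(r)


def _transition(state: float, r: float) -> tuple[float, float]:
    """P(next=+1), P(next=-1) one leg away from ``state`` (+1 or -1)."""
    if state > 0:
        return 1.0 - r, r
    return r, 1.0 - r


def expected_genotype(left: float | None, r1: float | None,
                      right: float | None, r2: float | None) -> float:
    """Conditional expectation of a +/-1 genotype given its flanks.

    ``left``/``right`` are the flanking +/-1 states (None when absent),
    ``r1``/``r2`` the recombination fractions of the corresponding legs.
    """
    if left is None and right is None:
        return 0.0
    if right is None:
        p_plus, p_minus = _transition(left, r1)
    elif left is None:
        # chain is reversible with uniform start: condition on the right flank
        p_plus, p_minus = _transition(right, r2)
    else:
        lp, lm = _transition(left, r1)       # P(x=+1|a), P(x=-1|a)
        tp, tm = _transition(right, r2)      # treat as P(x -> b): symmetric in sign of b
        p_plus = lp * tp
        p_minus = lm * tm
        tot = p_plus + p_minus
        if tot == 0.0:  # contradictory flanks at r=0; fall back to no information
            return 0.0
        p_plus, p_minus = p_plus / tot, p_minus / tot
    return p_plus - p_minus


def impute_flanking(g: GenotypeMatrix, linkage_map: LinkageMap,
                    model: str = "haldane", round_calls: bool = False) -> GenotypeMatrix:
    """Impute every missing genotype from its flanking markers.

    Imputed entries are left real-valued in [-1, +1] (conditional
    expectations) unless ``round_calls``, which rounds to the sign
    (ties -> +1). Non-missing entries are never modified. Markers absent
    from the map raise; markers on the map but placed in a group with no
    informative flank for a line are filled with 0.
    """
    mapped = set(linkage_map.table["marker_id"])
    unmapped = [m for m in g.marker_ids if m not in mapped]
    if unmapped:
        raise KeyError(f"markers missing from the linkage map: {unmapped[:5]}"
                       + ("..." if len(unmapped) > 5 else ""))

    values = g.values.copy()
    col_of = {m: j for j, m in enumerate(g.marker_ids)}

    for group in linkage_map.groups:
        markers = [m for m in linkage_map.markers_in_group(group) if m in col_of]
        if not markers:
            continue
        cols = np.array([col_of[m] for m in markers])
        pos = np.array([linkage_map.position(m) for m in markers])
        block = g.values[:, cols]  # raw values: flanks are raw observations only
        miss_rows, miss_cols = np.nonzero(np.isnan(block))
        for i, k in zip(miss_rows, miss_cols):
            row = block[i]
            left = right = None
            r1 = r2 = None
            obs = np.flatnonzero(~np.isnan(row))
            lo = obs[obs < k]
            hi = obs[obs > k]
            if lo.size:
                j = lo[-1]
                left = row[j]
                r1 = recomb_fraction(pos[k] - pos[j], model)
            if hi.size:
                j = hi[0]
                right = row[j]
                r2 = recomb_fraction(pos[j] - pos[k], model)
            values[i, cols[k]] = expected_genotype(left, r1, right, r2)

    if round_calls:
        was_missing = np.isnan(g.values)
        calls = np.where(values[was_missing] >= 0, 1.0, -1.0)
        values[was_missing] = calls

    n_imputed = g.n_missing
    if n_imputed:
        logger.info("imputed %d missing genotype entries (%s map function)",
                    n_imputed, model)
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), values)
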