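"""Linear-model design assembly: intercept, additive, pair and triple columns.

The genotype regression model for line means is

    y = 1*mu + X*beta + Z*gamma + W*delta + e

with X the additive +/-1 marker columns, Z columns the elementwise products
of marker pairs (additive x additive epistasis) and W columns the products
of marker triples (additive x additive x additive). Interaction columns are
built only over a designated subset of the additive markers — in the full
pipeline, the loci with significant additive effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import GenotypeMatrix

INTERCEPT = ("intercept",)

Term = tuple  # ("intercept",) | ("add", m) | ("pair", m1, m2) | ("triple", m1, m2, m3)


def term_label(term: Term) -> str:
    if term == INTERCEPT:
        return "intercept"
    return term[0] + "(" + ":".join(str(m) for m in term[1:]) + ")"


@dataclass
class ModelDesign:
    """Design matrix ``G = [1 X Z W]`` with per-column term provenance."""

    G: np.ndarray
    terms: list[Term]

    def __post_init__(self) -> None:
        if self.G.shape[1] != len(self.terms):
            raise ValueError("design width does not match term list")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in design")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def columns_of(self, kind: str) -> list[int]:
        return [j for j, t in enumerate(self.terms) if t[0] == kind]

    def subset(self, indices) -> "ModelDesign":
        idx = list(indices)
        return ModelDesign(self.G[:, idx], [self.terms[j] for j in idx])


def build_design(g: GenotypeMatrix, additive_markers,
                 interaction_source=None, max_order: int = 3) -> ModelDesign:
    """Assemble ``[1 X Z W]`` for the given markers.

    ``additive_markers`` (in the order given, typically map order) become
    the X columns; pairs and triples are formed over ``interaction_source``
    (default: all additive markers; must be a subset of them) in
    lexicographic order of their positions in the additive list. Each
    interaction stores its markers sorted by that order, so a triple is
    invariant under permutation of its three markers and no marker is ever
    paired with itself.
    """
    additive_markers = list(additive_markers)
    if interaction_source is None:
        interaction_source = additive_markers
    interaction_source = list(interaction_source)
    extra = [m for m in interaction_source if m not in additive_markers]
    if extra:
        raise ValueError(f"interaction markers not among additive markers: {extra}")
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")

    if np.isnan(g.values).any():
        raise ValueError("genotypes contain missing values; impute first")

    n = g.n_lines
    cols = [np.ones(n)]
    terms: list[Term] = [INTERCEPT]
    X = {m: g.column(m) for m in additive_markers}
    for m in additive_markers:
        cols.append(X[m])
        terms.append(("add", m))
    # interactions in the order markers appear in the additive list
    order = {m: i for i, m in enumerate(additive_markers)}
    src = sorted(interaction_source, key=order.__getitem__)
    if max_order >= 2:
        for m1, m2 in combinations(src, 2):
            cols.append(X[m1] * X[m2])
            terms.append(("pair", m1, m2))
    if max_order >= 3:
        for m1, m2, m3 in combinations(src, 3):
            cols.append(X[m1] * X[m2] * X[m3])
            terms.append(("triple", m1, m2, m3))
    return ModelDesign(np.column_stack(cols), terms)


def check_full_rank(design: ModelDesign, tol: float = 1e-8):
    """Numerical rank check with greedy identification of aliased columns.

    Walks the columns in term order, keeping each column that increases the
    rank of the kept set (singular-value tolerance ``tol`` relative to the
    largest); returns ``(is_full_rank, aliased_terms)`` where the aliased
    terms are those a fit must drop.
    """
    G = design.G
    kept: list[int] = []
    aliased: list[Term] = []
    for j in range(G.shape[1]):
        trial = G[:, kept + [j]]
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] > tol * max(s[0], 1.0):
            kept.append(j)
        else:
            aliased.append(design.terms[j])
    return len(aliased) == 0, aliased


def drop_aliased(design: ModelDesign, tol: float = 1e-8) -> ModelDesign:
    """Return the design with aliased columns removed (greedy, term order)."""
    ok, aliased = check_full_rank(design, tol)
    if ok:
        return design
    bad = set(aliased)
    keep = [j for j, t in enumerate(design.terms) if t not in bad]
    return design.subset(keep)
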