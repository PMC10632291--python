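"""Stepwise-AIC marker selection for the epistasis regression model.

Selection runs in three stages on the line-mean response:

1. within each linkage group, bidirectional stepwise selection by AIC over
   that group's additive marker columns, then a t-test filter on the
   selected additive coefficients at ``alpha_step`` (Bonferroni-corrected
   over the group's candidate count by default);
2. the survivors of all groups are pooled and the same stepwise + filter is
   repeated over the pooled set;
3. pair and triple product columns are formed over the surviving additive
   markers (interactions are allowed only at loci with significant additive
   effects) and stepwise AIC runs over the interaction terms with the
   additive terms protected in the model; retained triples must additionally
   have coefficient p < 0.001.

All steps are deterministic: candidates are scanned in term order and the
lowest-index term wins AIC ties. Selection is unweighted; the weighted fit
is applied to the already selected model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ModelDesign, Term, build_design, drop_aliased
from .io import GenotypeMatrix, LinkageMap
from .regress import fit_unweighted

_LOG_COLUMNS = ["stage", "group", "action", "term", "aic_before", "aic_after", "p_value"]


@dataclass
class SelectionConfig:
    """Knobs of the selection protocol."""

    alpha_step: float = 0.001       # significance level for stages 1-2
    bonferroni: bool = True         # divide alpha by the stage's candidate count
    alpha_triple: float = 0.001     # flat threshold for retained triples
    max_additive: int | None = None
    hierarchical: bool = False      # restrict triples to significant pairs

    def __post_init__(self) -> None:
        if not 0 < self.alpha_step <= 1:
            raise ValueError("alpha_step must be in (0, 1]")

    def threshold(self, n_candidates: int) -> float:
        if self.bonferroni and n_candidates > 0:
            return self.alpha_step / n_candidates
        return self.alpha_step


@dataclass
class SelectedModel:
    """Outcome of the three-stage selection."""

    additive_markers: list
    retained_pairs: list[Term] = field(default_factory=list)
    retained_triples: list[Term] = field(default_factory=list)
    selection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_LOG_COLUMNS))

    @property
    def n_qtls(self) -> int:
        return len(self.additive_markers)

    def to_dict(self) -> dict:
        return {
            "additive_markers": list(self.additive_markers),
            "retained_pairs": [list(t[1:]) for t in self.retained_pairs],
            "retained_triples": [list(t[1:]) for t in self.retained_triples],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectedModel":
        return cls(
            additive_markers=list(d["additive_markers"]),
            retained_pairs=[("pair", *p) for p in d.get("retained_pairs", [])],
            retained_triples=[("triple", *t) for t in d.get("retained_triples", [])],
        )


def _rss(A: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size == 1:
        return float(res[0])
    r = y - A @ coef
    return float(r @ r)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian AIC up to a constant: n*log(RSS/n) + 2k
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def stepwise_aic(y, candidate_cols: np.ndarray, forced_cols: np.ndarray | None = None,
                 direction: str = "both"):
    """Bidirectional greedy AIC selection over candidate columns.

    ``forced_cols`` (an n x f matrix, typically the intercept and any
    protected terms) are always in the model and never removed. Returns
    ``(selected, log)`` with ``selected`` the candidate column indices in
    selection order and ``log`` a list of ``(action, index, aic)`` moves.
    AIC = n*log(RSS/n) + 2k; ties go to the lowest candidate index.
    """
    if direction not in ("both", "forward"):
        raise ValueError("direction must be 'both' or 'forward'")
    y = np.asarray(y, dtype=float)
    n = y.size
    if candidate_cols.size == 0:
        return [], []
    if np.ptp(y) == 0.0:
        return [], []
    forced = (np.ones((n, 1)) if forced_cols is None
              else np.asarray(forced_cols, dtype=float))
    n_forced = forced.shape[1]
    n_cand = candidate_cols.shape[1]
    # floor the RSS at a relative tolerance: once the fit is numerically
    # perfect, further columns must not look like improvements
    floor = 1e-12 * float(y @ y + 1.0)

    selected: list[int] = []
    log: list[tuple] = []
    current = _aic(max(_rss(forced, y), floor), n, n_forced)

    while True:
        best_action = None  # (aic, kind, idx)
        k_now = n_forced + len(selected)
        # forward moves
        if k_now + 1 < n:
            for j in range(n_cand):
                if j in selected:
                    continue
                A = np.column_stack([forced] + [candidate_cols[:, s] for s in selected]
                                    + [candidate_cols[:, j]])
                aic = _aic(max(_rss(A, y), floor), n, k_now + 1)
                if best_action is None or aic < best_action[0] - 1e-12:
                    best_action = (aic, "add", j)
        # backward moves
        if direction == "both":
            for j in selected:
                rest = [s for s in selected if s != j]
                A = np.column_stack([forced] + [candidate_cols[:, s] for s in rest])
                aic = _aic(max(_rss(A, y), floor), n, k_now - 1)
                if best_action is None or aic < best_action[0] - 1e-12:
                    best_action = (aic, "remove", j)
        if best_action is None or best_action[0] >= current - 1e-10:
            break
        aic, kind, j = best_action
        if kind == "add":
            selected.append(j)
        else:
            selected.remove(j)
        log.append((kind, j, aic))
        current = aic
    return selected, log


def _additive_stage(y, g: GenotypeMatrix, markers: Sequence, stage: str, group,
                    cfg: SelectionConfig, log_rows: list) -> list:
    """One stepwise + significance-filter pass over additive candidates."""
    markers = list(markers)
    if not markers:
        return []
    cols = np.column_stack([g.column(m) for m in markers])
    selected, moves = stepwise_aic(y, cols, None, "both")
    for kind, j, aic in moves:
        log_rows.append((stage, group, kind, ("add", markers[j]), np.nan, aic, np.nan))
    if not selected:
        return []
    kept = [markers[j] for j in selected]
    thr = cfg.threshold(len(markers))
    # backward elimination at the threshold: correlated co-selected markers
    # share signal, so refit after each single drop rather than cutting all
    # non-significant coefficients at once
    while kept:
        design = build_design(g, kept, interaction_source=[], max_order=1)
        pruned = drop_aliased(design)
        for t in set(design.terms) - set(pruned.terms):
            log_rows.append((stage, group, "drop_aliased", t, np.nan, np.nan, np.nan))
            kept.remove(t[1])
        fit = fit_unweighted(y, pruned)
        tests = fit.coefficient_tests().set_index("term")
        p = tests.loc[[("add", m) for m in kept], "p"].astype(float)
        worst = int(np.argmax(p.to_numpy()))
        if p.iloc[worst] < thr:
            break
        term = ("add", kept[worst])
        log_rows.append((stage, group, "drop_nonsig", term, np.nan, np.nan,
                         float(p.iloc[worst])))
        kept.pop(worst)
    return kept


def select_markers(y, g: GenotypeMatrix, linkage_map: LinkageMap,
                   cfg: SelectionConfig | None = None) -> SelectedModel:
    """Three-stage selection of additive markers and their interactions."""
    cfg = cfg or SelectionConfig()
    y = np.asarray(y, dtype=float)
    if y.size != g.n_lines:
        raise ValueError("y must have one mean per genotype line")
    if np.isnan(g.values).any():
        raise ValueError("genotypes contain missing values; impute first")

    log_rows: list[tuple] = []

    # stage 1: per linkage group
    survivors: list = []
    present = set(g.marker_ids)
    for group in linkage_map.groups:
        markers = [m for m in linkage_map.markers_in_group(group) if m in present]
        survivors.extend(_additive_stage(y, g, markers, "group", group, cfg, log_rows))

    # stage 2: pooled
    additive = _additive_stage(y, g, survivors, "pooled", "all", cfg, log_rows)

    if cfg.max_additive is not None and len(additive) > cfg.max_additive:
        design = build_design(g, additive, interaction_source=[], max_order=1)
        tests = fit_unweighted(y, design).coefficient_tests().set_index("term")
        ranked = sorted(additive, key=lambda m: float(tests.loc[[("add", m)], "p"].iloc[0]))
        for m in ranked[cfg.max_additive:]:
            log_rows.append(("pooled", "all", "drop_cap", ("add", m), np.nan, np.nan, np.nan))
        capped = set(ranked[:cfg.max_additive])
        additive = [m for m in additive if m in capped]

    model = SelectedModel(additive_markers=additive)

    # stage 3: interactions over the surviving additive markers
    if len(additive) >= 2:
        full = build_design(g, additive, interaction_source=additive, max_order=3)
        inter_idx = full.columns_of("pair") + full.columns_of("triple")
        if cfg.hierarchical:
            pairs_only = [j for j in inter_idx if full.terms[j][0] == "pair"]
            model_pairs = _interaction_stage(y, full, pairs_only, cfg, log_rows)
            sig_pairs = {t[1:] for t in model_pairs}
            allowed_triples = [
                j for j in full.columns_of("triple")
                if all(p in sig_pairs for p in
                       [(full.terms[j][1], full.terms[j][2]),
                        (full.terms[j][1], full.terms[j][3]),
                        (full.terms[j][2], full.terms[j][3])])]
            retained = model_pairs + _interaction_stage(
                y, full, allowed_triples, cfg, log_rows,
                protected=[full.terms.index(t) for t in model_pairs])
        else:
            retained = _interaction_stage(y, full, inter_idx, cfg, log_rows)
        pairs = [t for t in retained if t[0] == "pair"]
        triples = [t for t in retained if t[0] == "triple"]
        # triples must be individually significant at the flat threshold
        if triples:
            keep_terms = ([("intercept",)] + [("add", m) for m in additive]
                          + pairs + triples)
            sub = full.subset([full.terms.index(t) for t in keep_terms])
            sub = drop_aliased(sub)
            tests = fit_unweighted(y, sub).coefficient_tests().set_index("term")
            sig = []
            for t in triples:
                if t not in sub.terms:
                    log_rows.append(("interaction", "all", "drop_aliased", t,
                                     np.nan, np.nan, np.nan))
                    continue
                p = float(tests.loc[[t], "p"].iloc[0])
                if p < cfg.alpha_triple:
                    sig.append(t)
                else:
                    log_rows.append(("interaction", "all", "drop_nonsig", t,
                                     np.nan, np.nan, p))
            triples = sig
        model.retained_pairs = pairs
        model.retained_triples = triples

    model.selection_log = pd.DataFrame(log_rows, columns=_LOG_COLUMNS)
    return model


def _interaction_stage(y, full: ModelDesign, candidate_idx: list[int],
                       cfg: SelectionConfig, log_rows: list,
                       protected: list[int] | None = None) -> list[Term]:
    """Stepwise AIC over interaction columns with additive terms protected."""
    if not candidate_idx:
        return []
    base_idx = [0] + full.columns_of("add") + (protected or [])
    forced = full.G[:, base_idx]
    cand = full.G[:, candidate_idx]
    selected, moves = stepwise_aic(y, cand, forced, "both")
    for kind, j, aic in moves:
        log_rows.append(("interaction", "all", kind, full.terms[candidate_idx[j]],
                         np.nan, aic, np.nan))
    return [full.terms[candidate_idx[j]] for j in selected]
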