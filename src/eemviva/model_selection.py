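"""Choosing the number of PARAFAC components.

Two complementary diagnostics drive the choice:

* a residual scan — one fit per candidate component number, recording the
  residual sum of squares, explained variance and core consistency; the
  correct model order is where extra components stop adding information;
* split-half validation — the samples are divided into two halves (by cell
  line in the study design) and models fitted independently on each; at
  the correct component number both halves recover the same emission and
  excitation loadings, quantified by the Tucker congruence of optimally
  matched components.

The selection rule returns the largest component number that passes
split-half in both spectral modes and still adds explained variance above
a noise-floor tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EEMCube
from .parafac import congruence_matrix, fit_parafac, match_components

logger = logging.getLogger(__name__)

#: Lighter fit options used for the per-F scans (selection needs stable
#: loadings, not machine-precision convergence).
SCAN_FIT_OPTIONS = dict(n_starts=3, tol=1e-7, max_iter=800)


@dataclass
class SplitHalfResult:
    """Per-F split-half congruence diagnostics for one two-way split."""

    split_spec: str
    half_sizes: tuple[int, int]
    F_range: list[int]
    em_congruences: dict[int, np.ndarray] = field(default_factory=dict)
    ex_congruences: dict[int, np.ndarray] = field(default_factory=dict)
    passed: dict[int, bool] = field(default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)
    threshold: float = 0.95

    def min_congruence(self, F: int) -> float:
        if F in self.errors:
            return np.nan
        return float(min(self.em_congruences[F].min(), self.ex_congruences[F].min()))


def _resolve_halves(cube: EEMCube, split_by, seed) -> tuple[np.ndarray, np.ndarray, str]:
    n = cube.n_samples
    if isinstance(split_by, str):
        col = cube.samples[split_by]
        levels = sorted(col.unique().tolist())
        if len(levels) == 2:
            a = np.nonzero((col == levels[0]).to_numpy())[0]
            b = np.nonzero((col == levels[1]).to_numpy())[0]
            return a, b, f"{split_by}: {levels[0]} vs {levels[1]}"
        # stratified random halves within levels of the grouping variable
        rng = np.random.default_rng(seed)
        a_idx, b_idx = [], []
        for lev in levels:
            idx = np.nonzero((col == lev).to_numpy())[0]
            idx = rng.permutation(idx)
            a_idx.append(idx[: len(idx) // 2])
            b_idx.append(idx[len(idx) // 2:])
        return (np.sort(np.concatenate(a_idx)), np.sort(np.concatenate(b_idx)),
                f"stratified random halves within {split_by}")
    a, b = (np.asarray(h, dtype=int) for h in split_by)
    if np.intersect1d(a, b).size:
        raise ValueError("split halves overlap")
    if np.union1d(a, b).size != n:
        raise ValueError("split halves do not partition the sample set")
    return a, b, "explicit index sets"


def split_half(cube: EEMCube, split_by="cell_line",
               F_range=range(1, 9), threshold: float = 0.95,
               seed: int | None = 0, fit_options: dict | None = None) -> SplitHalfResult:
    """Split-half validation over a range of component numbers.

    ``split_by`` is a metadata column (two levels give the study's split;
    more levels give stratified random halves) or an explicit pair of index
    sets.  For each F a model is fitted independently on each half, the
    components are matched by joint emission x excitation congruence, and F
    passes when the minimum matched congruence reaches ``threshold`` in both
    spectral modes.
    """
    opts = {**SCAN_FIT_OPTIONS, **(fit_options or {})}
    idx_a, idx_b, spec = _resolve_halves(cube, split_by, seed)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both split halves must be nonempty")
    result = SplitHalfResult(split_spec=spec, half_sizes=(len(idx_a), len(idx_b)),
                             F_range=list(F_range), threshold=threshold)
    rng = np.random.default_rng(seed)
    for F in result.F_range:
        seed_a = int(rng.integers(2**31))
        seed_b = int(rng.integers(2**31))
        if min(len(idx_a), len(idx_b)) < F:
            result.errors[F] = f"a half with fewer than F={F} samples cannot support the fit"
            result.passed[F] = False
            logger.warning("split-half skipped for F=%d: %s", F, result.errors[F])
            continue
        model_a, _ = fit_parafac(cube.data[idx_a], F, seed=seed_a, **opts)
        model_b, _ = fit_parafac(cube.data[idx_b], F, seed=seed_b, **opts)
        perm, _ = match_components(model_a, model_b, mode="both")
        Cem = congruence_matrix(model_a.em_loadings, model_b.em_loadings)
        Cex = congruence_matrix(model_a.ex_loadings, model_b.ex_loadings)
        em = np.array([Cem[f, perm[f]] for f in range(F)])
        ex = np.array([Cex[f, perm[f]] for f in range(F)])
        result.em_congruences[F] = em
        result.ex_congruences[F] = ex
        result.passed[F] = bool(em.min() >= threshold and ex.min() >= threshold)
    return result


def residual_scan(cube: EEMCube, F_range=range(1, 9), seed: int | None = 0,
                  fit_options: dict | None = None) -> pd.DataFrame:
    """One PARAFAC fit per candidate F; returns per-F fit diagnostics.

    Columns: F, sse, explained_variance_pct, core_consistency_pct,
    n_iterations, converged.
    """
    F_range = list(F_range)
    if not F_range:
        raise ValueError("F_range must be non-empty")
    opts = {**SCAN_FIT_OPTIONS, **(fit_options or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for F in F_range:
        _, diag = fit_parafac(cube, F, seed=int(rng.integers(2**31)), **opts)
        rows.append(dict(F=F, sse=diag.sse,
                         explained_variance_pct=diag.explained_variance_pct,
                         core_consistency_pct=diag.core_consistency_pct,
                         n_iterations=diag.n_iterations, converged=diag.converged))
    return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    chosen_F: int
    rationale: pd.DataFrame
    flagged_top_of_range: bool = False


def select_n_components(scan: pd.DataFrame, splithalf: SplitHalfResult,
                        gain_tolerance: float = 0.02) -> SelectionResult:
    """Choose F from the residual scan and split-half diagnostics.

    The chosen F is the largest candidate that (i) passes split-half in
    both spectral modes and (ii) adds more than ``gain_tolerance``
    percentage points of explained variance over F-1 (for the smallest
    scanned F the gain is measured from zero).  The rationale table lists
    the per-F verdicts.
    """
    fs = scan["F"].tolist()
    if sorted(fs) != sorted(splithalf.F_range):
        raise ValueError("scan and split-half must cover the same F range")
    ev = dict(zip(scan["F"], scan["explained_variance_pct"]))
    rows = []
    candidates = []
    for F in sorted(fs):
        gain = ev[F] - ev.get(F - 1, 0.0)
        sh_pass = splithalf.passed.get(F, False)
        ok = sh_pass and gain > gain_tolerance
        rows.append(dict(F=F, explained_variance_pct=ev[F], marginal_gain_pct=gain,
                         splithalf_pass=sh_pass,
                         min_congruence=splithalf.min_congruence(F) if F not in splithalf.errors else np.nan,
                         selected_candidate=ok))
        if ok:
            candidates.append(F)
    rationale = pd.DataFrame(rows)
    if not candidates:
        raise ValueError(
            "no component number passes both criteria; diagnostics:\n"
            + rationale.to_string(index=False)
        )
    chosen = max(candidates)
    flagged = chosen == max(fs)
    if flagged:
        logger.warning("chosen F %d is the top of the scanned range; "
                       "consider extending F_range", chosen)
    return SelectionResult(chosen_F=chosen, rationale=rationale,
                           flagged_top_of_range=flagged)
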