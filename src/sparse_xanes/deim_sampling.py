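"""Greedy interpolation-point selection (DEIM) and sparse reconstruction.

Given a reduced basis ``U_k`` of the states a measurement can visit, the
discrete empirical interpolation method picks ``k`` energy indices
``p_1..p_k`` greedily: the first at the largest-magnitude entry of
``u_1``; each subsequent one at the largest-magnitude entry of the
residual of the next basis vector against the interpolatory projector of
the points chosen so far.  Measuring only those rows then determines the
coefficients ``C`` from ``P^T A = (P^T U_k) C``, and ``U_k C`` approximates
the full measurement.  Oversampling (more rows than basis vectors, e.g. by
aggregating region-wise selections) turns the solve into least squares,
the gappy-POD extension, which buys robustness against noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .background_augmentation import BackgroundConfig, augment_library
from .reduced_basis import (
    ReducedBasis,
    compute_basis,
    numerical_rank,
    select_rank,
)
from .spectra_core import (
    ConfigurationError,
    DegeneracyError,
    EnergyGrid,
    SpectralLibrary,
)

__all__ = [
    "SamplingPlan",
    "Coefficients",
    "deim_select",
    "regional_deim",
    "solve_coefficients",
    "reconstruct",
    "reconstruction_error",
    "design_experiment",
    "save_plan",
    "load_plan",
]

#: condition number of P^T U_k above which a warning is recorded
CONDITION_WARN = 1e12


@dataclass(eq=False)
class SamplingPlan:
    """Ordered distinct energy indices chosen for measurement.

    ``indices`` are zero-based grid positions in selection order;
    ``energies`` the corresponding eV values (authoritative when a plan is
    reloaded against a grid).  ``residual_norms`` records the greedy
    max-|residual| at each step; ``regions`` optional provenance for plans
    aggregated from region-wise selections.
    """

    indices: np.ndarray
    energies: np.ndarray
    basis_rank: int
    residual_norms: np.ndarray | None = None
    regions: list | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        e = np.asarray(self.energies, dtype=float)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("a plan needs at least one index")
        if len(set(idx.tolist())) != idx.size:
            raise ValueError("plan indices must be distinct")
        if np.any(idx < 0):
            raise ValueError("plan indices must be non-negative")
        if e.shape != idx.shape:
            raise ValueError("one energy per index is required")
        self.indices, self.energies = idx, e

    @property
    def s(self) -> int:
        return int(self.indices.size)

    @property
    def oversampled(self) -> bool:
        return self.s > self.basis_rank


@dataclass(eq=False)
class Coefficients:
    """Solved mixing coefficients ``C`` (one column per measured spectrum)."""

    C: np.ndarray
    plan: SamplingPlan
    solve_mode: str
    condition: float = np.nan
    ill_conditioned: bool = False


def deim_select(basis: ReducedBasis, k: int | None = None) -> SamplingPlan:
    """Greedy selection of ``k`` interpolation indices from ``basis.U``.

    Ties at the argmax break toward the smallest index.  The residual is
    exactly zero at previously selected rows, so indices are guaranteed
    distinct; a repeat can only occur if the basis is degenerate, which
    raises :class:`DegeneracyError` naming the offending step.
    """
    k = basis.k if k is None else int(k)
    if not 1 <= k <= basis.l:
        raise ValueError(f"k={k} outside [1, {basis.l}]")
    U = basis.U
    indices: list[int] = []
    res_norms: list[float] = []
    p = int(np.argmax(np.abs(U[:, 0])))
    indices.append(p)
    res_norms.append(float(np.abs(U[p, 0])))
    for j in range(1, k):
        rows = np.array(indices)
        try:
            c = np.linalg.solve(U[rows, :j], U[rows, j])
        except np.linalg.LinAlgError as exc:
            raise DegeneracyError(
                f"interpolation system singular at step {j + 1}") from exc
        r = U[:, j] - U[:, :j] @ c
        p = int(np.argmax(np.abs(r)))
        if p in indices:
            raise DegeneracyError(
                f"degenerate residual at step {j + 1}: basis vector {j + 1} "
                "lies in the span of its predecessors at the selected rows")
        indices.append(p)
        res_norms.append(float(np.abs(r[p])))
    idx = np.array(indices)
    return SamplingPlan(indices=idx, energies=basis.grid.energies[idx],
                        basis_rank=k, residual_norms=np.array(res_norms))


def regional_deim(lib: SpectralLibrary, regions: list[tuple[float, float]],
                  k_per_region, centering: str = "none",
                  basis_rank: int | None = None) -> SamplingPlan:
    """Apply the greedy selection region by region and aggregate the points.

    For each energy interval the library rows are restricted to that
    window, a fresh local basis is computed there, and the greedy selection
    is run locally; selected rows map back to global indices.  The
    aggregate is the union with duplicates removed, keeping first-selection
    order.  Recomputing a local SVD (rather than slicing rows of the global
    basis) keeps each region's basis orthonormal and well conditioned.
    """
    if np.isscalar(k_per_region):
        ks = [int(k_per_region)] * len(regions)
    else:
        ks = [int(k) for k in k_per_region]
    if len(ks) != len(regions):
        raise ConfigurationError("one k per region is required")
    e = lib.grid.energies
    seen: set[int] = set()
    agg_idx: list[int] = []
    provenance: list[dict] = []
    for (lo, hi), k_r in zip(regions, ks):
        mask = (e >= lo) & (e <= hi)
        rows = np.nonzero(mask)[0]
        if rows.size < max(2, k_r):
            raise ConfigurationError(
                f"region ({lo:g}, {hi:g}) eV has {rows.size} grid points, "
                f"fewer than the {k_r} requested")
        sub = SpectralLibrary(EnergyGrid(e[rows]), lib.matrix[rows],
                              labels=lib.labels, edge_energy=lib.edge_energy,
                              signal_type=lib.signal_type)
        local = compute_basis(sub, centering=centering)
        # cap at the local numerical rank so noise-floor modes are not selected
        s = local.singular_values
        k_eff = min(k_r, max(1, int(np.count_nonzero(s > 1e-10 * s[0]))))
        plan_r = deim_select(local, k_eff)
        global_idx = rows[plan_r.indices]
        provenance.append({"interval": (float(lo), float(hi)), "k": int(k_eff),
                           "indices": [int(i) for i in global_idx]})
        for gi in global_idx:
            gi = int(gi)
            if gi not in seen:
                seen.add(gi)
                agg_idx.append(gi)
    idx = np.array(agg_idx)
    rank = int(basis_rank) if basis_rank is not None else min(len(idx), max(ks))
    return SamplingPlan(indices=idx, energies=e[idx], basis_rank=rank,
                        regions=provenance)


def solve_coefficients(basis: ReducedBasis, plan: SamplingPlan,
                       sampled: np.ndarray) -> Coefficients:
    """Solve ``(P^T U_k) C = P^T A`` for the coefficients ``C``.

    ``sampled`` holds the measurements at the plan's energies, one row per
    plan index (in plan order), one column per spectrum.  With exactly
    ``k`` samples the solve is interpolatory; with more it is the
    least-squares (gappy-POD) solution.  An ill-conditioned ``P^T U_k``
    (condition number above 1e12) is recorded as a warning, not an error.
    """
    k = basis.k
    a = np.asarray(sampled, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] != plan.s:
        raise ValueError("one sampled row per plan index is required")
    if plan.s < k:
        raise ValueError(
            f"underdetermined: {plan.s} samples for a rank-{k} basis")
    pu = basis.U[plan.indices, :k]
    rhs = a - basis.mean[plan.indices][:, None] if basis.centering == "mean" else a
    sv = np.linalg.svd(pu, compute_uv=False)
    condition = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    ill = condition > CONDITION_WARN
    if ill:
        warnings.warn(
            f"P^T U_k condition number {condition:.3g} exceeds "
            f"{CONDITION_WARN:g}; coefficients may be unreliable",
            RuntimeWarning, stacklevel=2)
    if plan.s == k:
        try:
            C = np.linalg.solve(pu, rhs)
        except np.linalg.LinAlgError as exc:
            raise DegeneracyError("P^T U_k is singular") from exc
        mode = "interpolatory"
    else:
        C, *_ = np.linalg.lstsq(pu, rhs, rcond=None)
        mode = "least_squares"
    return Coefficients(C=C, plan=plan, solve_mode=mode,
                        condition=condition, ill_conditioned=ill)


def reconstruct(basis: ReducedBasis, coeffs: Coefficients) -> np.ndarray:
    """Full-grid approximation ``U_k C`` (plus the mean if centered)."""
    out = basis.Uk @ coeffs.C
    if basis.centering == "mean":
        out = out + basis.mean[:, None]
    return out


def reconstruction_error(truth: np.ndarray, approx: np.ndarray,
                         mask=None) -> dict:
    """Columnwise relative l2 and max-abs errors, optionally row-masked.

    Columns of ``truth`` with zero norm are flagged (``rel_l2`` is NaN
    there) rather than divided through.
    """
    t = np.asarray(truth, dtype=float)
    a = np.asarray(approx, dtype=float)
    if t.ndim == 1:
        t, a = t[:, None], a[:, None]
    if t.shape != a.shape:
        raise ValueError("truth and approximation shapes differ")
    if mask is not None:
        t, a = t[mask], a[mask]
    diff = t - a
    norms = np.linalg.norm(t, axis=0)
    zero = norms == 0
    rel = np.full(t.shape[1], np.nan)
    rel[~zero] = np.linalg.norm(diff[:, ~zero], axis=0) / norms[~zero]
    return {
        "rel_l2": rel,
        "max_abs": np.max(np.abs(diff), axis=0) if t.size else np.zeros(0),
        "zero_norm_columns": np.nonzero(zero)[0],
    }


def design_experiment(standards: SpectralLibrary,
                      bg_cfg: BackgroundConfig | None = None,
                      rank_method: str = "auto", rank_param=None,
                      regions: list[tuple[float, float]] | None = None,
                      k_per_region=None,
                      centering: str = "none",
                      append_originals: bool = True,
                      ) -> tuple[ReducedBasis, SamplingPlan, dict]:
    """End-to-end design: augment -> basis -> rank -> select.

    Returns the reduced basis (with ``k`` set), the sampling plan (plain
    greedy, or region-aggregated when ``regions`` is given), and a
    JSON-serializable provenance record.
    """
    lib = (augment_library(standards, bg_cfg, append_originals=append_originals)
           if bg_cfg is not None else standards)
    basis = compute_basis(lib, centering=centering)
    if bg_cfg is not None and rank_method == "auto" and rank_param is None:
        # states-plus-background rule: every independent direction of the
        # prior standards (even a near-zero flat state, counted at
        # machine-precision tolerance) plus the number of independent
        # background components the augmentation added (rank increase at a
        # robust 1e-8 relative tolerance).  A pure variance threshold would
        # miss deliberately tiny states such as a 1e-8 flat background.
        eps_tol = max(standards.m, standards.n) * np.finfo(float).eps
        k_states = max(1, numerical_rank(standards.matrix, rel_tol=eps_tol))
        k_bg = (numerical_rank(lib.matrix) - numerical_rank(standards.matrix))
        k = min(k_states + max(k_bg, 0), basis.l)
    else:
        k = select_rank(basis, rank_method, rank_param)
    basis.k = k
    if regions:
        plan = regional_deim(lib, regions,
                             k_per_region if k_per_region is not None else k,
                             centering=centering, basis_rank=k)
    else:
        plan = deim_select(basis, k)
    provenance = {
        "version": __version__,
        "n_standards": standards.n,
        "library_columns": lib.n,
        "rank_method": rank_method,
        "rank_param": rank_param,
        "k": int(k),
        "centering": centering,
        "regions": regions,
        "background": None if bg_cfg is None else {
            "edge_energy": bg_cfg.edge_energy,
            "pre_anchor": bg_cfg.pre_anchor,
            "post_anchor": bg_cfg.post_anchor,
            "pre_window": list(bg_cfg.pre_window),
            "post_window": list(bg_cfg.post_window),
            "offset_range": bg_cfg.offset_range,
            "n_variants": bg_cfg.n_variants,
            "seed": bg_cfg.seed,
            "enabled": bg_cfg.enabled,
            "append_originals": append_originals,
        },
    }
    return basis, plan, provenance


# ---------------------------------------------------------------------------
# plan serialization

def save_plan(plan: SamplingPlan, path, provenance: dict | None = None) -> None:
    """Write a plan as JSON: ascending indices plus the selection order.

    Both zero-based indices and eV energies are stored; on reload against a
    grid the energies are authoritative and must match within 1e-6 eV.
    """
    order = np.argsort(plan.indices)
    doc = {
        "energies_ev": [float(e) for e in plan.energies[order]],
        "indices": [int(i) for i in plan.indices[order]],
        "selection_order": [int(i) for i in plan.indices],
        "basis_rank": int(plan.basis_rank),
        "residual_norms": (None if plan.residual_norms is None
                           else [float(r) for r in plan.residual_norms]),
        "regions": plan.regions,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_plan(path, grid: EnergyGrid | None = None) -> SamplingPlan:
    doc = json.loads(Path(path).read_text())
    sel = np.array(doc["selection_order"], dtype=int)
    by_index = dict(zip(doc["indices"], doc["energies_ev"]))
    energies = np.array([by_index[int(i)] for i in sel])
    if grid is not None:
        matched = []
        for e in energies:
            j = int(np.argmin(np.abs(grid.energies - e)))
            if abs(grid.energies[j] - e) > 1e-6:
                raise ValueError(
                    f"plan energy {e:g} eV not on the target grid (nearest "
                    f"point {grid.energies[j]:g} eV)")
            matched.append(j)
        sel = np.array(matched, dtype=int)
        energies = grid.energies[sel]
    res = doc.get("residual_norms")
    return SamplingPlan(indices=sel, energies=energies,
                        basis_rank=int(doc["basis_rank"]),
                        residual_norms=None if res is None else np.array(res),
                        regions=doc.get("regions"))
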