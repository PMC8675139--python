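"""Least-squares assembly and regularized solvers for linear ACE fits.

The loss over a training set of labeled configurations X,

    L = sum_X  wE_X^2 |E(X) - E_QM(X)|^2  +  wF_X^2 |F(X) - F_QM(X)|^2,

is linear in the coefficients, so it is assembled as ||Psi c - t||^2 with one
energy row per configuration and 3 N_X force rows.  Two regularization
schemes are provided, both built on the same diagonal smoothness prior Gamma
whose entry for a basis function is a rough estimate of the magnitude of its
p-th derivative,

    Gamma_vv = sum_t ( n_t^p + w_Y * l_t^p ),

which scales down high-degree basis functions and encourages a smooth
potential:

* ``lsqr_tychonov`` minimizes ||Psi c - t||^2 + lambda^2 ||Gamma c||^2 with
  the iterative LSQR solver on the augmented system;
* ``rrqr`` solves the preconditioned system Psi Gamma^-1 by a rank-revealing
  (column-pivoted) QR factorization, truncating below the tolerance lambda,
  then maps the solution back through Gamma^-1.

The documented default picks RRQR when the system is comfortably
overdetermined (rows >= 1.2 x columns) and LSQR+Tychonov otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.linalg import lsqr as _lsqr

from .potential import LinearACEModel
from .structures import AtomicConfiguration

__all__ = [
    "FitConfig",
    "FitProblem",
    "smoothness_prior",
    "assemble_design_matrix",
    "solve_tychonov_lsqr",
    "solve_rrqr",
    "fit",
]


@dataclass
class FitConfig:
    """Weights, prior exponent, regularization strength and solver choice.

    energy_weight has units 1/eV and force_weight 1/(eV/A) so residual rows
    are dimensionless.  Per-configuration overrides are read from
    ``config.info['energy_weight']`` / ``config.info['force_weight']``.
    """

    energy_weight: float = 1.0
    force_weight: float = 1.0
    smoothness_p: float = 2.0
    lam: float = 1e-8
    solver: str | None = None  # None -> auto (rrqr if rows >= 1.2 * cols)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.energy_weight == 0 and self.force_weight == 0:
            raise ValueError("energy and force weights cannot both be zero")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class FitProblem:
    """Design matrix Psi, target vector t and the diagonal regularizer."""

    design: np.ndarray
    targets: np.ndarray
    regularizer: np.ndarray  # diagonal of Gamma, length = n columns
    meta: dict = field(default_factory=dict)


def smoothness_prior(model: LinearACEModel, p: float) -> np.ndarray:
    """Diagonal Gamma over the full coefficient layout of ``model``.

    B-basis entry: sum_t (n_t^p + w_Y l_t^p); auxiliary pair entry: n^p.
    Strictly positive, nondecreasing in every n_t and l_t.
    """
    if p < 0:
        raise ValueError("smoothness order p must be >= 0")
    w_Y = model.basis.provenance.get("selection", {}).get("w_Y", 2.0)
    per_basis = np.array(
        [
            sum(n ** p + w_Y * l ** p for (n, l) in f.degree_terms)
            for f in model.basis.functions
        ]
    )
    blocks = [np.tile(per_basis, len(model.elements))]
    pair_gamma = np.array(
        [float(n) ** p for n in range(1, model.pair_n_max + 1)]
    )
    blocks.append(np.tile(pair_gamma, len(model.pairs)))
    gamma = np.concatenate(blocks) if len(model.basis) or model.pair_n_max else np.array([])
    return np.maximum(gamma, np.finfo(float).tiny)


def assemble_design_matrix(
    model: LinearACEModel,
    dataset: list[AtomicConfiguration],
    fitcfg: FitConfig,
) -> FitProblem:
    """Rows: one weighted energy observation per configuration (unless the
    one-body strategy is forces-only) followed by its 3 N weighted force
    components.  One-body energies are removed from the energy targets
    according to the model's current strategy."""
    forces_only = model.one_body_strategy == "forces_only_shift"
    rows, targets = [], []
    n_energy = n_force = 0
    for k, config in enumerate(dataset):
        wE = float(config.info.get("energy_weight", fitcfg.energy_weight))
        wF = float(config.info.get("force_weight", fitcfg.force_weight))
        use_energy = (wE > 0.0) and not forces_only
        use_forces = wF > 0.0
        if use_energy and config.energy is None:
            raise ValueError(f"configuration {k} has no energy label")
        if use_forces and config.forces is None:
            raise ValueError(f"configuration {k} has no force labels")
        if not use_energy and not use_forces:
            raise ValueError(f"configuration {k} contributes no observations")
        if use_forces:
            phi, dphi = model.config_features(config)
        else:
            phi = model._energy_features_only(config)
            dphi = None
        if use_energy:
            e0 = sum(model.one_body[z] for z in config.elements)
            rows.append(wE * phi)
            targets.append(wE * (config.energy - e0))
            n_energy += 1
        if use_forces:
            f_rows = -dphi.transpose(0, 2, 1).reshape(-1, model.n_features)
            rows.append(wF * f_rows)
            targets.append(wF * config.forces.reshape(-1))
            n_force += f_rows.shape[0]
    design = np.vstack([np.atleast_2d(r) for r in rows])
    targets = np.concatenate([np.atleast_1d(t) for t in targets])
    gamma = smoothness_prior(model, fitcfg.smoothness_p)
    return FitProblem(
        design=design,
        targets=targets,
        regularizer=gamma,
        meta={"n_energy_rows": n_energy, "n_force_rows": n_force},
    )


def solve_tychonov_lsqr(problem: FitProblem, lam: float):
    """Minimize ||Psi c - t||^2 + lam^2 ||Gamma c||^2 via LSQR on the
    augmented system [Psi; lam Gamma]."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    ncol = problem.design.shape[1]
    if lam > 0:
        A = scipy.sparse.vstack(
            [
                scipy.sparse.csr_matrix(problem.design),
                scipy.sparse.diags(lam * problem.regularizer),
            ]
        )
        b = np.concatenate([problem.targets, np.zeros(ncol)])
    else:
        A = scipy.sparse.csr_matrix(problem.design)
        b = problem.targets
    iter_lim = 20 * ncol + 2000
    result = _lsqr(A, b, atol=1e-14, btol=1e-14, conlim=1e14, iter_lim=iter_lim)
    c, istop, itn = result[0], result[1], result[2]
    diagnostics = {
        "solver": "lsqr_tychonov",
        "lambda": lam,
        "istop": int(istop),
        "iterations": int(itn),
        "converged": istop in (1, 2),
        "residual_norm": float(np.linalg.norm(problem.design @ c - problem.targets)),
        "regularizer_norm": float(np.linalg.norm(problem.regularizer * c)),
    }
    if not diagnostics["converged"]:
        diagnostics["warning"] = "LSQR hit its iteration cap; best iterate returned"
    return c, diagnostics


def solve_rrqr(problem: FitProblem, tol_lambda: float):
    """Rank-revealing QR on the preconditioned matrix Psi Gamma^-1 with
    truncation below ``tol_lambda`` (relative to the largest diagonal of R,
    measured on the scaled system), mapped back through Gamma^-1."""
    if tol_lambda < 0:
        raise ValueError("tolerance must be >= 0")
    Psi_s = problem.design / problem.regularizer[None, :]
    Q, R, piv = scipy.linalg.qr(Psi_s, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ncol = Psi_s.shape[1]
    if diag.size == 0 or diag[0] <= tol_lambda:
        rank = 0
    else:
        rank = int(np.sum(diag > tol_lambda))
    c_scaled = np.zeros(ncol)
    if rank > 0:
        y = scipy.linalg.solve_triangular(
            R[:rank, :rank], Q[:, :rank].T @ problem.targets
        )
        c_scaled[piv[:rank]] = y
    c = c_scaled / problem.regularizer
    diagnostics = {
        "solver": "rrqr",
        "lambda": tol_lambda,
        "effective_rank": rank,
        "residual_norm": float(np.linalg.norm(problem.design @ c - problem.targets)),
        "regularizer_norm": float(np.linalg.norm(problem.regularizer * c)),
    }
    return c, diagnostics


def _choose_solver(problem: FitProblem) -> str:
    rows, cols = problem.design.shape
    return "rrqr" if rows >= 1.2 * cols else "lsqr_tychonov"


def fit(
    model: LinearACEModel,
    dataset: list[AtomicConfiguration],
    fitcfg: FitConfig | None = None,
    isolated_energies: dict | None = None,
    one_body_strategy: str = "isolated_atom",
):
    """End-to-end fit: one-body handling, assembly, solve, diagnostics.

    Returns the fitted model (modified in place) and a diagnostics dict with
    training RMSE/MAE for per-atom energies (meV) and force components
    (meV/A), the effective rank, and residual norms.
    """
    fitcfg = fitcfg or FitConfig()
    if one_body_strategy == "isolated_atom":
        model.set_one_body_term("isolated_atom", values=isolated_energies or {})
    elif one_body_strategy == "training_average":
        model.set_one_body_term("training_average", dataset=dataset)
    elif one_body_strategy == "forces_only_shift":
        model.one_body_strategy = "forces_only_shift"
        model.one_body = {z: 0.0 for z in model.elements}
        model.energy_shift = 0.0
    else:
        raise ValueError(f"unknown one-body strategy {one_body_strategy!r}")

    problem = assemble_design_matrix(model, dataset, fitcfg)
    solver = fitcfg.solver or _choose_solver(problem)
    if solver == "lsqr_tychonov":
        c, diag = solve_tychonov_lsqr(problem, fitcfg.lam)
    elif solver == "rrqr":
        c, diag = solve_rrqr(problem, fitcfg.lam)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    model.theta = c
    if one_body_strategy == "forces_only_shift":
        labeled = [cfg for cfg in dataset if cfg.energy is not None]
        if labeled:
            model.set_one_body_term("forces_only_shift", dataset=labeled)

    e_res, f_res = [], []
    for config in dataset:
        if config.energy is not None:
            e_res.append(
                (model.total_energy(config) - config.energy) / config.n_atoms
            )
        if config.forces is not None:
            f_res.append((model.forces(config) - config.forces).reshape(-1))
    e_res = np.array(e_res)
    f_res = np.concatenate(f_res) if f_res else np.array([])
    diag.update(problem.meta)
    diag.update(
        {
            "n_parameters": model.n_features,
            "energy_rmse_per_atom_meV": float(np.sqrt(np.mean(e_res ** 2)) * 1e3)
            if e_res.size
            else None,
            "energy_mae_per_atom_meV": float(np.mean(np.abs(e_res)) * 1e3)
            if e_res.size
            else None,
            "force_rmse_meV_per_A": float(np.sqrt(np.mean(f_res ** 2)) * 1e3)
            if f_res.size
            else None,
            "force_mae_meV_per_A": float(np.mean(np.abs(f_res)) * 1e3)
            if f_res.size
            else None,
        }
    )
    return model, diag
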