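"""Model/Results front end for fitting linear ACE force fields.

`ACEForceField` is constructed from labeled training configurations plus the
basis truncation choices; ``fit()`` assembles the regularized linear
least-squares problem and returns an `ACEFitResults` carrying the estimated
coefficients, fit diagnostics and the ready-to-use potential, with a
``summary()`` table in the units the field reports (meV, meV/A).

    >>> ff = ACEForceField(train, degree_caps={1: 8, 2: 7, 3: 6})
    >>> res = ff.fit(lam=1e-6)
    >>> print(res.summary())
    >>> E, F = res.potential.energy_and_forces(some_config)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bbasis import BasisSelection, BasisSet, build_basis, default_selection
from .evaluation import error_metrics
from .fitting import FitConfig, fit as _fit
from .potential import LinearACEModel
from .radial import RadialSpec, build_orthogonal_polynomials
from .structures import AtomicConfiguration

__all__ = ["ACEForceField", "ACEFitResults"]


class ACEForceField:
    """A linear ACE force-field model specification bound to training data.

    Parameters
    ----------
    train : labeled configurations (energies in eV, forces in eV/A).
    elements : element set; inferred from the data when omitted.
    nu_max, degree_caps, w_Y : basis truncation (defaults: nu_max 4 for up to
        three distinct elements, else 3; w_Y = 2).
    r_cut : outer cutoff in A (default 5.0).
    r_in : inner cutoff; default is the minimum training-set pair distance
        minus 0.05 A, clamped to at least 0.5 A (the region inside carries
        little or no data and is excluded from the multibody basis).
    pair_n_max : size of the auxiliary short-range pair basis (default 6).
    one_body : 'isolated_atom' (supply ``isolated_energies``),
        'training_average', or 'forces_only_shift'.
    basis_seed : seed of the dependency-pruning environments (recorded in
        the basis provenance).
    """

    def __init__(
        self,
        train: list[AtomicConfiguration],
        elements=None,
        nu_max: int | None = None,
        degree_caps: dict[int, int] | None = None,
        w_Y: float = 2.0,
        r_cut: float = 5.0,
        r_in: float | None = None,
        n_max: int | None = None,
        pair_n_max: int = 6,
        one_body: str = "isolated_atom",
        isolated_energies: dict | None = None,
        basis_seed: int = 2021,
        basis: BasisSet | None = None,
        radial: RadialSpec | None = None,
    ):
        if not train:
            raise ValueError("training set is empty")
        self.train = list(train)
        if elements is None:
            elements = sorted({z for c in train for z in c.elements})
        self.elements = tuple(sorted(elements))

        kwargs = {"w_Y": w_Y}
        if nu_max is not None:
            kwargs["nu_max"] = nu_max
        if degree_caps is not None:
            kwargs["degree_caps"] = tuple(sorted(degree_caps.items()))
        self.selection: BasisSelection = default_selection(self.elements, **kwargs)

        if radial is None:
            if r_in is None:
                dmin = min(c.min_distance() for c in train)
                r_in = max(dmin - 0.05, 0.5)
            radial = RadialSpec(
                r_in=float(r_in),
                r_out=float(r_cut),
                n_max=int(n_max) if n_max is not None else self.selection.n_max,
            )
        self.radial = radial
        self.polys = build_orthogonal_polynomials(radial)
        if basis is None:
            basis = build_basis(self.selection, radial, self.polys, seed=basis_seed)
        self.basis = basis
        self.pair_n_max = pair_n_max
        self.one_body_strategy = one_body
        self.isolated_energies = dict(isolated_energies or {})

    @classmethod
    def from_extxyz(cls, path, **kwargs) -> "ACEForceField":
        from .io import read_extxyz

        return cls(read_extxyz(path), **kwargs)

    def fit(
        self,
        lam: float = 1e-8,
        solver: str | None = None,
        energy_weight: float = 1.0,
        force_weight: float = 1.0,
        smoothness_p: float = 2.0,
        seed: int = 0,
    ) -> "ACEFitResults":
        fitcfg = FitConfig(
            energy_weight=energy_weight,
            force_weight=force_weight,
            smoothness_p=smoothness_p,
            lam=lam,
            solver=solver,
            seed=seed,
        )
        model = LinearACEModel.zeros(
            self.basis, self.radial, self.polys, pair_n_max=self.pair_n_max
        )
        model, diagnostics = _fit(
            model,
            self.train,
            fitcfg,
            isolated_energies=self.isolated_energies,
            one_body_strategy=self.one_body_strategy,
        )
        return ACEFitResults(model=self, potential=model, diagnostics=diagnostics,
                             fit_config=fitcfg)


@dataclass
class ACEFitResults:
    """Estimates, diagnostics and the fitted potential."""

    model: ACEForceField
    potential: LinearACEModel
    diagnostics: dict
    fit_config: FitConfig = field(default_factory=FitConfig)

    @property
    def params(self) -> np.ndarray:
        """The flat linear coefficient vector (B blocks per center element,
        then auxiliary pair blocks)."""
        return self.potential.theta

    def predict(self, configs):
        """Energies (eV) and forces (eV/A) for a list of configurations."""
        energies, forces = [], []
        for c in configs:
            E, F = self.potential.energy_and_forces(c)
            energies.append(E)
            forces.append(F)
        return np.array(energies), forces

    def evaluate(self, test_set) -> dict:
        """MAE/RMSE metrics (meV, meV/A) on a labeled test set."""
        return error_metrics(self.potential, test_set)

    def save(self, path) -> None:
        from .io import save_model

        save_model(self.potential, path, diagnostics=self.diagnostics)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Linear ACE force field — fit summary",
            "=" * 52,
            f"elements                 {', '.join(self.model.elements)}",
            f"correlation order ν_max  {self.model.selection.nu_max}",
            f"degree caps D_ν^max      {self.model.selection.caps}",
            f"cutoffs r_in / r_out     {self.model.radial.r_in:.3f} / "
            f"{self.model.radial.r_out:.3f} Å",
            f"basis functions          {len(self.model.basis)}"
            f"  (+{len(self.potential.pairs) * self.potential.pair_n_max} pair)",
            f"parameters               {self.potential.n_features}",
            f"observations             {d.get('n_energy_rows', 0)} energies, "
            f"{d.get('n_force_rows', 0)} force components",
            f"solver                   {d.get('solver')}  (λ = {d.get('lambda'):g})",
            f"one-body strategy        {self.potential.one_body_strategy}",
        ]
        if d.get("effective_rank") is not None:
            lines.append(f"effective rank           {d['effective_rank']}")
        if d.get("iterations") is not None:
            lines.append(f"LSQR iterations          {d['iterations']}")
        lines += [
            "-" * 52,
            f"train energy RMSE        {d.get('energy_rmse_per_atom_meV'):.4g} meV/atom"
            if d.get("energy_rmse_per_atom_meV") is not None
            else "train energy RMSE        n/a (forces-only fit)",
            f"train energy MAE         {d.get('energy_mae_per_atom_meV'):.4g} meV/atom"
            if d.get("energy_mae_per_atom_meV") is not None
            else "train energy MAE         n/a",
            f"train force RMSE         {d.get('force_rmse_meV_per_A'):.4g} meV/Å"
            if d.get("force_rmse_meV_per_A") is not None
            else "train force RMSE         n/a",
            f"train force MAE          {d.get('force_mae_meV_per_A'):.4g} meV/Å"
            if d.get("force_mae_meV_per_A") is not None
            else "train force MAE          n/a",
            "=" * 52,
        ]
        return "\n".join(lines)
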