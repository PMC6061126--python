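"""Moiety-conservation analysis of reaction networks.

A conservation relation is a row vector gamma with gamma @ N = 0 for the
stoichiometry matrix N (species x reactions): the quantity gamma @ x is
constant along every trajectory of dx/dt = N v(x).  The left null space
of N is computed by QR factorisation with column pivoting of N', which
also partitions the species into independents (pivots) and dependents;
dependent species can then be eliminated as affine functions of the
independents and the conserved totals, shrinking the model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import linalg

from .core import ControlAffineModel
from .errors import ConfigurationError, ValidationError

__all__ = [
    "StoichiometricNetwork",
    "ConservationSet",
    "conservation_relations",
    "eliminate_conserved",
]

#: Singular values of N' below RANK_RTOL * largest count as zero (SBML
#: models can carry float stoichiometries).
RANK_RTOL = 1e-10


@dataclass
class StoichiometricNetwork:
    """Reaction network: species, reactions, stoichiometry and rate laws.

    ``rates(x) -> (r,)`` evaluates all reaction rates, so the ODE
    right-hand side is ``N @ rates(x)``.
    """

    species: list[str]
    reactions: list[str]
    N: np.ndarray
    rates: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        self.N = np.atleast_2d(np.asarray(self.N, dtype=float))
        if self.N.shape != (len(self.species), len(self.reactions)):
            raise ValidationError(
                f"N has shape {self.N.shape}, expected "
                f"({len(self.species)}, {len(self.reactions)})")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def drift(self, x: np.ndarray) -> np.ndarray:
        return self.N @ np.asarray(self.rates(x), dtype=float)

    def to_model(self, x0: Sequence[float],
                 outputs: dict[str, np.ndarray] | None = None,
                 input_fields: list | None = None,
                 input_names: list[str] | None = None) -> ControlAffineModel:
        """Wrap as a ControlAffineModel; outputs are named linear combinations
        of species (default: every species)."""
        if outputs is None:
            C = np.eye(self.n_species)
            out_names = list(self.species)
        else:
            out_names = list(outputs)
            C = np.vstack([outputs[k] for k in out_names])
        return ControlAffineModel(
            state_names=list(self.species),
            drift=self.drift,
            input_fields=input_fields or [],
            output_map=lambda x: C @ x,
            initial_state=np.asarray(x0, dtype=float),
            input_names=input_names or [],
            output_names=out_names,
        )


@dataclass
class ConservationSet:
    """A basis of conservation relations and the species pivoting.

    ``Gamma`` (c x n) spans the left null space of N; ``independent`` and
    ``dependent`` index the species partition chosen by QR column
    pivoting; ``totals`` are the conserved quantities evaluated at x0 (or
    zeros if no state was supplied).
    """

    Gamma: np.ndarray
    independent: np.ndarray
    dependent: np.ndarray
    totals: np.ndarray
    species: list[str]

    @property
    def n_relations(self) -> int:
        return self.Gamma.shape[0]

    def totals_from(self, x0: np.ndarray) -> np.ndarray:
        return self.Gamma @ np.asarray(x0, dtype=float)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.Gamma, columns=self.species)


def conservation_relations(network: StoichiometricNetwork,
                           x0: np.ndarray | None = None) -> ConservationSet:
    """Basis of the left null space of N via pivoted QR of N'.

    QR with column pivoting of N' (r x n) ranks the species columns; the
    first ``rank`` pivots are the independent species.  Writing the
    permuted stoichiometry as [Na; Nb] with Na the independent rows,
    Nb = M Na for M = Nb pinv(Na), and Gamma = [-M  I] (unpermuted)
    satisfies Gamma N = 0 with rank(Gamma) = n - rank(N).
    """
    N = network.N
    n = network.n_species
    if not np.all(np.isfinite(N)):
        raise ValidationError("stoichiometry matrix contains non-finite entries")
    # pivoted QR of N^T ranks species columns by independence
    _, R, piv = linalg.qr(N.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R)) if R.size else np.array([])
    rank = int(np.sum(diag > (diag[0] if len(diag) else 0.0) * RANK_RTOL))
    independent = np.sort(piv[:rank])
    dependent = np.sort(piv[rank:])
    c = n - rank
    if c == 0:
        Gamma = np.zeros((0, n))
    else:
        Na = N[independent, :]
        Nb = N[dependent, :]
        M = Nb @ np.linalg.pinv(Na) if rank else np.zeros((c, 0))
        Gamma = np.zeros((c, n))
        Gamma[:, independent] = -M
        Gamma[np.arange(c), dependent] = 1.0
        # clean tiny numerical residue for readability
        Gamma[np.abs(Gamma) < 1e-12] = 0.0
    totals = (Gamma @ np.asarray(x0, dtype=float)
              if x0 is not None else np.zeros(c))
    resid = np.abs(Gamma @ N).max() if c else 0.0
    if resid > 1e-8 * max(1.0, np.abs(N).max()):
        raise ValidationError(f"conservation basis residual too large: {resid:.3g}")
    return ConservationSet(Gamma=Gamma, independent=independent,
                           dependent=dependent, totals=totals,
                           species=list(network.species))


def eliminate_conserved(network: StoichiometricNetwork,
                        x0: np.ndarray,
                        conservation: ConservationSet | None = None,
                        outputs: dict[str, np.ndarray] | None = None,
                        input_fields: list | None = None,
                        input_names: list[str] | None = None,
                        ) -> ControlAffineModel:
    """Reduce a network to its independent species.

    Each dependent species is replaced by the affine expression implied by
    its conservation relation (total minus the weighted sum of independent
    members), giving an (n - c)-state model whose simulated outputs equal
    the original's to solver tolerance.  Output and input maps declared on
    the full species vector are composed with the reconstruction.
    """
    x0 = np.asarray(x0, dtype=float)
    if conservation is None:
        conservation = conservation_relations(network, x0)
    cons = conservation
    ind, dep = cons.independent, cons.dependent
    c = cons.n_relations
    totals = cons.totals_from(x0)
    n = network.n_species

    # x_dep = totals - Gamma[:, ind] @ x_ind   (since Gamma[:, dep] = I)
    Gd = cons.Gamma[:, dep]
    if c and np.abs(Gd - np.eye(c)).max() > 1e-9:
        # general basis: solve Gd x_dep = totals - Gi x_ind
        Gd_inv = np.linalg.inv(Gd)
    else:
        Gd_inv = np.eye(c)
    Gi = cons.Gamma[:, ind]

    def reconstruct(x_ind: np.ndarray) -> np.ndarray:
        x = np.empty(n)
        x[ind] = x_ind
        if c:
            x[dep] = Gd_inv @ (totals - Gi @ x_ind)
        return x

    def drift(x_ind: np.ndarray) -> np.ndarray:
        return network.drift(reconstruct(x_ind))[ind]

    if outputs is None:
        C = np.eye(n)
        out_names = list(network.species)
    else:
        out_names = list(outputs)
        C = np.vstack([outputs[k] for k in out_names])

    fields = []
    for g in (input_fields or []):
        fields.append(lambda x_ind, g=g: np.asarray(
            g(reconstruct(x_ind)), dtype=float)[ind])

    reduced = ControlAffineModel(
        state_names=[network.species[i] for i in ind],
        drift=drift,
        input_fields=fields,
        output_map=lambda x_ind: C @ reconstruct(x_ind),
        initial_state=x0[ind],
        input_names=input_names or [],
        output_names=out_names,
    )
    # self-check: reduced stoichiometry has full row rank by construction
    Na = network.N[ind, :]
    if Na.size and np.linalg.matrix_rank(Na) < len(ind):
        raise ConfigurationError(
            "pivot selection left a rank-deficient reduced stoichiometry; "
            "conservation basis and pivoting are inconsistent")
    return reduced
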