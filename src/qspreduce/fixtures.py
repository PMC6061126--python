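"""Deterministic test-model generators.

Everything a test needs is generated from (name, seed): random stable
linear systems for the balanced-truncation property tests, and a small
catalogue of reaction networks with known reductions — parallel identical
compartments (exact one-lump), a reversible isomerisation and a
Michaelis-Menten mechanism (known conservation counts 1 and 2), and a
six-state receptor cascade standing in for a chemotactic signalling
pathway (ligand input, terminal phosphorylated-messenger output) to
exercise the full reduce-and-link pipeline without external model files.
"""

from __future__ import annotations

import numpy as np

from .conservation import StoichiometricNetwork
from .core import ControlAffineModel, LinearStateSpaceModel

__all__ = [
    "DEFAULT_SEED",
    "random_stable_linear_system",
    "parallel_compartments",
    "isomerisation_network",
    "michaelis_menten_network",
    "receptor_cascade",
    "toy_networks",
]

DEFAULT_SEED = 20180326


def random_stable_linear_system(n: int, l: int = 1, p: int = 1,
                                seed: int = DEFAULT_SEED,
                                spectral_range: tuple[float, float] = (0.1, 10.0),
                                ) -> LinearStateSpaceModel:
    """Random guaranteed-Hurwitz system A = V diag(-lam) V^-1.

    Eigenvalues are drawn log-uniformly in ``spectral_range`` (all real,
    negative); V is a well-conditioned random basis (orthogonal matrix
    plus a small perturbation); B and C are dense with unit-scale entries.
    The same (n, l, p, seed) always regenerates the identical system.
    """
    if min(n, l, p) < 1:
        raise ValueError("n, l, p must all be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spectral_range
    lam = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    V = Q + 0.1 * rng.standard_normal((n, n))
    A = V @ np.diag(-lam) @ np.linalg.inv(V)
    B = rng.standard_normal((n, l))
    C = rng.standard_normal((p, n))
    return LinearStateSpaceModel(
        A=A, B=B, C=C,
        state_names=[f"x{i + 1}" for i in range(n)],
        input_names=[f"u{i + 1}" for i in range(l)],
        output_names=[f"y{i + 1}" for i in range(p)],
    )


def parallel_compartments(n_parallel: int = 2, k_in: float = 1.0,
                          k_out: float = 0.5) -> LinearStateSpaceModel:
    """Central compartment feeding ``n_parallel`` identical peripherals.

    The peripherals have the same rates and initial states, so lumping
    them into one is exact: the output (sum of peripherals) is preserved
    with zero error.
    """
    n = 1 + n_parallel
    A = np.zeros((n, n))
    A[0, 0] = -n_parallel * k_in
    for i in range(1, n):
        A[i, 0] = k_in
        A[i, i] = -k_out
        A[0, i] = 0.0
    B = np.zeros((n, 1)); B[0, 0] = 1.0
    C = np.zeros((1, n)); C[0, 1:] = 1.0
    x0 = np.zeros(n); x0[0] = 1.0
    return LinearStateSpaceModel(
        A=A, B=B, C=C,
        state_names=["central"] + [f"peripheral{i}" for i in range(1, n)],
        input_names=["inflow"], output_names=["peripheral_total"],
        initial_state=x0,
    )


def isomerisation_network(kf: float = 1.0, kr: float = 1.0
                          ) -> StoichiometricNetwork:
    """Reversible isomerisation A <-> B: one conservation relation (A + B)."""
    N = np.array([[-1.0, 1.0],
                  [1.0, -1.0]])
    return StoichiometricNetwork(
        species=["A", "B"], reactions=["forward", "reverse"], N=N,
        rates=lambda x: np.array([kf * x[0], kr * x[1]]),
    )


def michaelis_menten_network(k1: float = 10.0, km1: float = 1.0,
                             k2: float = 2.0) -> StoichiometricNetwork:
    """S + E <-> C -> E + P: two conservation relations (E + C, S + C + P)."""
    #            bind  unbind  cat
    N = np.array([[-1.0, 1.0, 0.0],    # S
                  [-1.0, 1.0, 1.0],    # E
                  [1.0, -1.0, -1.0],   # C
                  [0.0, 0.0, 1.0]])    # P
    return StoichiometricNetwork(
        species=["S", "E", "C", "P"], reactions=["bind", "unbind", "cat"], N=N,
        rates=lambda x: np.array([k1 * x[0] * x[1], km1 * x[2], k2 * x[2]]),
    )


def receptor_cascade() -> ControlAffineModel:
    """Six-state receptor signalling cascade with a ligand input.

    Extracellular ligand (the input, e.g. a drug concentration delivered
    by a PK model) binds free receptor R to form an active complex RL,
    which phosphorylates a two-step messenger chain M1 -> M1p and
    M2 -> M2p; the terminal phosphorylated messenger M2p is the output
    (the cell-response correlate).  Mass-action kinetics, parameters of
    order 1/h chosen so the cascade responds on a faster scale than
    whole-body pharmacokinetics.
    """
    k_on, k_off = 5.0, 1.0          # per (conc*h), per h
    k_p1, k_d1 = 4.0, 2.0
    k_p2, k_d2 = 3.0, 1.5

    # states: R, RL, M1, M1p, M2, M2p
    def drift(x):
        R, RL, M1, M1p, M2, M2p = x
        v_off = k_off * RL
        v_p1 = k_p1 * RL * M1
        v_d1 = k_d1 * M1p
        v_p2 = k_p2 * M1p * M2
        v_d2 = k_d2 * M2p
        return np.array([
            v_off,            # R   (+ binding via input field)
            -v_off,           # RL
            -v_p1 + v_d1,     # M1
            v_p1 - v_d1,      # M1p
            -v_p2 + v_d2,     # M2
            v_p2 - v_d2,      # M2p
        ])

    def g_ligand(x):
        # binding flux per unit ligand concentration: k_on * R
        R = x[0]
        return np.array([-k_on * R, k_on * R, 0.0, 0.0, 0.0, 0.0])

    x0 = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    return ControlAffineModel(
        state_names=["R", "RL", "M1", "M1p", "M2", "M2p"],
        drift=drift,
        input_fields=[g_ligand],
        output_map=lambda x: np.array([x[5]]),
        initial_state=x0,
        input_names=["ligand"],
        output_names=["M2p"],
    )


def toy_networks() -> dict[str, object]:
    """Catalogue of the packaged toy fixtures, keyed by name."""
    return {
        "parallel": parallel_compartments(),
        "isomerisation": isomerisation_network(),
        "mm": michaelis_menten_network(),
        "cascade": receptor_cascade(),
    }
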