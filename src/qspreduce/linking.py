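"""Model linkage: wire outputs of one model to inputs of another.

A QSP model is assembled from components (a whole-body PK model, a
cellular signalling network, ...) by declaring that an output of one
component is the input of another — e.g. liver drug concentration driving
a bacterial chemotaxis pathway, or brain concentration driving a receptor
cascade.  :func:`link` builds a single monolithic control-affine system
from such declarations (one joint ODE system, so there is no co-simulation
coupling error), and :func:`decompose_linear_nonlinear` performs the
reverse: it cuts a model into a linear block and a nonlinear block joined
by input-output arcs, so the linear part can be reduced by balanced
truncation and the nonlinear part by lumping before relinking.

Feedback loops between components are allowed; because every component's
outputs read only its states (no direct input-to-output feedthrough),
instantaneous algebraic loops cannot arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import ControlAffineModel, LinearStateSpaceModel
from .errors import ValidationError, WiringError

__all__ = ["Linkage", "CompositeModel", "link", "decompose_linear_nonlinear"]


@dataclass
class Linkage:
    """One wiring arc: upstream model output -> downstream model input.

    ``coupling`` converts upstream output units into downstream input
    units; by default a linear gain (e.g. mg/L -> uM with a declared
    conversion factor).
    """

    upstream: object
    upstream_output: str
    downstream: object
    downstream_input: str
    gain: float = 1.0
    coupling: Callable[[float], float] | None = None
    units: str | None = None

    def convert(self, value: float) -> float:
        if self.coupling is not None:
            return self.coupling(value)
        return self.gain * value


def _as_affine(model) -> ControlAffineModel:
    if isinstance(model, LinearStateSpaceModel):
        return model.to_control_affine()
    return model


@dataclass
class CompositeModel:
    """A linked ensemble flattened into one control-affine system.

    ``model`` is the joint system; ``members`` maps member names to their
    state slices.  Exposed inputs are the unbound member inputs and
    exposed outputs the union of member outputs, both namespaced
    ``member.channel``.
    """

    model: ControlAffineModel
    members: dict[str, slice]

    @property
    def n_states(self) -> int:
        return self.model.n_states


def link(links: Sequence[Linkage],
         names: dict[int, str] | None = None) -> CompositeModel:
    """Compose models by binding declared outputs to declared inputs.

    Models are discovered from the linkage list (first appearance fixes
    state ordering) and named ``m1, m2, ...`` unless ``names`` maps
    ``id(model)`` to a label.  Cycles between members are permitted.

    Raises
    ------
    WiringError
        If a linkage names a channel its model does not declare.
    """
    if not links:
        raise WiringError("no linkages given")
    raw: list[object] = []
    for lk in links:
        for m in (lk.upstream, lk.downstream):
            if not any(m is r for r in raw):
                raw.append(m)
    models = [_as_affine(m) for m in raw]
    label = {}
    for i, m in enumerate(raw):
        label[id(m)] = (names or {}).get(id(m), f"m{i + 1}")

    # validate channels and build binding table
    for lk in links:
        up = models[next(i for i, r in enumerate(raw) if r is lk.upstream)]
        dn = models[next(i for i, r in enumerate(raw) if r is lk.downstream)]
        if lk.upstream_output not in up.output_names:
            raise WiringError(
                f"{label[id(lk.upstream)]} has no output "
                f"{lk.upstream_output!r} (outputs: {up.output_names}); "
                f"wiring to {label[id(lk.downstream)]}.{lk.downstream_input}")
        if lk.downstream_input not in dn.input_names:
            raise WiringError(
                f"{label[id(lk.downstream)]} has no input "
                f"{lk.downstream_input!r} (inputs: {dn.input_names}); "
                f"wired from {label[id(lk.upstream)]}.{lk.upstream_output}")

    offsets, slices = [], {}
    n = 0
    for m, r in zip(models, raw):
        offsets.append(n)
        slices[label[id(r)]] = slice(n, n + m.n_states)
        n += m.n_states

    bound: dict[tuple[int, int], list] = {}
    for lk in links:
        ui = next(i for i, r in enumerate(raw) if r is lk.upstream)
        di = next(i for i, r in enumerate(raw) if r is lk.downstream)
        ch = models[di].input_index(lk.downstream_input)
        out = models[ui].output_names.index(lk.upstream_output)
        bound.setdefault((di, ch), []).append((ui, out, lk))

    free_inputs = []   # (model index, channel index, name)
    for i, m in enumerate(models):
        for ch, nm in enumerate(m.input_names):
            if (i, ch) not in bound:
                free_inputs.append((i, ch, f"{label[id(raw[i])]}.{nm}"))

    out_channels = []  # (model index, output index, name)
    for i, m in enumerate(models):
        for j, nm in enumerate(m.output_names):
            out_channels.append((i, j, f"{label[id(raw[i])]}.{nm}"))

    state_names = []
    for i, m in enumerate(models):
        state_names += [f"{label[id(raw[i])]}.{s}" for s in m.state_names]
    x0 = np.concatenate([m.initial_state for m in models]) if models else np.zeros(0)

    def member_states(x, i):
        return x[offsets[i]:offsets[i] + models[i].n_states]

    def drift(x):
        dx = np.empty_like(x)
        outputs = [np.asarray(m.output_map(member_states(x, i)), dtype=float)
                   for i, m in enumerate(models)]
        for i, m in enumerate(models):
            xi = member_states(x, i)
            d = np.asarray(m.drift(xi), dtype=float)
            for (di, ch), sources in bound.items():
                if di != i:
                    continue
                u = sum(lk.convert(outputs[ui][out]) for ui, out, lk in sources)
                if u != 0.0:
                    d = d + np.asarray(m.input_fields[ch](xi), dtype=float) * u
            dx[offsets[i]:offsets[i] + m.n_states] = d
        return dx

    def make_field(i, ch):
        def field(x):
            g = np.zeros_like(x)
            xi = member_states(x, i)
            g[offsets[i]:offsets[i] + models[i].n_states] = \
                np.asarray(models[i].input_fields[ch](xi), dtype=float)
            return g
        return field

    def output_map(x):
        vals = []
        for i, j, _ in out_channels:
            y = np.asarray(models[i].output_map(member_states(x, i)), dtype=float)
            vals.append(y[j])
        return np.array(vals)

    composite = ControlAffineModel(
        state_names=state_names,
        drift=drift,
        input_fields=[make_field(i, ch) for i, ch, _ in free_inputs],
        output_map=output_map,
        initial_state=x0,
        input_names=[nm for _, _, nm in free_inputs],
        output_names=[nm for _, _, nm in out_channels],
    )
    return CompositeModel(model=composite, members=slices)


# ---------------------------------------------------------------------------
# linear / nonlinear decomposition
# ---------------------------------------------------------------------------

def _jacobian(f, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x), dtype=float)
    J = np.empty((len(f0), len(x)))
    for j in range(len(x)):
        h = eps * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        J[:, j] = (np.asarray(f(xp), dtype=float) - np.asarray(f(xm), dtype=float)) / (2 * h)
    return J


def decompose_linear_nonlinear(model: ControlAffineModel,
                               nonlinear_states: Sequence[str],
                               n_check_samples: int = 20,
                               rtol: float = 1e-6,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[LinearStateSpaceModel, ControlAffineModel, list[Linkage]]:
    """Cut a model into a linear block and a nonlinear block plus wiring.

    The complement of ``nonlinear_states`` must have dynamics linear in
    the full state (checked numerically at random sample points around
    the initial state); the dependence of the nonlinear block on the
    linear states must likewise be affine (its input fields may still
    depend on the nonlinear states, which control-affine form allows).
    Cut arcs are promoted to input/output channels on both blocks and
    returned as the Linkage list that reassembles the original model —
    ``link(links)`` reproduces the original trajectories to solver
    tolerance.

    Raises
    ------
    ValidationError
        If the linearity/affineness checks fail; the offending states are
        named in the message.
    """
    rng = rng or np.random.default_rng(0)
    names = model.state_names
    N_idx = [names.index(s) for s in nonlinear_states]
    L_idx = [i for i in range(model.n_states) if i not in N_idx]
    if not L_idx:
        raise ValidationError("no linear states left after selection")
    L_names = [names[i] for i in L_idx]
    N_names = [names[i] for i in N_idx]

    x_ref = model.initial_state
    scale = np.maximum(1.0, np.abs(x_ref))
    J0 = _jacobian(model.drift, np.zeros_like(x_ref))
    f00 = np.asarray(model.drift(np.zeros_like(x_ref)), dtype=float)
    if np.abs(f00[L_idx]).max() > rtol * max(1.0, np.abs(J0).max()):
        raise ValidationError(
            "linear block has a constant drift offset; only homogeneous "
            "linear blocks are supported")

    # verify: f_L is globally linear, f_N affine in x_L
    bad = set()
    for _ in range(n_check_samples):
        x = rng.standard_normal(model.n_states) * scale
        fx = np.asarray(model.drift(x), dtype=float)
        lin_pred = J0[L_idx] @ x
        err = np.abs(fx[L_idx] - lin_pred)
        tol = rtol * max(1.0, np.abs(fx[L_idx]).max())
        for row, e in zip(L_idx, err):
            if e > tol:
                bad.add(names[row])
        if not N_idx:
            continue
        # affineness of f_N in x_L: second difference along random x_L dir
        d = np.zeros(model.n_states)
        d[L_idx] = rng.standard_normal(len(L_idx)) * scale[L_idx]
        fp = np.asarray(model.drift(x + d), dtype=float)[N_idx]
        fm = np.asarray(model.drift(x - d), dtype=float)[N_idx]
        second = np.abs(fp + fm - 2 * fx[N_idx])
        tolN = rtol * max(1.0, np.abs(fx[N_idx]).max())
        for row, e in zip(N_idx, second):
            if e > tolN:
                bad.add(names[row])
    if bad:
        raise ValidationError(
            f"decomposition invalid: states {sorted(bad)} violate the "
            "linearity/affineness requirements")

    A_LL = J0[np.ix_(L_idx, L_idx)]
    A_LN = J0[np.ix_(L_idx, N_idx)]
    cut_into_linear = [j for j in range(len(N_idx))
                       if np.any(np.abs(A_LN[:, j]) > 0)]
    J_NL = J0[np.ix_(N_idx, L_idx)]
    cut_into_nonlinear = [j for j in range(len(L_idx))
                          if np.any(np.abs(J_NL[:, j]) > 0)]

    # original external inputs: require constant g restricted to each block
    B_cols, lin_in_names = [], []
    nonlin_fields, nonlin_in_names = [], []
    for ch, g in enumerate(model.input_fields):
        g0 = np.asarray(g(x_ref), dtype=float)
        if np.any(np.abs(g0[L_idx]) > 0):
            B_cols.append(g0[L_idx])
            lin_in_names.append(model.input_names[ch])
        if np.any(np.abs(g0[N_idx]) > 0):
            nonlin_fields.append(lambda z, ch=ch: _nonlin_g(model, ch, z))
            nonlin_in_names.append(model.input_names[ch])

    def _nonlin_g(model, ch, z):
        x = np.zeros(model.n_states)
        x[N_idx] = z
        return np.asarray(model.input_fields[ch](x), dtype=float)[N_idx]

    # cut inputs into the linear block: one channel per feeding nonlinear state
    for j in cut_into_linear:
        B_cols.append(A_LN[:, j])
        lin_in_names.append(f"cut_{N_names[j]}")
    B = np.column_stack(B_cols) if B_cols else np.zeros((len(L_idx), 0))

    # linear block outputs: identity on every linear state (cut arcs and any
    # original output built on linear states read from these)
    C = np.eye(len(L_idx))
    linear_block = LinearStateSpaceModel(
        A=A_LL, B=B, C=C, state_names=L_names,
        input_names=lin_in_names, output_names=list(L_names),
        initial_state=x_ref[L_idx],
    )

    # nonlinear block: f_N with x_L = 0, cut inputs with state-dependent fields
    def f_N0(z):
        x = np.zeros(model.n_states)
        x[N_idx] = z
        return np.asarray(model.drift(x), dtype=float)[N_idx]

    def cut_field(j):
        def g(z):
            x = np.zeros(model.n_states)
            x[N_idx] = z
            Jz = _jacobian(model.drift, x)
            return Jz[N_idx, L_idx[j]]
        return g

    for j in cut_into_nonlinear:
        nonlin_fields.append(cut_field(j))
        nonlin_in_names.append(f"cut_{L_names[j]}")

    nonlinear_block = ControlAffineModel(
        state_names=N_names,
        drift=f_N0,
        input_fields=nonlin_fields,
        output_map=lambda z: z.copy(),
        initial_state=x_ref[N_idx],
        input_names=nonlin_in_names,
        output_names=list(N_names),
    )

    links = []
    for j in cut_into_linear:
        links.append(Linkage(upstream=nonlinear_block, upstream_output=N_names[j],
                             downstream=linear_block,
                             downstream_input=f"cut_{N_names[j]}"))
    for j in cut_into_nonlinear:
        links.append(Linkage(upstream=linear_block, upstream_output=L_names[j],
                             downstream=nonlinear_block,
                             downstream_input=f"cut_{L_names[j]}"))
    return linear_block, nonlinear_block, links
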