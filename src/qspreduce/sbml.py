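"""SBML import for reaction-network models.

Reads SBML Level 2/3 core documents with kinetic laws into the package's
model types: species become states (concentrations; amount-based initial
values are divided by compartment size), reactions supply the
stoichiometry matrix and symbolic rate laws, and parameters (global and
reaction-local, the latter namespaced) are resolved numerically.
Boundary-condition and constant species are held fixed at their initial
value unless promoted to a model input via ``input_species``.

The kinetic-law MathML is converted to sympy expressions; function
definitions are inlined.  Constructs outside the supported subset —
events, rules, constraints, delays — raise
:class:`~qspreduce.errors.UnsupportedSBMLFeature` listing what was found,
rather than importing a silently wrong model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp
from lxml import etree

from .conservation import StoichiometricNetwork
from .core import ControlAffineModel
from .errors import UnsupportedSBMLFeature, ValidationError

__all__ = ["read_sbml", "mathml_to_sympy"]


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(node, name):
    return [c for c in node if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(node, name):
    got = _children(node, name)
    return got[0] if got else None


# ---------------------------------------------------------------------------
# content MathML -> sympy
# ---------------------------------------------------------------------------

_MATHML_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "minus": lambda *a: (-a[0] if len(a) == 1 else a[0] - a[1]),
    "divide": lambda a, b: a / b,
    "power": lambda a, b: a ** b,
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
}


def mathml_to_sympy(node, symbols: dict[str, sp.Expr],
                    functions: dict[str, sp.Lambda] | None = None) -> sp.Expr:
    """Convert a content-MathML element tree to a sympy expression.

    ``symbols`` maps SBML identifiers to sympy symbols/values;
    ``functions`` holds SBML function definitions for inlining.
    """
    functions = functions or {}
    tag = _local(node.tag)
    if tag == "math":
        kids = [c for c in node if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise UnsupportedSBMLFeature("math element must have one child")
        return mathml_to_sympy(kids[0], symbols, functions)
    if tag == "ci":
        name = node.text.strip()
        if name in functions:
            raise UnsupportedSBMLFeature(f"bare function reference {name!r}")
        if name not in symbols:
            raise ValidationError(f"unknown identifier {name!r} in MathML")
        return symbols[name]
    if tag == "cn":
        cn_type = node.get("type", "real")
        if cn_type == "e-notation":
            parts = [t for t in node.itertext()]
            # text, <sep/>, text
            mant = float(node.text.strip())
            exp = float(node[-1].tail.strip()) if len(node) else float(parts[-1])
            return sp.Float(mant * 10 ** exp)
        if cn_type == "rational":
            num = int(node.text.strip())
            den = int(node[-1].tail.strip())
            return sp.Rational(num, den)
        if cn_type == "integer":
            return sp.Integer(int(node.text.strip()))
        return sp.Float(float(node.text.strip()))
    if tag == "apply":
        kids = [c for c in node if isinstance(c.tag, str)]
        head, args = kids[0], kids[1:]
        head_tag = _local(head.tag)
        vals = [mathml_to_sympy(a, symbols, functions) for a in args]
        if head_tag == "ci":  # user-defined function call
            fname = head.text.strip()
            if fname not in functions:
                raise UnsupportedSBMLFeature(f"call to undefined function {fname!r}")
            return functions[fname](*vals)
        if head_tag == "root":
            # possibly with <degree>
            return sp.sqrt(vals[0]) if len(vals) == 1 else vals[-1] ** (1 / vals[0])
        if head_tag == "log":
            return sp.log(vals[-1], 10) if len(vals) == 1 else sp.log(vals[-1], vals[0])
        if head_tag in _MATHML_OPS:
            return _MATHML_OPS[head_tag](*vals)
        raise UnsupportedSBMLFeature(f"MathML operator <{head_tag}> not supported",
                                     features=[head_tag])
    if tag == "csymbol":
        raise UnsupportedSBMLFeature(
            f"csymbol ({node.text and node.text.strip()}) not supported",
            features=["csymbol"])
    if tag in ("degree", "logbase"):
        kids = [c for c in node if isinstance(c.tag, str)]
        return mathml_to_sympy(kids[0], symbols, functions)
    if tag == "lambda":
        kids = [c for c in node if isinstance(c.tag, str)]
        bvars = [mathml_to_sympy(_find(b, "ci"), symbols, functions)
                 for b in kids if _local(b.tag) == "bvar"]
        body = mathml_to_sympy(kids[-1], symbols, functions)
        return sp.Lambda(tuple(bvars), body)
    raise UnsupportedSBMLFeature(f"MathML element <{tag}> not supported",
                                 features=[tag])


# ---------------------------------------------------------------------------
# SBML document
# ---------------------------------------------------------------------------

@dataclass
class _Species:
    sid: str
    compartment: str
    initial: float            # concentration
    boundary: bool
    constant: bool


def read_sbml(path, input_species: tuple[str, ...] = ()
              ) -> tuple[ControlAffineModel, StoichiometricNetwork]:
    """Parse an SBML file into a control-affine model plus its network.

    Parameters
    ----------
    path : str or Path
    input_species
        Boundary/constant species promoted to model input channels (their
        concentration becomes u_i(t)); the kinetics must be affine in each
        promoted species, which is verified symbolically.

    Returns
    -------
    (ControlAffineModel, StoichiometricNetwork)
        States are the non-boundary, non-constant species (concentration
        units); the network carries the stoichiometry of those states and
        the numeric rate-law functions.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise ValidationError(f"{path} is not an SBML document")
    model_el = _find(root, "model")
    if model_el is None:
        raise ValidationError("SBML document has no <model>")

    unsupported = []
    for listname in ("listOfEvents", "listOfRules", "listOfConstraints"):
        el = _find(model_el, listname)
        if el is not None and len(el):
            unsupported.append(listname)
    if unsupported:
        raise UnsupportedSBMLFeature(
            f"unsupported SBML constructs present: {unsupported}",
            features=unsupported)

    # compartments
    comp_size = {}
    lc = _find(model_el, "listOfCompartments")
    for comp in (lc if lc is not None else []):
        comp_size[comp.get("id")] = float(comp.get("size", comp.get("volume", 1.0) or 1.0))

    # parameters (global)
    params: dict[str, float] = {}
    lp = _find(model_el, "listOfParameters")
    for p in (lp if lp is not None else []):
        params[p.get("id")] = float(p.get("value", "nan"))

    # species
    species: list[_Species] = []
    ls = _find(model_el, "listOfSpecies")
    for s in (ls if ls is not None else []):
        comp = s.get("compartment")
        vol = comp_size.get(comp, 1.0)
        if s.get("initialConcentration") is not None:
            init = float(s.get("initialConcentration"))
        elif s.get("initialAmount") is not None:
            init = float(s.get("initialAmount")) / vol
        else:
            init = 0.0
        species.append(_Species(
            sid=s.get("id"), compartment=comp, initial=init,
            boundary=s.get("boundaryCondition", "false") == "true",
            constant=s.get("constant", "false") == "true",
        ))
    sp_by_id = {s.sid: s for s in species}
    for name in input_species:
        if name not in sp_by_id:
            raise ValidationError(f"input species {name!r} not in model")

    dynamic = [s for s in species
               if not (s.boundary or s.constant) and s.sid not in input_species]
    state_ids = [s.sid for s in dynamic]
    fixed = {s.sid: s.initial for s in species
             if (s.boundary or s.constant) and s.sid not in input_species}

    # symbols
    sym = {sid: sp.Symbol(sid) for sid in state_ids}
    input_syms = {name: sp.Symbol(name) for name in input_species}
    symbols: dict[str, sp.Expr] = {}
    symbols.update({k: sp.Float(v) for k, v in comp_size.items()})
    symbols.update({k: sp.Float(v) for k, v in params.items()})
    symbols.update({k: sp.Float(v) for k, v in fixed.items()})
    symbols.update(sym)
    symbols.update(input_syms)

    # function definitions
    functions: dict[str, sp.Lambda] = {}
    lf = _find(model_el, "listOfFunctionDefinitions")
    for f in (lf if lf is not None else []):
        math = _find(f, "math")
        functions[f.get("id")] = mathml_to_sympy(math, symbols, functions)

    # initial assignments (simple numeric evaluation)
    lia = _find(model_el, "listOfInitialAssignments")
    for ia in (lia if lia is not None else []):
        target = ia.get("symbol")
        expr = mathml_to_sympy(_find(ia, "math"), symbols, functions)
        val = float(expr.evalf(subs={v: 0 for v in expr.free_symbols}))
        if target in params:
            params[target] = val
            symbols[target] = sp.Float(val)
        elif target in sp_by_id:
            sp_by_id[target].initial = val
        elif target in comp_size:
            comp_size[target] = val
            symbols[target] = sp.Float(val)

    # reactions
    reactions, rate_exprs, stoich_cols = [], [], []
    lr = _find(model_el, "listOfReactions")
    for rxn in (lr if lr is not None else []):
        rid = rxn.get("id")
        reactions.append(rid)
        col = np.zeros(len(state_ids))
        for side, sign in (("listOfReactants", -1.0), ("listOfProducts", +1.0)):
            lst = _find(rxn, side)
            for ref in (lst if lst is not None else []):
                if _local(ref.tag) != "speciesReference":
                    continue
                sid = ref.get("species")
                st = float(ref.get("stoichiometry", 1.0))
                if sid in state_ids:
                    i = state_ids.index(sid)
                    vol = comp_size.get(sp_by_id[sid].compartment, 1.0)
                    col[i] += sign * st / vol
        stoich_cols.append(col)

        kl = _find(rxn, "kineticLaw")
        if kl is None:
            raise UnsupportedSBMLFeature(f"reaction {rid} has no kinetic law")
        local_syms = dict(symbols)
        for lname in ("listOfLocalParameters", "listOfParameters"):
            lst = _find(kl, lname)
            for p in (lst if lst is not None else []):
                local_syms[p.get("id")] = sp.Float(float(p.get("value")))
        rate_exprs.append(mathml_to_sympy(_find(kl, "math"), local_syms, functions))

    N = np.column_stack(stoich_cols) if stoich_cols else np.zeros((len(state_ids), 0))

    state_vec = [sym[sid] for sid in state_ids]
    input_vec = [input_syms[n] for n in input_species]

    # numeric rate function (inputs at their fixed initial value)
    input_fixed = {input_syms[n]: sp_by_id[n].initial for n in input_species}
    rates_fn = sp.lambdify([state_vec], [e.subs(input_fixed) for e in rate_exprs],
                           modules="numpy")
    network = StoichiometricNetwork(
        species=list(state_ids), reactions=reactions, N=N,
        rates=lambda x: np.asarray(rates_fn(x), dtype=float),
    )

    drift_exprs = sp.Matrix(N) @ sp.Matrix(rate_exprs) if reactions else sp.zeros(len(state_ids), 1)
    # verify affine dependence on each promoted input and extract fields
    g_fns = []
    for u in input_vec:
        g_expr = drift_exprs.diff(u)
        if any(e.has(u) for e in g_expr):
            raise ValidationError(
                f"kinetics are not affine in input species {u}; cannot "
                "promote it to a control-affine input channel")
        g_fns.append(sp.lambdify([state_vec],
                                 list(g_expr.subs(input_fixed)), modules="numpy"))
    f_expr = drift_exprs.subs({u: 0 for u in input_vec})
    f_fn = sp.lambdify([state_vec], list(f_expr), modules="numpy")

    x0 = np.array([sp_by_id[sid].initial for sid in state_ids])
    model = ControlAffineModel(
        state_names=list(state_ids),
        drift=lambda x: np.asarray(f_fn(x), dtype=float),
        input_fields=[
            (lambda x, g=g: np.asarray(g(x), dtype=float)) for g in g_fns
        ],
        output_map=lambda x: x.copy(),
        initial_state=x0,
        input_names=list(input_species),
        output_names=list(state_ids),
    )
    return model, network
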