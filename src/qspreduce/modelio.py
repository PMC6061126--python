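"""Model serialization: a documented JSON schema plus trajectory CSV.

Two model kinds round-trip:

``linear``
    {"kind": "linear", "states": [...], "inputs": [...], "outputs": [...],
     "A": [[...]], "B": [[...]], "C": [[...]], "x0": [...]}

``symbolic``
    As above but with "drift", "input_fields" (list of lists) and
    "output_map" holding sympy-parseable expression strings over the
    state names.

Reading a written model reproduces its simulations bit-for-bit under the
same solver settings (the linear path is deterministic linear algebra).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import sympy as sp

from .core import ControlAffineModel, LinearStateSpaceModel
from .errors import ValidationError

__all__ = ["write_model", "read_model", "ModelDocument", "symbolic_model"]

SCHEMA_VERSION = 1


@dataclass
class ModelDocument:
    """A parsed model with provenance (source path, format, content hash)."""

    model: object
    source: str
    format: str
    sha256: str


def _model_payload(model) -> dict:
    if isinstance(model, LinearStateSpaceModel):
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "linear",
            "states": list(model.state_names),
            "inputs": list(model.input_names),
            "outputs": list(model.output_names),
            "A": model.A.tolist(),
            "B": model.B.tolist(),
            "C": model.C.tolist(),
            "x0": model.initial_state.tolist(),
        }
    if isinstance(model, ControlAffineModel) and hasattr(model, "expressions"):
        drift, fields, outputs = model.expressions
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "symbolic",
            "states": list(model.state_names),
            "inputs": list(model.input_names),
            "outputs": list(model.output_names),
            "drift": [str(e) for e in drift],
            "input_fields": [[str(e) for e in f] for f in fields],
            "output_map": [str(e) for e in outputs],
            "x0": model.initial_state.tolist(),
        }
    raise ValidationError(
        "only linear models and symbolic control-affine models (built via "
        "symbolic_model) can be serialized")


def write_model(model, path) -> None:
    Path(path).write_text(json.dumps(_model_payload(model), indent=1))


def symbolic_model(state_names, drift_exprs, output_exprs, x0,
                   input_field_exprs=(), input_names=(), output_names=None,
                   ) -> ControlAffineModel:
    """Build a ControlAffineModel from sympy-parseable expression strings.

    The expressions may reference the state names as symbols.  The
    resulting model carries its expressions (``model.expressions``) so it
    serializes through :func:`write_model`.
    """
    syms = [sp.Symbol(s) for s in state_names]
    local = {s: sym for s, sym in zip(state_names, syms)}

    def parse(e):
        return sp.sympify(e, locals=local)

    drift = [parse(e) for e in drift_exprs]
    fields = [[parse(e) for e in f] for f in input_field_exprs]
    outputs = [parse(e) for e in output_exprs]

    f_fn = sp.lambdify([syms], drift, modules="numpy")
    g_fns = [sp.lambdify([syms], f, modules="numpy") for f in fields]
    h_fn = sp.lambdify([syms], outputs, modules="numpy")

    model = ControlAffineModel(
        state_names=list(state_names),
        drift=lambda x: np.asarray(f_fn(x), dtype=float),
        input_fields=[
            (lambda x, g=g: np.asarray(g(x), dtype=float)) for g in g_fns
        ],
        output_map=lambda x: np.asarray(h_fn(x), dtype=float),
        initial_state=np.asarray(x0, dtype=float),
        input_names=list(input_names),
        output_names=(list(output_names) if output_names is not None
                      else [f"y{i}" for i in range(len(outputs))]),
    )
    model.expressions = (drift, fields, outputs)
    return model


def read_model(path) -> ModelDocument:
    """Read a model JSON document (see module docstring for the schema)."""
    text = Path(path).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    doc = json.loads(text)
    kind = doc.get("kind")
    if kind == "linear":
        model = LinearStateSpaceModel(
            A=np.array(doc["A"], dtype=float),
            B=np.array(doc["B"], dtype=float),
            C=np.array(doc["C"], dtype=float),
            state_names=doc["states"], input_names=doc["inputs"],
            output_names=doc["outputs"],
            initial_state=np.array(doc["x0"], dtype=float),
        )
    elif kind == "symbolic":
        model = symbolic_model(
            doc["states"], doc["drift"], doc["output_map"], doc["x0"],
            input_field_exprs=doc.get("input_fields", ()),
            input_names=doc["inputs"], output_names=doc["outputs"],
        )
    else:
        raise ValidationError(f"unknown model kind {kind!r} in {path}")
    return ModelDocument(model=model, source=str(path), format="qspreduce-json",
                         sha256=digest)
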