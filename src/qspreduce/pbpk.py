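"""Whole-body physiologically based pharmacokinetic (PBPK) model builder.

Constructs the 16-compartment perfusion-limited PBPK model (13 tissues,
venous and arterial blood, and an oral dosing depot) as a linear
state-space system from a physiological parameter set (body weight,
cardiac output, fractional tissue volumes and blood flows) and a
compound-specific set (blood:plasma ratio, absorption rate, hepatic blood
clearance, tissue:plasma partition coefficients).

Model structure
---------------
Tissue compartments are perfusion-limited: for tissue t with blood flow
Q_t = FQ_t * QC and volume V_t = FV_t * BW,

    dC_t/dt = Q_t (C_ar - C_t / Kp_t) / V_t,

with the partition coefficient Kp_t read as a tissue:blood ratio
(``kp_reference="blood"``, the default).  Reading the same values as
tissue:plasma ratios instead puts the blood-to-plasma ratio BP in the
outflow term, C_t * BP / Kp_t (``kp_reference="plasma"``); both
conventions appear in the PBPK literature and the choice is exposed.

Spleen and gut drain into the liver (splanchnic circulation); the liver
additionally receives hepatic-arterial blood and eliminates drug by
hepatic blood clearance CL_h applied to its outflow blood concentration.
The lung is in series between venous and arterial blood at full cardiac
output.  Oral doses enter an amount-based depot that empties into gut
tissue at first-order rate Ka; IV doses enter venous blood.

Units: concentrations mg/L, amounts mg, time h, flows L/h, volumes L.

Parameter fixtures for a 70 kg reference human and for three compounds —
pindolol (strong base), midazolam (weak base) and thiopental (acid) —
ship with the package under the names ``"human70kg"``, ``"pindolol"``,
``"midazolam"`` and ``"thiopental"``.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import LinearStateSpaceModel
from .errors import ConfigurationError, ValidationError

__all__ = [
    "PhysiologicalParameters",
    "CompoundParameters",
    "build_pbpk",
    "default_outputs",
    "physiological_fixture",
    "compound_fixture",
    "tissue_volumes",
    "amount_coordinates",
    "lumping_weights",
    "split_oral_depot",
    "TISSUES",
    "STATE_NAMES",
]

#: Perfused tissue compartments (short codes).
TISSUES = ["ad", "bo", "br", "gu", "he", "ki", "li", "lu", "mu", "sk", "sp", "te", "re"]

_TISSUE_LONG = {
    "ad": "adipose", "bo": "bone", "br": "brain", "gu": "gut", "he": "heart",
    "ki": "kidney", "li": "liver", "lu": "lung", "mu": "muscle", "sk": "skin",
    "sp": "spleen", "te": "testes", "re": "rest",
}

#: State ordering of the built model: 13 tissue concentrations, venous and
#: arterial blood concentrations (mg/L), then the oral depot amount (mg).
STATE_NAMES = [_TISSUE_LONG[t] for t in TISSUES] + ["venous", "arterial", "oral_depot"]

#: Tissues with a directly printed fractional blood flow (hepatic flow "h"
#: is the total splanchnic outflow: hepatic artery + gut + spleen).
_FQ_KEYS = ["ad", "bo", "br", "gu", "he", "ki", "h", "lu", "mu", "sk", "sp"]

#: Tissues whose Kp is printed; testes and rest-of-body use the mean rule.
_KP_KEYS = ["ad", "bo", "br", "gu", "he", "ki", "li", "lu", "mu", "sk", "sp"]


@dataclass
class PhysiologicalParameters:
    """Physiology of the dosed individual (reference: 70 kg adult male)."""

    name: str
    BW: float                      # body weight, kg
    QC: float                      # cardiac output, L/h
    MPPGL: float                   # mg microsomal protein / g liver (carried, unused)
    FV: dict[str, float]           # fractional volumes, L/kg
    FQ: dict[str, float]           # fractional blood flows (of QC)

    def __post_init__(self):
        needed_fv = set(TISSUES) | {"ve", "ar", "pl", "rb"}
        missing = needed_fv - set(self.FV)
        if missing:
            raise ValidationError(f"missing fractional volumes: {sorted(missing)}")
        missing_q = set(_FQ_KEYS) - set(self.FQ)
        if missing_q:
            raise ValidationError(f"missing fractional flows: {sorted(missing_q)}")
        if any(v <= 0 for v in self.FV.values()) or any(v <= 0 for v in self.FQ.values()):
            raise ValidationError("fractional volumes/flows must be positive")
        if self.FQ["lu"] != 1:
            raise ValidationError("lung fractional flow must be 1 (full cardiac output)")
        if self.residual_flow_fraction < 0:
            raise ValidationError(
                "printed systemic flow fractions exceed 1; no residual flow left")

    @property
    def residual_flow_fraction(self) -> float:
        """1 - sum of printed systemic flow fractions (goes to testes + rest).

        Gut and spleen are inside the hepatic fraction FQ["h"], so the
        systemic sum counts ad, bo, br, he, ki, mu, sk and h.
        """
        systemic = sum(self.FQ[k] for k in ["ad", "bo", "br", "he", "ki", "mu", "sk", "h"])
        return 1.0 - systemic

    def flow(self, tissue: str) -> float:
        """Absolute blood flow Q_t in L/h (testes/rest: volume-weighted residual)."""
        if tissue in self.FQ:
            return self.FQ[tissue] * self.QC
        if tissue in ("te", "re"):
            share = self.FV[tissue] / (self.FV["te"] + self.FV["re"])
            return self.residual_flow_fraction * share * self.QC
        raise KeyError(tissue)

    def volume(self, tissue: str) -> float:
        """Absolute volume V_t in L."""
        return self.FV[tissue] * self.BW


@dataclass
class CompoundParameters:
    """Compound-specific disposition parameters."""

    name: str
    BP: float                      # blood-to-plasma concentration ratio
    fu_p: float                    # fraction unbound in plasma (carried, unused)
    Ka: float                      # first-order absorption rate, 1/h
    CL_bl: float                   # hepatic blood clearance, mL/min/kg
    Kp: dict[str, float]           # tissue:plasma partition coefficients
    Kp_residual_rule: str = "mean"

    def __post_init__(self):
        missing = set(_KP_KEYS) - set(self.Kp)
        if missing:
            raise ValidationError(f"missing partition coefficients: {sorted(missing)}")
        if any(v <= 0 for v in (self.BP, self.fu_p, self.Ka)):
            raise ValidationError("BP, fu_p and Ka must be positive")
        if self.CL_bl < 0:
            raise ValidationError("CL_bl cannot be negative")
        if self.fu_p > 1:
            raise ValidationError("fraction unbound cannot exceed 1")
        if any(v <= 0 for v in self.Kp.values()):
            raise ValidationError("partition coefficients must be positive")

    def kp(self, tissue: str) -> float:
        """Kp for any tissue; testes/rest default to the mean of printed values."""
        if tissue in self.Kp:
            return self.Kp[tissue]
        if tissue in ("te", "re") and self.Kp_residual_rule == "mean":
            return float(np.mean([self.Kp[k] for k in _KP_KEYS]))
        raise KeyError(tissue)

    def hepatic_clearance(self, BW: float) -> float:
        """CL_h in L/h: CL_bl [mL/min/kg] * BW [kg] * 60 / 1000."""
        return self.CL_bl * BW * 60.0 / 1000.0


# ---------------------------------------------------------------------------
# packaged parameter fixtures
# ---------------------------------------------------------------------------

_HUMAN70KG = PhysiologicalParameters(
    name="human70kg", BW=70.0, QC=390.0, MPPGL=45.0,
    FV={
        "ad": 2.13e-1, "bo": 8.56e-2, "br": 2e-2, "gu": 1.71e-2, "he": 4.7e-3,
        "ki": 4.4e-3, "li": 2.1e-2, "lu": 7.6e-3, "mu": 4e-1, "sk": 3.71e-2,
        "sp": 2.6e-3, "te": 1e-2, "ve": 5.14e-2, "ar": 2.57e-2,
        "pl": 4.24e-2, "rb": 3.47e-2, "re": 9.98e-2,
    },
    FQ={
        "ad": 5e-2, "bo": 5e-2, "br": 1.2e-1, "gu": 1.46e-1, "he": 4e-2,
        "ki": 1.9e-1, "h": 2.15e-1, "lu": 1.0, "mu": 1.7e-1, "sk": 5e-2,
        "sp": 1.72e-2,
    },
)

_COMPOUNDS = {
    "pindolol": CompoundParameters(
        name="pindolol", BP=0.81, fu_p=0.41, Ka=2.08, CL_bl=4.20,
        Kp={"ad": 1.52, "bo": 2.79, "br": 2.26, "gu": 9.01, "he": 8.43,
            "ki": 17.94, "li": 16.40, "lu": 14.11, "mu": 6.08, "sk": 5.13,
            "sp": 11.70},
    ),
    "midazolam": CompoundParameters(
        name="midazolam", BP=0.53, fu_p=0.05, Ka=1.13, CL_bl=8.70,
        Kp={"ad": 2.41, "bo": 2.26, "br": 5.12, "gu": 5.38, "he": 2.25,
            "ki": 2.51, "li": 2.77, "lu": 3.33, "mu": 1.61, "sk": 7.84,
            "sp": 1.47},
    ),
    "thiopental": CompoundParameters(
        name="thiopental", BP=0.88, fu_p=0.18, Ka=5.64, CL_bl=2.02,
        Kp={"ad": 12.17, "bo": 1.64, "br": 1.09, "gu": 2.03, "he": 1.72,
            "ki": 4.85, "li": 3.60, "lu": 1.72, "mu": 0.78, "sk": 1.25,
            "sp": 0.94},
    ),
}


def physiological_fixture(name: str = "human70kg") -> PhysiologicalParameters:
    """Packaged physiological parameter set (currently only ``"human70kg"``)."""
    if name != "human70kg":
        raise ConfigurationError(f"unknown physiological fixture {name!r}")
    return copy.deepcopy(_HUMAN70KG)


def compound_fixture(name: str) -> CompoundParameters:
    """Packaged compound parameter set: pindolol, midazolam or thiopental."""
    try:
        return copy.deepcopy(_COMPOUNDS[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown compound fixture {name!r}; available: {sorted(_COMPOUNDS)}"
        ) from None


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_pbpk(phys: PhysiologicalParameters,
               compound: CompoundParameters,
               outputs: list[str] | None = None,
               kp_reference: str = "blood") -> LinearStateSpaceModel:
    """Assemble the 16-state linear PBPK model.

    Parameters
    ----------
    phys, compound
        Parameter sets (see :func:`physiological_fixture`,
        :func:`compound_fixture`).
    outputs
        Compartment names selected as outputs (default ``["venous"]``).
    kp_reference
        ``"blood"`` (default): partition coefficients are tissue:blood, so
        tissue outflow blood concentration is C_t / Kp_t.  ``"plasma"``:
        they are tissue:plasma and the outflow is C_t * BP / Kp_t.

    Returns
    -------
    LinearStateSpaceModel
        16 states (see :data:`STATE_NAMES`), input channels ``oral`` (mg
        into the depot) and ``IV`` (mg into venous blood), zero initial
        state.  Off-diagonal entries of A are non-negative (compartmental
        structure); the only mass sink is hepatic clearance.

    Raises
    ------
    ConfigurationError
        If the hepatic arterial flow (hepatic minus gut minus spleen flow)
        is not positive.
    """
    if kp_reference not in ("blood", "plasma"):
        raise ConfigurationError(
            f"kp_reference must be 'blood' or 'plasma', got {kp_reference!r}")
    BP, Ka = compound.BP, compound.Ka
    QC, BW = phys.QC, phys.BW

    Q = {t: phys.flow(t) for t in TISSUES if t not in ("li", "lu")}
    V = {t: phys.volume(t) for t in TISSUES}
    V["ve"] = phys.volume("ve")
    V["ar"] = phys.volume("ar")
    Q_h = phys.FQ["h"] * QC
    Q_ha = Q_h - Q["gu"] - Q["sp"]
    if Q_ha <= 0:
        raise ConfigurationError(
            f"hepatic arterial flow is non-positive ({Q_ha:.3g} L/h): "
            "gut + spleen flow exceeds total hepatic flow")
    CL_h = compound.hepatic_clearance(BW)
    if CL_h >= Q_h:
        warnings.warn(
            f"hepatic clearance CL_h={CL_h:.3g} L/h >= hepatic blood flow "
            f"Q_h={Q_h:.3g} L/h; non-physical for a blood-clearance model",
            stacklevel=2)

    idx = {name: i for i, name in enumerate(STATE_NAMES)}
    n = len(STATE_NAMES)
    A = np.zeros((n, n))

    def venous_return(tissue_code: str) -> float:
        """Outflow blood-concentration factor (1/Kp or BP/Kp) for a tissue."""
        if kp_reference == "blood":
            return 1.0 / compound.kp(tissue_code)
        return BP / compound.kp(tissue_code)

    i_ve, i_ar, i_dep = idx["venous"], idx["arterial"], idx["oral_depot"]

    # oral depot (amount, mg): first-order emptying into gut tissue
    A[i_dep, i_dep] = -Ka
    i_gu = idx["gut"]
    A[i_gu, i_dep] += Ka / V["gu"]

    # generic perfusion-limited tissues returning to venous blood
    for t in ["ad", "bo", "br", "he", "ki", "mu", "sk", "te", "re"]:
        i = idx[_TISSUE_LONG[t]]
        A[i, i_ar] += Q[t] / V[t]
        A[i, i] -= Q[t] * venous_return(t) / V[t]
        A[i_ve, i] += Q[t] * venous_return(t) / V["ve"]

    # splanchnic: gut and spleen drain into the liver
    for t in ["gu", "sp"]:
        i = idx[_TISSUE_LONG[t]]
        A[i, i_ar] += Q[t] / V[t]
        A[i, i] -= Q[t] * venous_return(t) / V[t]

    i_li = idx["liver"]
    A[i_li, i_ar] += Q_ha / V["li"]
    A[i_li, i_gu] += Q["gu"] * venous_return("gu") / V["li"]
    A[i_li, idx["spleen"]] += Q["sp"] * venous_return("sp") / V["li"]
    A[i_li, i_li] -= (Q_h + CL_h) * venous_return("li") / V["li"]
    A[i_ve, i_li] += Q_h * venous_return("li") / V["ve"]

    # pulmonary circulation and arterial supply
    i_lu = idx["lung"]
    A[i_lu, i_ve] += QC / V["lu"]
    A[i_lu, i_lu] -= QC * venous_return("lu") / V["lu"]
    A[i_ar, i_lu] += QC * venous_return("lu") / V["ar"]
    A[i_ar, i_ar] -= QC / V["ar"]
    A[i_ve, i_ve] -= QC / V["ve"]

    B = np.zeros((n, 2))
    B[i_dep, 0] = 1.0            # oral: mg into the depot amount
    B[i_ve, 1] = 1.0 / V["ve"]   # IV: mg into venous blood volume

    model = LinearStateSpaceModel(
        A=A, B=B, C=np.zeros((1, n)), state_names=list(STATE_NAMES),
        input_names=["oral", "IV"], output_names=["venous"],
        initial_state=np.zeros(n),
    )
    return default_outputs(model, outputs or ["venous"])


def default_outputs(model: LinearStateSpaceModel,
                    compartments: list[str]) -> LinearStateSpaceModel:
    """Re-target the output map to select the named compartments.

    Each requested compartment contributes one identity row of C, so the
    outputs are the raw state concentrations.  ``compartments=list of all
    states`` yields C = I.
    """
    if not compartments:
        raise ConfigurationError("output selection must name at least one compartment")
    n = model.n_states
    C = np.zeros((len(compartments), n))
    for r, name in enumerate(compartments):
        if name not in model.state_names:
            raise ConfigurationError(
                f"unknown compartment {name!r}; states are {model.state_names}")
        C[r, model.state_names.index(name)] = 1.0
    return model.with_outputs(C, list(compartments))


def tissue_volumes(phys: PhysiologicalParameters) -> dict[str, float]:
    """Volumes (L) keyed by state name, incl. blood pools; depot has 'volume' 1.

    Used for mass-balance accounting: total drug mass is
    sum_t V_t * C_t + depot amount.
    """
    vols = {_TISSUE_LONG[t]: phys.volume(t) for t in TISSUES}
    vols["venous"] = phys.volume("ve")
    vols["arterial"] = phys.volume("ar")
    vols["oral_depot"] = 1.0
    return vols


def amount_coordinates(model: LinearStateSpaceModel,
                       phys: PhysiologicalParameters) -> LinearStateSpaceModel:
    """Similarity-transform a PBPK model from concentrations to amounts (mg).

    The input-output behaviour is unchanged (outputs are re-expressed so
    they still report the original concentrations); lumping operates most
    naturally on amounts, where merging compartments conserves mass.
    """
    vols_d = tissue_volumes(phys)
    v = np.array([vols_d[s] for s in model.state_names])
    D, Di = np.diag(v), np.diag(1.0 / v)
    return LinearStateSpaceModel(
        A=D @ model.A @ Di, B=D @ model.B, C=model.C @ Di,
        state_names=list(model.state_names), input_names=list(model.input_names),
        output_names=list(model.output_names),
        initial_state=v * model.initial_state,
    )


def lumping_weights(phys: PhysiologicalParameters,
                    compound: CompoundParameters,
                    state_names: list[str],
                    kp_reference: str = "blood") -> np.ndarray:
    """Effective-volume weights for distributing a lumped amount.

    Compartments merged into one lump are modelled as sharing a common
    blood-equivalent concentration, so a lumped amount is distributed in
    proportion to the effective volume V_t * Kp_t (tissue:blood reference;
    V_t * Kp_t / BP for tissue:plasma).  Blood pools weight by their plain
    volume and the oral depot (an amount, not a concentration) by 1.
    """
    long2short = {v: k for k, v in _TISSUE_LONG.items()}
    vols = tissue_volumes(phys)
    w = []
    for s in state_names:
        if s in ("venous", "arterial"):
            w.append(vols[s])
        elif s == "oral_depot":
            w.append(1.0)
        else:
            kp = compound.kp(long2short[s])
            if kp_reference == "plasma":
                kp = kp / compound.BP
            w.append(vols[s] * kp)
    return np.array(w)


def split_oral_depot(model: LinearStateSpaceModel, Ka: float
                     ) -> tuple[LinearStateSpaceModel, np.ndarray]:
    """Separate the oral depot from the 15-state distribution block.

    The depot is a pure one-state absorption process; the rest of the
    model is a distribution network driven by the absorption flux
    Ka * A_depot(t) (mg/h).  Returns the distribution block as a linear
    model with a single input channel ``absorption`` (the flux) and the
    original outputs, plus the depot's column of A (for reattachment).

    Used by the reduce-then-relink workflow: reduce the block under the
    declared outputs, then reattach the depot with
    :func:`qspreduce.workflows.attach_oral_depot`.
    """
    if "oral_depot" not in model.state_names:
        raise ConfigurationError("model has no oral_depot state")
    i_dep = model.state_names.index("oral_depot")
    keep = [i for i in range(model.n_states) if i != i_dep]
    A = model.A[np.ix_(keep, keep)]
    # depot column of A is Ka * (unit-flux distribution); normalise by Ka
    b_flux = (model.A[keep, i_dep] / Ka).reshape(-1, 1)
    C = model.C[:, keep]
    if np.any(model.C[:, i_dep] != 0):
        raise ConfigurationError("outputs must not read the oral depot directly")
    block = LinearStateSpaceModel(
        A=A, B=b_flux, C=C,
        state_names=[model.state_names[i] for i in keep],
        input_names=["absorption"], output_names=list(model.output_names),
        initial_state=model.initial_state[keep],
    )
    return block, b_flux
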